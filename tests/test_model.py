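"""State enumeration, reaction rates, and the intensity matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sytfuse.model import (
    BindingState,
    InvalidParameterError,
    InvalidStateError,
    ModelParameters,
    build_intensity_matrix,
    enumerate_states,
    fusion_rate,
    reaction_rates,
)

# the published worked example: all states for 3 syts and 2 slots, in order
PRINTED_ORDER_3_2 = [
    (0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 1, 0), (0, 1, 1), (0, 1, 2),
    (0, 2, 0), (0, 2, 1), (0, 3, 0), (1, 0, 0), (1, 0, 1), (1, 1, 0),
    (1, 1, 1), (1, 2, 0), (2, 0, 0), (2, 1, 0),
]


class TestEnumeration:
    def test_worked_listing_3_2(self):
        space = enumerate_states(3, 2)
        assert [s.triplet for s in space.states[:-1]] == PRINTED_ORDER_3_2
        assert space.states[-1].fused

    def test_standard_model_has_141_states(self):
        assert len(enumerate_states(15, 3)) == 141

    def test_minimal_space(self):
        # brute-force: triplets with n+m+k<=1 and n+k<=1
        space = enumerate_states(1, 1)
        assert [s.triplet for s in space.states[:-1]] == [
            (0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)
        ]
        assert len(space) == 5

    def test_counts_match_bruteforce(self):
        for n_syts, M in [(2, 2), (4, 3), (15, 6), (5, 1)]:
            space = enumerate_states(n_syts, M)
            brute = [
                (n, m, k)
                for n in range(n_syts + 1)
                for m in range(n_syts + 1)
                for k in range(n_syts + 1)
                if n + m + k <= n_syts and n + k <= M
            ]
            assert space.n_binding_states == len(brute)
            assert [s.triplet for s in space.states[:-1]] == sorted(brute)

    def test_index_maps_are_bijective(self):
        space = enumerate_states(4, 2)
        for i, s in enumerate(space.states):
            assert space.index(s) == i
            assert space.state(i) == s

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            enumerate_states(0, 3)
        with pytest.raises(InvalidParameterError):
            enumerate_states(3, 0)


class TestParameters:
    def test_derived_dissociation_rates(self, params3):
        assert params3.beta == pytest.approx(221.0**2 * params3.alpha)
        assert params3.delta == pytest.approx(20.0 * params3.gamma)

    def test_allosteric_factor_from_affinity_shift(self, params3):
        assert params3.A == pytest.approx((3.3 / 221.0) ** 2, rel=0.02)

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            ModelParameters(alpha=-1, gamma=1, pip2=1, f=2)
        with pytest.raises(InvalidParameterError):
            ModelParameters(alpha=1, gamma=1, pip2=1, f=0.5)
        with pytest.raises(InvalidParameterError):
            ModelParameters(alpha=1, gamma=1, pip2=1, f=2, A=1.5)

    def test_round_trip_yaml(self, tmp_path, params3):
        path = tmp_path / "p.yaml"
        import yaml

        path.write_text(yaml.safe_dump(params3.to_dict()))
        assert ModelParameters.from_yaml(path) == params3


class TestFusionRate:
    def test_no_dual_bindings_gives_basal_rate(self, params3):
        assert fusion_rate(0, params3) == params3.L_plus

    def test_factor_one_is_flat(self, params3):
        p = params3.replace(f=1.0)
        for n in range(4):
            assert fusion_rate(n, p) == p.L_plus

    def test_three_duals(self, params3):
        assert fusion_rate(3, params3) == pytest.approx(4.23e-4 * 128.2**3)

    def test_negative_duals_rejected(self, params3):
        with pytest.raises(InvalidStateError):
            fusion_rate(-1, params3)


class TestReactionRates:
    def test_empty_state_rates(self, params3):
        rates = dict(
            (t.triplet if not t.fused else "F", r)
            for t, r in reaction_rates(BindingState(0, 0, 0), params3, ca=50.0)
        )
        assert rates[(0, 0, 1)] == pytest.approx(
            15 * 3 * params3.gamma * params3.pip2)
        assert rates[(0, 1, 0)] == pytest.approx(15 * 50.0**2 * params3.alpha)
        assert set(rates) == {(0, 0, 1), (0, 1, 0), "F"}

    def test_zero_calcium_kills_association(self, params3):
        for state in [BindingState(0, 0, 0), BindingState(1, 2, 1)]:
            for target, rate in reaction_rates(state, params3, ca=0.0):
                if not target.fused and target.m + target.n > state.m + state.n:
                    assert rate == 0.0

    def test_dual_dissociation_targets_and_rates(self, params3):
        out = dict(
            (t.triplet, r)
            for t, r in reaction_rates(BindingState(1, 0, 0), params3, ca=1.0)
            if not t.fused
        )
        assert out[(0, 1, 0)] == pytest.approx(params3.A * params3.delta)
        assert out[(0, 0, 1)] == pytest.approx(params3.A * params3.beta)

    def test_inadmissible_state_rejected(self, params3):
        with pytest.raises(InvalidStateError):
            reaction_rates(BindingState(4, 0, 0), params3, ca=1.0)


def _hand_assembled_Q(params, ca, pip2, include_fusion=True):
    """Independent per-entry assembly of the (3, 2) intensity matrix from
    the reaction-rate table (no reuse of reaction_rates)."""
    space = enumerate_states(3, 2)
    N, M = 3, 2
    idx = {s.triplet: i for i, s in enumerate(space.states[:-1])}
    F = space.fused_index
    Q = np.zeros((len(space), len(space)))
    cac = ca**2
    for (n, m, k), i in idx.items():
        free, slots = N - n - m - k, M - n - k
        if free > 0 and slots > 0:
            Q[i, idx[(n, m, k + 1)]] += free * slots * pip2 * params.gamma
        if k > 0:
            Q[i, idx[(n, m, k - 1)]] += k * params.delta
        if free > 0:
            Q[i, idx[(n, m + 1, k)]] += free * cac * params.alpha
        if m > 0:
            Q[i, idx[(n, m - 1, k)]] += m * params.beta
        if m > 0 and slots > 0:
            Q[i, idx[(n + 1, m - 1, k)]] += m * slots * pip2 * params.gamma
        if n > 0:
            Q[i, idx[(n - 1, m + 1, k)]] += params.A * n * params.delta
        if k > 0:
            Q[i, idx[(n + 1, m, k - 1)]] += k * cac * params.alpha
        if n > 0:
            Q[i, idx[(n - 1, m, k + 1)]] += params.A * n * params.beta
        if include_fusion:
            Q[i, F] += params.L_plus * params.f**n
        Q[i, i] = -Q[i].sum()
    return Q


class TestIntensityMatrix:
    def test_matches_hand_assembly(self, small_params):
        space = enumerate_states(3, 2)
        Q = build_intensity_matrix(space, small_params, ca=5.0).Q
        Q_hand = _hand_assembled_Q(small_params, ca=5.0, pip2=small_params.pip2)
        np.testing.assert_allclose(Q, Q_hand, rtol=1e-14)

    def test_fused_row_absorbing(self, params3):
        space = enumerate_states(15, 3)
        Q = build_intensity_matrix(space, params3, ca=50.0).Q
        assert np.all(Q[-1] == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(
        alpha=st.floats(1e-3, 1e3), gamma=st.floats(1e-3, 1e3),
        pip2=st.floats(0.0, 50.0), ca=st.floats(0.0, 100.0),
        f=st.floats(1.0, 1e4),
    )
    def test_row_sums_vanish(self, alpha, gamma, pip2, ca, f):
        p = ModelParameters(alpha=alpha, gamma=gamma, pip2=pip2, f=f,
                            n_syts=4, M_slots=2)
        Q = build_intensity_matrix(enumerate_states(4, 2), p, ca=ca).Q
        scale = np.abs(Q).max() + 1.0
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * scale

    def test_detailed_balance_on_elementary_cycles(self, params3):
        """Kolmogorov criterion on the fusion-free chain: around the square
        (n,m,k) -> (n,m,k+1) -> (n+1,m,k) -> (n+1,m-1,k) -> (n,m,k) formed
        by PI(4,5)P2 binding / dual formation via Ca2+ / dual loss of
        PI(4,5)P2 / Ca2+ unbinding, forward and backward rate products
        agree (the allosteric factor sits on both dissociation legs)."""
        space = enumerate_states(15, 3)
        ca, pip2 = 5.0, params3.pip2

        def rate(src, dst):
            for t, r in reaction_rates(src, params3, ca, include_fusion=False):
                if t == dst:
                    return r
            return 0.0

        checked = 0
        for s in space.states[:-1]:
            n, m, k = s.triplet
            if m < 1:
                continue
            cycle = [BindingState(n, m, k), BindingState(n, m, k + 1),
                     BindingState(n + 1, m, k), BindingState(n + 1, m - 1, k)]
            if not all(c.admissible(15, 3) for c in cycle):
                continue
            fwd = bwd = 1.0
            ring = cycle + [cycle[0]]
            for a, b in zip(ring[:-1], ring[1:]):
                fwd *= rate(a, b)
                bwd *= rate(b, a)
            assert fwd == pytest.approx(bwd, rel=1e-10)
            checked += 1
        assert checked > 10
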