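"""Per-syt stochastic engine: propensities, initialisation, equivalences."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp, kstest

from sytfuse import _gillespie_kernel as gk
from sytfuse.analytic import time_course
from sytfuse.gillespie import (
    ca_affinity_mutant,
    heterozygous_steady_state,
    init_from_steady_state,
    no_ca_binding_mutant,
    run,
    run_heterozygous,
    wild_type_class,
)
from sytfuse.steady_state import steady_state
from sytfuse.synthetic import StimulusTrace


class TestPropensities:
    def test_full_slots_block_pip2_binding(self, params3):
        """An unbound syt on a vesicle with all slots taken cannot bind
        PI(4,5)P2; only Ca2+ binding remains."""
        prop = gk._syt_propensity.py_func(
            gk.UNBOUND, 0, 50.0**2, params3.pip2,
            params3.alpha, params3.beta, params3.gamma, params3.delta,
            params3.A)
        assert prop == pytest.approx(params3.alpha * 50.0**2)

    def test_dual_bound_syt(self, params3):
        prop = gk._syt_propensity.py_func(
            gk.DUAL, 3, 50.0**2, params3.pip2,
            params3.alpha, params3.beta, params3.gamma, params3.delta,
            params3.A)
        assert prop == pytest.approx(params3.A * (params3.beta + params3.delta))

    def test_unbound_syt_with_free_slots(self, params3):
        prop = gk._syt_propensity.py_func(
            gk.UNBOUND, 2, 10.0**2, params3.pip2,
            params3.alpha, params3.beta, params3.gamma, params3.delta,
            params3.A)
        assert prop == pytest.approx(
            2 * params3.gamma * params3.pip2 + params3.alpha * 100.0)


class TestInitialisation:
    def test_degenerate_distribution_gives_empty_matrix(self, params3):
        phi = steady_state(params3, pip2=0.0, ca=0.0)
        # all mass on (0,0,0)
        codes = init_from_steady_state(phi, 50, rng=0)
        assert (codes == gk.UNBOUND).all()

    def test_frequencies_match_phi(self, params3):
        phi = steady_state(params3)
        n = 100_000
        codes = init_from_steady_state(phi, n, rng=1)
        # recover aggregated (n, m, k) per vesicle
        n_dual = (codes == gk.DUAL).sum(axis=0)
        n_ca = (codes == gk.CA_ONLY).sum(axis=0)
        n_pip = (codes == gk.PIP2_ONLY).sum(axis=0)
        space = phi.space
        idx = {tuple(t): i for i, t in enumerate(space.triplets)}
        counts = np.zeros(space.n_binding_states)
        for a, b, c in zip(n_dual, n_ca, n_pip):
            counts[idx[(a, b, c)]] += 1
        expected = phi.binding_phi * n
        keep = expected > 5
        stat, pval = chisquare(counts[keep],
                               expected[keep] * counts[keep].sum()
                               / expected[keep].sum())
        assert pval > 0.001

    def test_column_fill_order(self, params3):
        """Duals first, then Ca2+-only, then PI(4,5)P2-only."""
        phi = steady_state(params3)
        phi.phi[:] = 0.0
        # force the state (1, 2, 1)
        j = [tuple(t) for t in phi.space.triplets].index((1, 2, 1))
        phi.phi[j] = 1.0
        codes = init_from_steady_state(phi, 3, rng=0)
        expect = [gk.DUAL, gk.CA_ONLY, gk.CA_ONLY, gk.PIP2_ONLY] + [
            gk.UNBOUND] * 11
        for col in codes.T:
            assert list(col) == expect


class TestRuns:
    def test_reproducible_with_seed(self, params3):
        a = run(params3, 100, 50.0, t_end=0.02, seed=5)
        b = run(params3, 100, 50.0, t_end=0.02, seed=5)
        np.testing.assert_array_equal(a.fusion_times, b.fusion_times)

    def test_matches_analytic_cdf(self, params3):
        """Primary oracle: at constant Ca2+ the empirical fusion-time CDF
        agrees with the closed-form G (Kolmogorov-Smirnov)."""
        res = run(params3, 4000, 50.0, t_end=0.1, seed=11)
        assert res.fused.all()
        tc = time_course(params3, 50.0)
        stat, pval = kstest(res.fusion_times,
                            lambda x: np.interp(x, tc.t, tc.G))
        assert pval > 0.01

    def test_resting_stimulus_produces_no_fusion(self, params3):
        res = run(params3, 500, params3.ca_rest, t_end=6e-3, seed=3)
        assert res.fused.sum() == 0

    def test_constant_trace_equivalent_to_scalar(self, params3):
        """The 0.8 ms refresh cap used for traces is statistically
        transparent: a constant trace gives the same fusion-time
        distribution as the scalar fast path."""
        trace = StimulusTrace.constant(50.0, 0.02)
        a = run(params3, 1500, trace, t_end=0.02, seed=21)
        b = run(params3, 1500, 50.0, t_end=0.02, seed=22)
        stat, pval = ks_2samp(a.fusion_times[a.fused], b.fusion_times[b.fused])
        assert pval > 0.01

    def test_short_stimulus_rejected(self, params3):
        trace = StimulusTrace.constant(50.0, 0.005)
        with pytest.raises(ValueError):
            run(params3, 10, StimulusTrace(trace.t, trace.conc), pip2=None,
                t_end=0.02, seed=0)

    def test_slot_constraint_never_violated(self, params3):
        """No trajectory may engage more than M_slots syts on the
        membrane at once; spot-check terminal states of unfused runs."""
        res = run(params3, 300, 2.0, t_end=5e-3, seed=9,
                  census_times=np.linspace(0, 5e-3, 6))
        assert res.census_counts.shape[1] == params3.M_slots + 1
        # census rows count every unfused vesicle exactly once
        totals = res.census_counts.sum(axis=1) + 0  # duals <= M_slots by shape
        assert (totals <= 300).all()

    def test_dual_census_mode_at_fusion(self, params3):
        """At 50 uM most fusions happen out of the fully engaged
        (three-dual) configuration."""
        res = run(params3, 2000, 50.0, t_end=0.05, seed=13)
        hist = np.bincount(res.dual_at_fusion[res.fused], minlength=4)
        assert hist.argmax() == 3

    def test_no_allostericity_rarely_multiple_duals(self, params3):
        """With A=1 dual bindings collapse almost instantly, vesicles
        almost never hold more than one, and fusion is rare."""
        p = params3.replace(A=1.0)
        res = run(p, 500, 50.0, t_end=6e-3, seed=17,
                  census_times=np.array([1e-3, 3e-3, 5e-3]))
        multi = res.census_counts[:, 2:].sum()
        total = res.census_counts.sum()
        assert multi / total < 0.02
        assert res.fused.mean() < 0.05

    def test_episode_lifetimes_shorter_without_allostericity(self, params3):
        res_a = run(params3, 200, 50.0, t_end=0.01, seed=31,
                    record_episodes=True)
        res_b = run(params3.replace(A=1.0), 200, 50.0, t_end=0.01, seed=32,
                    record_episodes=True)
        assert np.mean(res_a.episode_durations) > 100 * np.mean(
            res_b.episode_durations)


class TestHeterozygous:
    def _joint_oracle(self, classes, params, ca, pip2):
        """Null-space oracle on the explicitly assembled joint generator."""
        states, probs = heterozygous_steady_state(classes, params, ca, pip2)
        idx = {s: i for i, s in enumerate(states)}
        n = len(states)
        Q = np.zeros((n, n))
        M = params.M_slots
        cac = ca**params.ca_exponent
        for s, i in idx.items():
            used = sum(nn + kk for (nn, mm, kk) in s)
            for ci, ((nn, mm, kk), (cls, copies)) in enumerate(zip(s, classes)):
                free = copies - nn - mm - kk
                slots = M - used

                def bump(ds, rate):
                    t = list(s)
                    t[ci] = (nn + ds[0], mm + ds[1], kk + ds[2])
                    Q[i, idx[tuple(t)]] += rate

                if free > 0 and slots > 0:
                    bump((0, 0, 1), free * slots * pip2 * cls.gamma)
                if kk > 0:
                    bump((0, 0, -1), kk * cls.delta)
                if free > 0 and cls.alpha > 0:
                    bump((0, 1, 0), free * cac * cls.alpha)
                if mm > 0:
                    bump((0, -1, 0), mm * cls.beta)
                if mm > 0 and slots > 0:
                    bump((1, -1, 0), mm * slots * pip2 * cls.gamma)
                if nn > 0:
                    bump((-1, 1, 0), cls.A * nn * cls.delta)
                if kk > 0 and cls.alpha > 0:
                    bump((1, 0, -1), kk * cac * cls.alpha)
                if nn > 0:
                    bump((-1, 0, 1), cls.A * nn * cls.beta)
            Q[i, i] -= Q[i].sum()
        w, v = np.linalg.eig(Q.T)
        vec = np.real(v[:, np.argmin(np.abs(w))])
        vec /= vec.sum()
        return states, probs, vec

    def test_joint_steady_state_matches_nullspace(self, params3):
        p = params3.replace(n_syts=4)
        classes = [(wild_type_class(p), 2), (ca_affinity_mutant(p), 2)]
        states, probs, oracle = self._joint_oracle(
            classes, p, ca=0.5, pip2=p.pip2)
        np.testing.assert_allclose(probs, oracle, atol=1e-10)

    def test_identical_classes_reduce_to_homozygous(self, params3):
        """Splitting the wild-type syts into two identical 'classes' must
        not change the fusion-time distribution."""
        wt = wild_type_class(params3)
        het = run_heterozygous(params3, [(wt, 8), (wt, 7)], 1500, 50.0,
                               t_end=0.02, seed=41)
        hom = run(params3, 1500, 50.0, t_end=0.02, seed=42)
        stat, pval = ks_2samp(het.fusion_times[het.fused],
                              hom.fusion_times[hom.fused])
        assert pval > 0.01

    def test_slot_blocking_mutant_suppresses_fusion(self, params3):
        """'No Ca2+ binding, A-on' mutants hog the PI(4,5)P2 slots and
        suppress fusion relative to pure wild type; the 'A-off' variant
        (normal PI(4,5)P2 affinity) is much milder."""
        wt = wild_type_class(params3)
        t_end = 6e-3
        hom = run(params3, 400, 50.0, t_end=t_end, seed=51)
        aon = run_heterozygous(
            params3, [(wt, 8), (no_ca_binding_mutant(params3, True), 7)],
            400, 50.0, t_end=t_end, seed=52)
        aoff = run_heterozygous(
            params3, [(wt, 8), (no_ca_binding_mutant(params3, False), 7)],
            400, 50.0, t_end=t_end, seed=53)
        assert aon.fused.mean() < 0.5 * hom.fused.mean()
        assert aoff.fused.mean() > aon.fused.mean()
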