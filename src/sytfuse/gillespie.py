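"""Exact stochastic simulation of individual syts (Gillespie algorithm).

Unlike the analytic engine, which tracks the aggregated vesicle state,
this engine tracks every syt of every vesicle with a per-syt binding code,
which allows time-varying Ca2+ / PI(4,5)P2 stimuli, mixtures of wild-type
and mutant syts on the same vesicle, and variable syt copy numbers.  The
event loop is compiled with numba; vesicles are independent, so large
pools are simulated in chunks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from . import _gillespie_kernel as _gk
from .model import ModelParameters
from .steady_state import SteadyStateDistribution, steady_state
from .synthetic import StimulusTrace

__all__ = [
    "SytClass",
    "wild_type_class",
    "ca_affinity_mutant",
    "no_ca_binding_mutant",
    "GillespieResult",
    "init_from_steady_state",
    "heterozygous_steady_state",
    "run",
    "run_heterozygous",
    "run_variable_copies",
    "dual_binding_census",
]

#: maximum waiting time between stimulus/propensity refreshes (s)
CAP_DT = 8e-4


@dataclass(frozen=True)
class SytClass:
    """Kinetic parameters of one syt species (wild type or a mutant)."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    A: float
    label: str = "WT"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def wild_type_class(params: ModelParameters) -> SytClass:
    return SytClass(alpha=params.alpha, beta=params.beta, gamma=params.gamma,
                    delta=params.delta, A=params.A, label="WT")


def ca_affinity_mutant(params: ModelParameters, kd_factor: float = 10.0) -> SytClass:
    """Reduced Ca2+ affinity: the dissociation rate scaled by ``kd_factor``."""
    return replace(wild_type_class(params), beta=params.beta * kd_factor,
                   label=f"KD_Ca x{kd_factor:g}")


def no_ca_binding_mutant(params: ModelParameters, allosteric_on: bool = True) -> SytClass:
    """Mutant unable to bind Ca2+.

    With ``allosteric_on`` the PI(4,5)P2 affinity permanently mimics the
    Ca2+-bound (allosterically stabilised) state, i.e. the PI(4,5)P2
    dissociation rate is ``A * delta``; otherwise PI(4,5)P2 binding is
    normal.  Either way the mutant never reaches a dual binding, so it
    contributes nothing to fusion and only competes for slots.
    """
    delta = params.A * params.delta if allosteric_on else params.delta
    label = "noCa-Aon" if allosteric_on else "noCa-Aoff"
    return replace(wild_type_class(params), alpha=0.0, beta=0.0,
                   delta=delta, label=label)


@dataclass
class GillespieResult:
    """Outcome of one stochastic run (possibly assembled from chunks)."""

    fusion_times: np.ndarray        # s, inf where unfused
    dual_at_fusion: np.ndarray      # -1 where unfused
    census_times: np.ndarray | None = None
    census_counts: np.ndarray | None = None   # (n_times, M_slots+1)
    episode_durations: np.ndarray | None = None  # s, completed episodes
    t_end: float = 0.0

    @property
    def fused(self) -> np.ndarray:
        return np.isfinite(self.fusion_times)

    def merged(self, other: "GillespieResult") -> "GillespieResult":
        return GillespieResult(
            fusion_times=np.concatenate([self.fusion_times, other.fusion_times]),
            dual_at_fusion=np.concatenate([self.dual_at_fusion, other.dual_at_fusion]),
            census_times=self.census_times,
            census_counts=(
                None if self.census_counts is None
                else self.census_counts + other.census_counts
            ),
            episode_durations=(
                None if self.episode_durations is None
                else np.concatenate([self.episode_durations, other.episode_durations])
            ),
            t_end=self.t_end,
        )


def _fill_column(codes: np.ndarray, j: int, offset: int, n: int, m: int, k: int,
                 n_syts: int) -> None:
    """Write a (n, m, k) triplet into rows [offset, offset+n_syts) of
    column j: first the duals, then Ca2+-only, then PI(4,5)P2-only."""
    row = offset
    for code, count in ((_gk.DUAL, n), (_gk.CA_ONLY, m), (_gk.PIP2_ONLY, k),
                        (_gk.UNBOUND, n_syts - n - m - k)):
        codes[row : row + count, j] = code
        row += count


def init_from_steady_state(
    phi: SteadyStateDistribution,
    n_ves: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-syt code matrix sampled from the aggregated steady state.

    Each vesicle draws an aggregated state by the inverse-CDF rule
    (smallest index whose cumulative probability reaches the uniform draw)
    and its syts are filled systematically: duals first, then Ca2+-only,
    then PI(4,5)P2-only, the rest unbound.
    """
    if abs(phi.phi.sum() - 1.0) > 1e-8:
        raise ValueError("steady state is not normalised")
    rng = np.random.default_rng(rng)
    space = phi.space
    n_syts = space.n_syts
    cdf = np.cumsum(phi.binding_phi)
    draws = np.searchsorted(cdf, rng.random(n_ves), side="left")
    codes = np.empty((n_syts, n_ves), dtype=np.int8)
    for j, s in enumerate(draws):
        n, m, k = space.triplets[s]
        _fill_column(codes, j, 0, n, m, k, n_syts)
    return codes


def heterozygous_steady_state(
    classes: list[tuple[SytClass, int]],
    params: ModelParameters,
    ca: float | None = None,
    pip2: float | None = None,
):
    """Joint fusion-free equilibrium of a vesicle carrying several syt
    classes sharing the PI(4,5)P2 slots.

    States are tuples of per-class triplets ``((n1,m1,k1), (n2,m2,k2), ...)``
    with ``n_c+m_c+k_c <= copies_c`` and ``sum_c (n_c+k_c) <= M_slots``.
    By detailed balance the equilibrium weight factorises into per-class
    binding weights times a falling-factorial slot-availability factor
    shared across classes (each PI(4,5)P2 association consumed one of the
    then-free slots).  Returns (state list, probability array).
    """
    if ca is None:
        ca = params.ca_rest
    if pip2 is None:
        pip2 = params.pip2
    M = params.M_slots
    cac = ca**params.ca_exponent

    per_class = []
    for cls, copies in classes:
        cbar = cac * cls.alpha / cls.beta if cls.beta > 0 else 0.0
        if cls.alpha == 0.0:
            cbar = 0.0
        pbar = pip2 * cls.gamma / cls.delta if cls.delta > 0 else 0.0
        dbar = cbar * pbar / cls.A if cls.A > 0 else 0.0
        triplets = [
            (n, m, k)
            for n in range(min(copies, M) + 1)
            for m in range(copies - n + 1)
            for k in range(min(copies - n - m, M - n) + 1)
        ]
        per_class.append((copies, cbar, pbar, dbar, triplets))

    states, weights = [], []
    for combo in itertools.product(*(pc[4] for pc in per_class)):
        used = sum(n + k for (n, m, k) in combo)
        if used > M:
            continue
        w = 1.0
        for (copies, cbar, pbar, dbar, _), (n, m, k) in zip(per_class, combo):
            w *= (
                math.comb(copies, n) * math.comb(copies - n, m)
                * math.comb(copies - n - m, k)
                * (dbar**n if n else 1.0)
                * (cbar**m if m else 1.0)
                * (pbar**k if k else 1.0)
            )
        # slot-availability factor M (M-1) ... (M-used+1)
        for i in range(used):
            w *= M - i
        states.append(combo)
        weights.append(w)
    p = np.asarray(weights)
    return states, p / p.sum()


def _effective_chunk(ca, pip2, chunk_size: int) -> int:
    """With a time-varying stimulus every event refreshes all vesicle
    propensities, so per-chunk work grows quadratically in chunk size;
    batches of 100 independent vesicles keep it linear overall."""
    if isinstance(ca, StimulusTrace) or isinstance(pip2, StimulusTrace):
        return min(chunk_size, 100)
    return chunk_size


def _as_traces(ca, pip2, params: ModelParameters, t_end: float):
    if isinstance(ca, (int, float)):
        ca = StimulusTrace.constant(float(ca), t_end)
        ca_varying = False
    else:
        ca_varying = True
    if pip2 is None:
        pip2 = params.pip2
    if isinstance(pip2, (int, float)):
        pip2 = StimulusTrace.constant(float(pip2), t_end)
        pip2_varying = False
    else:
        pip2_varying = True
    return ca, pip2, (ca_varying or pip2_varying)


def _run_codes(
    codes: np.ndarray,
    cls_row: np.ndarray,
    classes: list[SytClass],
    params: ModelParameters,
    ca,
    pip2,
    t_end: float,
    seed: int,
    census_times: np.ndarray | None,
    record_episodes: bool,
    max_episodes: int = 1_000_000,
) -> GillespieResult:
    ca_tr, pip2_tr, varying = _as_traces(ca, pip2, params, t_end)
    if varying and min(ca_tr.t_end, pip2_tr.t_end) < t_end - 1e-12:
        raise ValueError("stimulus trace shorter than the requested horizon")
    n_ves = codes.shape[1]
    fusion_times = np.full(n_ves, np.inf)
    dual_at_fusion = np.full(n_ves, -1, dtype=np.int64)
    ct = census_times if census_times is not None else np.empty(0)
    census = np.zeros((len(ct), params.M_slots + 1), dtype=np.int64)
    episodes = np.empty(max_episodes if record_episodes else 0)

    n_epi = _gk.gillespie_run(
        codes, cls_row,
        np.array([c.alpha for c in classes]),
        np.array([c.beta for c in classes]),
        np.array([c.gamma for c in classes]),
        np.array([c.delta for c in classes]),
        np.array([c.A for c in classes]),
        ca_tr.t, ca_tr.conc, pip2_tr.t, pip2_tr.conc, varying,
        params.M_slots, params.L_plus, params.f, params.ca_exponent,
        t_end, CAP_DT, seed,
        ct, census,
        record_episodes, episodes,
        fusion_times, dual_at_fusion,
    )
    return GillespieResult(
        fusion_times=fusion_times,
        dual_at_fusion=dual_at_fusion,
        census_times=census_times,
        census_counts=census if census_times is not None else None,
        episode_durations=episodes[:n_epi] if record_episodes else None,
        t_end=t_end,
    )


def run(
    params: ModelParameters,
    n_ves: int,
    ca,
    pip2=None,
    t_end: float | None = None,
    seed: int | None = None,
    census_times: np.ndarray | None = None,
    record_episodes: bool = False,
    chunk_size: int = 256,
) -> GillespieResult:
    """Simulate ``n_ves`` homozygous vesicles under a Ca2+ stimulus.

    ``ca`` (and optionally ``pip2``) may be a scalar (constant stimulus) or
    a :class:`StimulusTrace`.  The initial per-syt states are drawn from
    the fusion-free steady state at resting conditions (at the stimulus
    concentration itself when it lies below rest).  Vesicles are
    independent and are simulated in chunks.
    """
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = ca.t_end if isinstance(ca, StimulusTrace) else 0.1
    ca0 = ca(0.0) if isinstance(ca, StimulusTrace) else min(ca, params.ca_rest)
    pip2_0 = pip2(0.0) if isinstance(pip2, StimulusTrace) else pip2
    phi = steady_state(params, ca=min(float(ca0), params.ca_rest), pip2=pip2_0)
    wt = wild_type_class(params)
    cls_row = np.zeros(params.n_syts, dtype=np.int8)

    chunk_size = _effective_chunk(ca, pip2, chunk_size)
    result = None
    for start in range(0, n_ves, chunk_size):
        nv = min(chunk_size, n_ves - start)
        codes = init_from_steady_state(phi, nv, rng)
        sub = _run_codes(codes, cls_row, [wt], params, ca, pip2, t_end,
                         int(rng.integers(2**31 - 1)), census_times,
                         record_episodes)
        result = sub if result is None else result.merged(sub)
    return result


def run_heterozygous(
    params: ModelParameters,
    classes: list[tuple[SytClass, int]],
    n_ves: int,
    ca,
    pip2=None,
    t_end: float | None = None,
    seed: int | None = None,
    census_times: np.ndarray | None = None,
    chunk_size: int = 256,
) -> GillespieResult:
    """Simulate vesicles carrying a mixture of syt classes.

    ``classes`` lists (class, copies) pairs; the first class occupies the
    first rows of the state matrix, the second the following rows, and so
    on.  Initial conditions are drawn from the joint steady state over the
    per-class triplets with shared slots.
    """
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = ca.t_end if isinstance(ca, StimulusTrace) else 0.1
    ca0 = float(ca(0.0)) if isinstance(ca, StimulusTrace) else float(ca)
    pip2_0 = float(pip2(0.0)) if isinstance(pip2, StimulusTrace) else pip2
    states, probs = heterozygous_steady_state(
        classes, params, ca=min(ca0, params.ca_rest), pip2=pip2_0)
    cdf = np.cumsum(probs)
    copies = [c for _, c in classes]
    n_rows = sum(copies)
    cls_row = np.concatenate([
        np.full(c, ci, dtype=np.int8) for ci, c in enumerate(copies)
    ])
    cls_objs = [cls for cls, _ in classes]

    chunk_size = _effective_chunk(ca, pip2, chunk_size)
    result = None
    for start in range(0, n_ves, chunk_size):
        nv = min(chunk_size, n_ves - start)
        codes = np.empty((n_rows, nv), dtype=np.int8)
        draws = np.searchsorted(cdf, rng.random(nv), side="left")
        for j, s in enumerate(draws):
            offset = 0
            for (n, m, k), c in zip(states[s], copies):
                _fill_column(codes, j, offset, n, m, k, c)
                offset += c
        sub = _run_codes(codes, cls_row, cls_objs, params, ca, pip2, t_end,
                         int(rng.integers(2**31 - 1)), census_times, False)
        result = sub if result is None else result.merged(sub)
    return result


def run_variable_copies(
    params: ModelParameters,
    n_ves: int,
    ca,
    pip2=None,
    t_end: float | None = None,
    seed: int | None = None,
    mean_copies: float = 15.0,
    census_times: np.ndarray | None = None,
    chunk_size: int = 256,
) -> GillespieResult:
    """Simulate vesicles whose syt copy number is Poisson distributed.

    Copy numbers are drawn from Poisson(``mean_copies``) with zero draws
    replaced by one; each vesicle's initial state is drawn from the steady
    state computed for its own copy number.
    """
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = ca.t_end if isinstance(ca, StimulusTrace) else 0.1
    ca0 = float(ca(0.0)) if isinstance(ca, StimulusTrace) else float(ca)
    pip2_0 = float(pip2(0.0)) if isinstance(pip2, StimulusTrace) else pip2
    ca_ss = min(ca0, params.ca_rest)
    wt = wild_type_class(params)

    copies_all = rng.poisson(mean_copies, size=n_ves)
    copies_all[copies_all == 0] = 1
    n_rows = int(copies_all.max())
    phis: dict[int, SteadyStateDistribution] = {}

    chunk_size = _effective_chunk(ca, pip2, chunk_size)
    result = None
    for start in range(0, n_ves, chunk_size):
        nv = min(chunk_size, n_ves - start)
        codes = np.full((n_rows, nv), _gk.ABSENT, dtype=np.int8)
        for j in range(nv):
            nc = int(copies_all[start + j])
            if nc not in phis:
                phis[nc] = steady_state(params.replace(n_syts=nc),
                                        ca=ca_ss, pip2=pip2_0)
            phi = phis[nc]
            s = int(np.searchsorted(np.cumsum(phi.binding_phi), rng.random(),
                                    side="left"))
            n, m, k = phi.space.triplets[s]
            _fill_column(codes, j, 0, n, m, k, nc)
        cls_row = np.zeros(n_rows, dtype=np.int8)
        sub = _run_codes(codes, cls_row, [wt], params, ca, pip2, t_end,
                         int(rng.integers(2**31 - 1)), census_times, False)
        result = sub if result is None else result.merged(sub)
    return result


def dual_binding_census(result: GillespieResult) -> dict:
    """Summaries of dual-binding engagement from a recorded run:
    the histogram of dual bindings at the moment of fusion, the per-time
    counts of unfused vesicles holding 0..M_slots dual bindings, and the
    completed dual-binding episode lifetimes (s)."""
    fused = result.fused
    counts = np.bincount(result.dual_at_fusion[fused],
                         minlength=(0 if result.census_counts is None
                                    else result.census_counts.shape[1]))
    return {
        "dual_at_fusion_hist": counts,
        "census_times": result.census_times,
        "census_counts": result.census_counts,
        "episode_durations": result.episode_durations,
    }
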