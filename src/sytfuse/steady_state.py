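"""Pre-stimulus equilibrium of the binding chain and RRP-size statistics.

Before a stimulus the vesicle sits at resting Ca2+ (0.05 uM) and the very
low basal fusion rate is neglected, so the binding chain is a closed,
reversible Markov chain.  Microscopic reversibility then gives the
equilibrium by detailed balance: walking the lexicographically ordered
states, each state's weight is obtained from an already-visited neighbour
via the ratio of forward to backward reaction rates.  The ``n``-increment
step uses the two-reaction path ``(n-1,0,0) -> (n-1,1,0) -> (n,0,0)``
(bind Ca2+, then convert to a dual binding), since those two states are not
connected by a single reaction; path independence is guaranteed by the
Kolmogorov cycle criterion and checked against a null-space solve in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    InvalidParameterError,
    ModelParameters,
    StateSpace,
    enumerate_states,
)

__all__ = [
    "SteadyStateDistribution",
    "steady_state",
    "occupancy_summary",
    "RRPDistribution",
    "sample_rrp_sizes",
]

#: release latency = time of the k-th fusion; undefined for pools below this
MIN_POOL_FOR_LATENCY = 5


class DegenerateParameterError(InvalidParameterError):
    """A zero backward rate makes the detailed-balance recursion singular."""


@dataclass
class SteadyStateDistribution:
    """Probability vector over the full state space (fused mass is zero)."""

    phi: np.ndarray
    space: StateSpace
    ca: float
    pip2: float

    @property
    def binding_phi(self) -> np.ndarray:
        """Probabilities of the binding states only (fused slot dropped)."""
        return self.phi[:-1]

    def to_frame(self):
        """Steady state as a table of (n, m, k, probability)."""
        import pandas as pd

        t = self.space.triplets
        return pd.DataFrame(
            {"n": t[:, 0], "m": t[:, 1], "k": t[:, 2], "probability": self.phi[:-1]}
        )


def steady_state(
    params: ModelParameters,
    ca: float | None = None,
    pip2: float | None = None,
    space: StateSpace | None = None,
) -> SteadyStateDistribution:
    """Fusion-free equilibrium distribution at the given concentrations.

    ``ca`` defaults to the resting concentration; callers simulating a
    stimulus below rest should pass that sub-resting concentration directly.
    States unreachable because a ligand concentration is zero receive zero
    probability.
    """
    if ca is None:
        ca = params.ca_rest
    if pip2 is None:
        pip2 = params.pip2
    if ca < 0 or pip2 < 0:
        raise InvalidParameterError("concentrations must be nonnegative")
    if space is None:
        space = enumerate_states(params.n_syts, params.M_slots)
    N, M = params.n_syts, params.M_slots
    cac = ca**params.ca_exponent
    al, be, ga, de, A = params.alpha, params.beta, params.gamma, params.delta, params.A

    weights: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
    for n, m, k in map(tuple, space.triplets[1:]):
        if k > 0:
            prev = (n, m, k - 1)
            fwd = (N - n - m - (k - 1)) * (M - n - (k - 1)) * pip2 * ga
            bwd = k * de
        elif m > 0:
            prev = (n, m - 1, 0)
            fwd = (N - n - (m - 1)) * cac * al
            bwd = m * be
        else:  # n > 0, m == k == 0: two-step path via (n-1, 1, 0)
            prev = (n - 1, 0, 0)
            fwd = (N - n + 1) * cac * al * (M - n + 1) * pip2 * ga
            bwd = be * A * n * de
        if weights[prev] == 0.0 or fwd == 0.0:
            weights[(n, m, k)] = 0.0
        elif bwd == 0.0:
            raise DegenerateParameterError(
                f"zero backward rate into state {(n, m, k)}"
            )
        else:
            weights[(n, m, k)] = weights[prev] * fwd / bwd

    phi = np.zeros(len(space))
    phi[:-1] = [weights[tuple(t)] for t in space.triplets]
    phi /= phi.sum()
    return SteadyStateDistribution(phi=phi, space=space, ca=ca, pip2=pip2)


def occupancy_summary(dist: SteadyStateDistribution) -> dict:
    """Marginal occupancies of the steady state.

    Returns the marginal distributions of the dual (``n``), Ca2+-only
    (``m``) and PI(4,5)P2-only (``k``) counts, and the probability that at
    least one syt engages PI(4,5)P2 (``n + k >= 1``).
    """
    t = dist.space.triplets
    p = dist.binding_phi
    out = {}
    for name, col in (("n", 0), ("m", 1), ("k", 2)):
        marg = np.bincount(t[:, col], weights=p)
        out[f"{name}_marginal"] = marg / marg.sum()
    out["p_any_pip2"] = float(p[(t[:, 0] + t[:, 2]) >= 1].sum())
    return out


@dataclass(frozen=True)
class RRPDistribution:
    """Gamma-distributed readily releasable pool size, rounded to integers."""

    mean: float = 4000.0
    sd: float = 2000.0

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean


def sample_rrp_sizes(
    dist: RRPDistribution,
    count: int,
    rng: np.random.Generator | int | None = None,
    min_size: int | None = None,
) -> np.ndarray:
    """Draw ``count`` integer pool sizes; optionally redraw sizes below
    ``min_size`` (used where the latency, the 5th fusion, must exist)."""
    rng = np.random.default_rng(rng)
    sizes = np.rint(rng.gamma(dist.shape, dist.scale, size=count)).astype(np.int64)
    if min_size is not None:
        for _ in range(1000):
            bad = sizes < min_size
            if not bad.any():
                break
            sizes[bad] = np.rint(
                rng.gamma(dist.shape, dist.scale, size=int(bad.sum()))
            ).astype(np.int64)
    return sizes
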