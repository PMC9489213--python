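"""Aggregated Markov model of synaptotagmin (syt) triggered vesicle fusion.

A readily releasable vesicle carries ``n_syts`` copies of the Ca2+ sensor
synaptotagmin.  Each C2B domain can bind two Ca2+ ions, one PI(4,5)P2
molecule, or both ("dual binding"); at most ``M_slots`` syts per vesicle can
engage PI(4,5)P2 simultaneously (slot limitation).  Because syts are
interchangeable, a vesicle is fully described by the triplet ``(n, m, k)``:

* ``n`` -- number of dual-bound syts,
* ``m`` -- number of syts with only Ca2+ bound,
* ``k`` -- number of syts with only PI(4,5)P2 bound,

subject to ``n + m + k <= n_syts`` and ``n + k <= M_slots``, plus one
absorbing fused state.  Dual binding is allosterically stabilised: both
dissociation rates out of the dual-bound configuration are multiplied by the
factor ``A < 1`` (microscopic reversibility requires the factor on both
legs).  Each dual binding multiplies the basal fusion rate ``L_plus`` by
``f``, i.e. lowers the fusion barrier by ``ln f`` (in units of kBT).

Units are seconds and micromolar throughout; only the added latency delay
``d`` is kept in milliseconds because it is a pure output-side shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "BindingState",
    "StateSpace",
    "enumerate_states",
    "reaction_rates",
    "fusion_rate",
    "IntensityMatrix",
    "build_intensity_matrix",
    "BEST_FIT",
    "best_fit_parameters",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its admissibility constraints."""


class InvalidStateError(ValueError):
    """A binding state violates the copy-number or slot constraints."""


# Fixed constants (in-vitro affinities and literature values) and the best-fit
# free parameters (alpha, gamma, pip2, f, d) for each slot count M_slots=1..6.
_FIXED = dict(
    KD_Ca=221.0**2,     # uM^2, dissociation constant for the 2-Ca2+ step
    KD_PIP2=20.0,       # uM
    A=0.00022,          # allosteric factor = (3.3/221)^2
    L_plus=4.23e-4,     # s^-1, basal fusion rate
    n_syts=15,
    ca_rest=0.05,       # uM
    ca_exponent=2,
)

BEST_FIT: dict[int, dict[str, float]] = {
    1: dict(alpha=0.03712, gamma=1.425e5, pip2=0.009658, f=4.259e6, d=0.3211),
    2: dict(alpha=34.99, gamma=572.6, pip2=0.2523, f=1298.0, d=0.3761),
    3: dict(alpha=24.70, gamma=124.7, pip2=1.109, f=128.2, d=0.3803),
    4: dict(alpha=25.08, gamma=121.3, pip2=0.4528, f=152.1, d=0.3866),
    5: dict(alpha=24.51, gamma=124.31, pip2=0.3048, f=159.6, d=0.3876),
    6: dict(alpha=24.11, gamma=126.6, pip2=0.2320, f=163.5, d=0.3881),
}


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, affinities and copy numbers of the model.

    Parameters
    ----------
    alpha : float
        Ca2+ association rate constant (uM^-c s^-1 with c = ``ca_exponent``).
    gamma : float
        PI(4,5)P2 association rate constant (uM^-1 s^-1).
    pip2 : float
        Effective PI(4,5)P2 concentration experienced by the syts (uM).
    f : float
        Fusion-rate factor per dual binding (dimensionless, >= 1).
    d : float
        Added latency delay in milliseconds (output-side shift).
    KD_Ca, KD_PIP2 : float
        Dissociation constants; the dissociation rate constants are derived
        as ``beta = KD_Ca * alpha`` and ``delta = KD_PIP2 * gamma``.
    A : float
        Allosteric factor in (0, 1] applied to both dissociation rates out
        of the dual-bound state.
    L_plus : float
        Basal fusion rate (s^-1) of a vesicle with no dual bindings.
    n_syts, M_slots : int
        Syt copies per vesicle and PI(4,5)P2 binding slots.
    ca_rest : float
        Resting Ca2+ concentration (uM).
    ca_exponent : int
        Ca2+ stoichiometry per C2B domain (2 for the standard model).
    """

    alpha: float
    gamma: float
    pip2: float
    f: float
    d: float = 0.0
    KD_Ca: float = _FIXED["KD_Ca"]
    KD_PIP2: float = _FIXED["KD_PIP2"]
    A: float = _FIXED["A"]
    L_plus: float = _FIXED["L_plus"]
    n_syts: int = _FIXED["n_syts"]
    M_slots: int = 3
    ca_rest: float = _FIXED["ca_rest"]
    ca_exponent: int = _FIXED["ca_exponent"]

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "pip2", "KD_Ca", "KD_PIP2",
                     "L_plus", "ca_rest"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        if not (0.0 < self.A <= 1.0):
            raise InvalidParameterError("allosteric factor A must be in (0, 1]")
        if self.f < 1.0:
            raise InvalidParameterError("fusion factor f must be >= 1")
        if self.n_syts < 1 or self.M_slots < 1:
            raise InvalidParameterError("n_syts and M_slots must be >= 1")
        if self.ca_exponent < 1:
            raise InvalidParameterError("ca_exponent must be a positive integer")

    @property
    def beta(self) -> float:
        """Ca2+ dissociation rate constant (s^-1), ``KD_Ca * alpha``."""
        return self.KD_Ca * self.alpha

    @property
    def delta(self) -> float:
        """PI(4,5)P2 dissociation rate constant (s^-1), ``KD_PIP2 * gamma``."""
        return self.KD_PIP2 * self.gamma

    @property
    def energy_barrier_reduction(self) -> float:
        """Fusion-barrier reduction per dual binding, ``ln f`` (kBT)."""
        return math.log(self.f)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    # -- config I/O ---------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelParameters":
        names = set(cls.__dataclass_fields__)
        unknown = set(cfg) - names
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


def best_fit_parameters(M_slots: int = 3, **overrides) -> ModelParameters:
    """Best-fit parameter set for a given slot count (M_slots in 1..6)."""
    if M_slots not in BEST_FIT:
        raise InvalidParameterError(f"no best fit tabulated for M_slots={M_slots}")
    return ModelParameters(M_slots=M_slots, **BEST_FIT[M_slots]).replace(**overrides)


@dataclass(frozen=True, order=True)
class BindingState:
    """Vesicle binding state ``(n, m, k)`` or the absorbing fused state."""

    n: int = 0
    m: int = 0
    k: int = 0
    fused: bool = False

    def __post_init__(self) -> None:
        if not self.fused and (self.n < 0 or self.m < 0 or self.k < 0):
            raise InvalidStateError("binding counts must be nonnegative")

    @property
    def triplet(self) -> tuple[int, int, int]:
        return (self.n, self.m, self.k)

    def admissible(self, n_syts: int, M_slots: int) -> bool:
        if self.fused:
            return True
        return (self.n + self.m + self.k <= n_syts
                and self.n + self.k <= M_slots)


FUSED = BindingState(0, 0, 0, fused=True)


class StateSpace:
    """Ordered enumeration of the vesicle states.

    The binding states come first, in lexicographic order of ``(n, m, k)``,
    and the absorbing fused state occupies the last index.
    """

    def __init__(self, n_syts: int, M_slots: int):
        if n_syts < 1 or M_slots < 1:
            raise InvalidParameterError("n_syts and M_slots must be >= 1")
        self.n_syts = n_syts
        self.M_slots = M_slots
        triplets = [
            (n, m, k)
            for n in range(M_slots + 1)
            for m in range(n_syts - n + 1)
            for k in range(min(n_syts - n - m, M_slots - n) + 1)
        ]
        triplets.sort()
        self.states: tuple[BindingState, ...] = tuple(
            [BindingState(*t) for t in triplets] + [FUSED]
        )
        self._index = {s: i for i, s in enumerate(self.states)}
        self.triplets = np.asarray(triplets, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[BindingState]:
        return iter(self.states)

    @property
    def n_binding_states(self) -> int:
        return len(self.states) - 1

    @property
    def fused_index(self) -> int:
        return len(self.states) - 1

    def index(self, state: BindingState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise InvalidStateError(f"state {state} not in space "
                                    f"({self.n_syts} syts, {self.M_slots} slots)")

    def state(self, i: int) -> BindingState:
        return self.states[i]


def enumerate_states(n_syts: int, M_slots: int) -> StateSpace:
    """Enumerate all admissible ``(n, m, k)`` triplets plus the fused state."""
    return StateSpace(n_syts, M_slots)


def fusion_rate(n_dual: int, params: ModelParameters) -> float:
    """Vesicle fusion rate ``L_plus * f**n_dual`` (s^-1)."""
    if n_dual < 0:
        raise InvalidStateError("number of dual bindings must be nonnegative")
    return params.L_plus * params.f**n_dual


def reaction_rates(
    state: BindingState,
    params: ModelParameters,
    ca: float,
    pip2: float | None = None,
    include_fusion: bool = True,
) -> list[tuple[BindingState, float]]:
    """All reactions leaving ``state`` with their rates (s^-1).

    The nine possible reactions (eight ligand (un)binding steps plus fusion)
    are returned only when their admissibility condition holds; a reaction
    with zero ligand concentration is still listed with rate 0 as long as its
    condition on the state holds.
    """
    if state.fused:
        return []
    N, M = params.n_syts, params.M_slots
    if not state.admissible(N, M):
        raise InvalidStateError(f"state {state} inadmissible for "
                                f"n_syts={N}, M_slots={M}")
    if ca < 0 or (pip2 is not None and pip2 < 0):
        raise InvalidParameterError("ligand concentrations must be nonnegative")
    if pip2 is None:
        pip2 = params.pip2
    n, m, k = state.triplet
    free = N - n - m - k          # syts with nothing bound
    slots = M - n - k             # free PI(4,5)P2 slots
    cac = ca**params.ca_exponent
    out: list[tuple[BindingState, float]] = []
    if free > 0 and slots > 0:    # PI(4,5)P2 binding to an unbound syt
        out.append((BindingState(n, m, k + 1), free * slots * pip2 * params.gamma))
    if k > 0:                     # PI(4,5)P2 unbinding
        out.append((BindingState(n, m, k - 1), k * params.delta))
    if free > 0:                  # Ca2+ binding to an unbound syt
        out.append((BindingState(n, m + 1, k), free * cac * params.alpha))
    if m > 0:                     # Ca2+ unbinding
        out.append((BindingState(n, m - 1, k), m * params.beta))
    if m > 0 and slots > 0:       # dual formation via PI(4,5)P2 binding
        out.append((BindingState(n + 1, m - 1, k), m * slots * pip2 * params.gamma))
    if n > 0:                     # dual loses PI(4,5)P2 (allosterically slowed)
        out.append((BindingState(n - 1, m + 1, k), params.A * n * params.delta))
    if k > 0:                     # dual formation via Ca2+ binding
        out.append((BindingState(n + 1, m, k - 1), k * cac * params.alpha))
    if n > 0:                     # dual loses Ca2+ (allosterically slowed)
        out.append((BindingState(n - 1, m, k + 1), params.A * n * params.beta))
    if include_fusion:
        out.append((FUSED, fusion_rate(n, params)))
    return out


@dataclass
class IntensityMatrix:
    """Transition-rate (generator) matrix of the vesicle Markov chain."""

    Q: np.ndarray
    space: StateSpace
    ca: float
    pip2: float
    include_fusion: bool = True


def build_intensity_matrix(
    space: StateSpace,
    params: ModelParameters,
    ca: float,
    pip2: float | None = None,
    include_fusion: bool = True,
) -> IntensityMatrix:
    """Assemble the intensity matrix Q over ``space`` at given concentrations.

    Off-diagonal entries are the reaction rates, the diagonal is minus the
    row sum, and the fused row is identically zero (absorbing state).  With
    ``include_fusion=False`` the fusion reactions are omitted, which yields
    the closed fusion-free chain used for the steady state.
    """
    if pip2 is None:
        pip2 = params.pip2
    if params.n_syts != space.n_syts or params.M_slots != space.M_slots:
        raise InvalidParameterError("state space does not match parameters")
    ns = len(space)
    Q = np.zeros((ns, ns))
    for i, state in enumerate(space.states[:-1]):
        for target, rate in reaction_rates(state, params, ca, pip2,
                                           include_fusion=include_fusion):
            Q[i, space.index(target)] += rate
        Q[i, i] = -Q[i].sum()
    return IntensityMatrix(Q=Q, space=space, ca=ca, pip2=pip2,
                           include_fusion=include_fusion)
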