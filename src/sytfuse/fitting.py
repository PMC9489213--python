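"""Parameter estimation from uncaging dose-response data.

The free parameters are the association rate constants ``alpha`` and
``gamma``, the effective PI(4,5)P2 concentration, the fusion factor ``f``
and the latency delay ``d``.  The objective combines both observables of an
uncaging experiment:

    cost = w * sum_i (r_max,model(ca_i) - r_max,data(ca_i))^2  -  sum_j ll_j

with the peak-rate deviations in (vesicles/ms)^2, ``w = 2`` by default, and
``ll_j`` the log-likelihood (per-ms density) of the observed latency at
concentration ``ca_j`` under the gamma-pool order-statistic density.  The
model peak rate uses the mean pool size.  Minimisation is Nelder-Mead on
transformed coordinates (log for the positive parameters, logit for ``d``
inside its bounds), optionally from multiple start points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .analytic import peak_release_rate, spectral_propagator, time_course
from .likelihood import _log_density_gamma_from_u
from .model import ModelParameters
from .steady_state import RRPDistribution

__all__ = ["FitSpec", "FitResult", "cost", "fit", "grid_explore"]

#: optimisation bounds: d within [0.3, 0.405] ms, rates below 1e10
D_BOUNDS = (0.3, 0.405)
UPPER_BOUND = 1e10
MAX_ITER = 5000

_LOG_PARAMS = ("alpha", "gamma", "pip2", "f")
_LN1000 = math.log(1000.0)  # per-second -> per-millisecond density shift


@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` lists the free parameters (subset of alpha, gamma, pip2, f, d);
    ``base`` carries the fixed values (and the starting center for the free
    ones).  ``n_starts`` Nelder-Mead runs are launched: the first from
    ``base`` itself, the others from log-uniform perturbations within
    ``start_spread`` decades around it.
    """

    base: ModelParameters
    free: tuple[str, ...] = ("alpha", "gamma", "pip2", "f", "d")
    rrp: RRPDistribution = field(default_factory=RRPDistribution)
    rate_weight: float = 2.0
    n_starts: int = 8
    start_spread: float = 1.0
    max_iter: int = MAX_ITER
    seed: int | None = None
    xatol: float = 1e-4
    fatol: float = 1e-4


@dataclass
class FitResult:
    params: ModelParameters
    cost: float
    start_costs: list[float]
    converged: bool


class FitFailureError(RuntimeError):
    """No start point produced a finite cost."""


def _prepare(params: ModelParameters, ca_values, rrp: RRPDistribution):
    """Per-concentration model quantities that do not depend on d: the
    spectral propagator and the peak ensemble rate (vesicles/ms)."""
    out = {}
    for ca in ca_values:
        sp = spectral_propagator(params, ca)
        peak1, _ = peak_release_rate(params, ca, n_ves=1.0, _spectral=sp)
        out[ca] = {"peak_per_ms": rrp.mean * peak1 * 1e-3, "sp": sp}
    return out


def _latency_loglik(prep, params, frame, rrp):
    """Sum of per-ms latency log-likelihoods; -inf if any term is."""
    total = 0.0
    for ca, lat_ms in zip(frame["ca_uM"], frame["latency_ms"]):
        sp = prep[ca]["sp"]
        t = (lat_ms - params.d) * 1e-3
        if t <= 0:
            return -np.inf
        if sp.ok:
            u = float(np.clip(sp.G(t)[0], 0.0, 1.0))
            gp = max(float(sp.Gp(t)[0]), 0.0)
        else:
            tc = time_course(params, ca).extend_to_time(t)
            u = float(np.interp(t, tc.t, tc.G))
            gp = float(np.interp(t, tc.t, tc.Gp))
        ll = _log_density_gamma_from_u(u, gp, rrp.shape, rrp.scale) - _LN1000
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def cost(
    params: ModelParameters,
    data,
    rrp: RRPDistribution | None = None,
    rate_weight: float = 2.0,
) -> float:
    """Combined squared-rate-deviation / latency-likelihood cost (lower is
    better); non-finite intermediate values yield +inf."""
    if rrp is None:
        rrp = RRPDistribution()
    frame = getattr(data, "frame", data)
    if len(frame) == 0:
        return 0.0
    try:
        prep = _prepare(params, frame["ca_uM"].unique(), rrp)
    except Exception:
        return np.inf
    sq = 0.0
    for ca, r_obs in zip(frame["ca_uM"], frame["peak_rate_per_ms"]):
        sq += (prep[ca]["peak_per_ms"] - r_obs) ** 2
    ll = _latency_loglik(prep, params, frame, rrp)
    total = rate_weight * sq - ll
    return float(total) if np.isfinite(total) else np.inf


def _to_x(params: ModelParameters, free) -> np.ndarray:
    x = []
    for name in free:
        v = getattr(params, name)
        if name == "d":
            lo, hi = D_BOUNDS
            x.append(float(logit((v - lo) / (hi - lo))))
        else:
            x.append(math.log(min(v, UPPER_BOUND)))
    return np.asarray(x)


def _from_x(x: np.ndarray, base: ModelParameters, free) -> ModelParameters:
    kw = {}
    for name, xi in zip(free, x):
        if name == "d":
            lo, hi = D_BOUNDS
            kw[name] = lo + (hi - lo) * float(expit(xi))
        else:
            kw[name] = float(min(math.exp(xi), UPPER_BOUND))
    return base.replace(**kw)


def fit(data, spec: FitSpec) -> FitResult:
    """Nelder-Mead minimisation of :func:`cost`, best of ``n_starts``."""
    rng = np.random.default_rng(spec.seed)
    frame = getattr(data, "frame", data)
    free = tuple(spec.free)
    for name in free:
        if name not in _LOG_PARAMS + ("d",):
            raise ValueError(f"cannot free parameter {name!r}")

    def objective(x):
        try:
            p = _from_x(x, spec.base, free)
        except Exception:
            return np.inf
        return cost(p, frame, rrp=spec.rrp, rate_weight=spec.rate_weight)

    x0 = _to_x(spec.base, free)
    starts = [x0]
    for _ in range(spec.n_starts - 1):
        pert = np.array([
            0.0 if name == "d"
            else rng.uniform(-spec.start_spread, spec.start_spread) * math.log(10.0)
            for name in free
        ])
        starts.append(x0 + pert)

    best = None
    start_costs = []
    for x_start in starts:
        res = minimize(
            objective, x_start, method="Nelder-Mead",
            options=dict(maxiter=spec.max_iter, maxfev=spec.max_iter,
                         xatol=spec.xatol, fatol=spec.fatol),
        )
        start_costs.append(float(res.fun))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"all {len(starts)} starts gave non-finite cost")
    return FitResult(
        params=_from_x(best.x, spec.base, free),
        cost=float(best.fun),
        start_costs=start_costs,
        converged=bool(best.success),
    )


def grid_explore(
    base: ModelParameters,
    alpha_values,
    gamma_values,
    pip2_values,
    data,
    rrp: RRPDistribution | None = None,
    rate_weight: float = 2.0,
):
    """Cost over a (alpha, gamma, pip2) grid with d re-optimised per point.

    ``f`` stays fixed at ``base.f``.  Because d only shifts the latencies,
    the per-point time courses and peak rates are computed once and the 1-D
    d-optimisation reuses them.  Returns (cost_array, d_array) with shape
    (len(alpha_values), len(gamma_values), len(pip2_values)).
    """
    if rrp is None:
        rrp = RRPDistribution()
    frame = getattr(data, "frame", data)
    ca_values = frame["ca_uM"].unique()
    shape = (len(alpha_values), len(gamma_values), len(pip2_values))
    costs = np.full(shape, np.inf)
    d_opt = np.full(shape, np.nan)
    for ia, a in enumerate(alpha_values):
        for ig, g in enumerate(gamma_values):
            for ip, pp in enumerate(pip2_values):
                p = base.replace(alpha=a, gamma=g, pip2=pp)
                try:
                    prep = _prepare(p, ca_values, rrp)
                except Exception:
                    continue
                sq = sum(
                    (prep[ca]["peak_per_ms"] - r) ** 2
                    for ca, r in zip(frame["ca_uM"], frame["peak_rate_per_ms"])
                )

                def neg(d):
                    ll = _latency_loglik(prep, p.replace(d=d), frame, rrp)
                    v = rate_weight * sq - ll
                    return v if np.isfinite(v) else 1e300

                res = minimize_scalar(neg, bounds=D_BOUNDS, method="bounded")
                costs[ia, ig, ip] = float(res.fun)
                d_opt[ia, ig, ip] = float(res.x)
    return costs, d_opt
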