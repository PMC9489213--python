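"""Synthetic inputs: stimulus traces and uncaging-style datasets.

The dose-response data the model is fitted to (one release latency and one
peak release rate per Ca2+ concentration) and the action-potential-like
Ca2+ transients driving the stochastic engine are not shipped with the
package; this module generates statistically equivalent stand-ins from
known parameters, so every pipeline stage runs without external files.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import (
    peak_release_rate,
    sample_release_latencies,
    time_course,
    uncaging_grid,
)
from .model import ModelParameters
from .steady_state import MIN_POOL_FOR_LATENCY, RRPDistribution, sample_rrp_sizes

__all__ = [
    "LatencyRateDataset",
    "StimulusTrace",
    "uncaging_grid",
    "ap_transient",
    "paired_pulse_protocol",
    "synthesize_fit_dataset",
]

#: default AP-like microdomain transient: brief pulse in the tens of uM
AP_PEAK_UM = 40.0
AP_FWHM_MS = 0.5
CA_BASELINE_UM = 0.05


@dataclass
class StimulusTrace:
    """Piecewise-linear (time, concentration) stimulus; times strictly
    increasing, linear interpolation between samples."""

    t: np.ndarray      # seconds
    conc: np.ndarray   # uM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be nonnegative")

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.conc)

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.t * 1e3, "conc_uM": self.conc}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StimulusTrace":
        df = pd.read_csv(path)
        return cls(t=df["time_ms"].to_numpy() * 1e-3,
                   conc=df["conc_uM"].to_numpy())

    @classmethod
    def constant(cls, conc: float, t_end: float) -> "StimulusTrace":
        return cls(t=np.array([0.0, t_end]), conc=np.array([conc, conc]))


@dataclass
class LatencyRateDataset:
    """Per-concentration release latencies and peak release rates.

    Columns: ``ca_uM``, ``latency_ms``, ``peak_rate_per_ms`` (vesicles/ms);
    one single measurement per concentration, as in uncaging experiments.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "external-file"})

    def __post_init__(self) -> None:
        required = {"ca_uM", "latency_ms", "peak_rate_per_ms"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.frame["peak_rate_per_ms"] < 0).any():
            raise ValueError("peak rates must be nonnegative")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2, default=float)

    @classmethod
    def from_csv(cls, path) -> "LatencyRateDataset":
        return cls(frame=pd.read_csv(path))


def ap_transient(
    peak: float = AP_PEAK_UM,
    fwhm_ms: float = AP_FWHM_MS,
    baseline: float = CA_BASELINE_UM,
    t_peak_ms: float = 1.0,
    duration_ms: float = 6.0,
    dt_ms: float = 0.02,
) -> StimulusTrace:
    """Gaussian AP-like Ca2+ microdomain transient riding on the baseline.

    Defaults emulate the brief (~0.5 ms half-width) local transient peaking
    in the tens of uM that a docked vesicle experiences during an action
    potential.
    """
    if fwhm_ms <= 0:
        raise ValueError("transient width must be positive")
    if peak <= baseline:
        raise ValueError("peak must exceed baseline")
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    conc = baseline + (peak - baseline) * np.exp(-0.5 * ((t - t_peak_ms) / sigma) ** 2)
    # the tails of the Gaussian are numerically at baseline at t=0 and t=end
    conc[0] = conc[-1] = baseline
    return StimulusTrace(t=t * 1e-3, conc=conc)


def paired_pulse_protocol(
    interval_ms: float = 10.0,
    residual_amp: float = 0.4,
    residual_rate: float = 0.154,
    residual_as_time_constant: bool = False,
    pip2_wt: float = 1.109,
    pip2_start_fraction: float = 0.25,
    pip2_rise_tau_ms: float = 5.0,
    peak: float = AP_PEAK_UM,
    fwhm_ms: float = AP_FWHM_MS,
    t_first_ms: float = 1.0,
    duration_ms: float = 20.0,
    dt_ms: float = 0.02,
) -> dict:
    """Two AP-like transients 10 ms apart plus a residual-Ca2+ tail.

    The residual transient starts at the first pulse with amplitude 0.4 uM
    and decays as ``exp(-t * 0.154 s^-1)`` (set
    ``residual_as_time_constant=True`` to read 0.154 as seconds instead).
    Two PI(4,5)P2 trajectories are returned: the wild-type trace constant at
    ``pip2_wt``, and a mutant trace that starts at a fraction of it and
    relaxes toward the wild-type level between the pulses, emulating
    activity-dependent re-docking of undocked vesicles.

    Returns a dict with keys ``ca``, ``pip2_wt``, ``pip2_mutant``.
    """
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    ca = np.full_like(t, CA_BASELINE_UM)
    for t0 in (t_first_ms, t_first_ms + interval_ms):
        ca = ca + (peak - CA_BASELINE_UM) * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    rate = 1.0 / residual_rate if residual_as_time_constant else residual_rate
    after = t >= t_first_ms
    ca[after] += residual_amp * np.exp(-(t[after] - t_first_ms) * 1e-3 * rate)

    pip2_wt_trace = StimulusTrace(t=t * 1e-3, conc=np.full_like(t, pip2_wt))
    start = pip2_start_fraction * pip2_wt
    pip2_mut = np.full_like(t, start)
    pip2_mut[after] = pip2_wt - (pip2_wt - start) * np.exp(
        -(t[after] - t_first_ms) / pip2_rise_tau_ms
    )
    return {
        "ca": StimulusTrace(t=t * 1e-3, conc=ca),
        "pip2_wt": pip2_wt_trace,
        "pip2_mutant": StimulusTrace(t=t * 1e-3, conc=pip2_mut),
        "t_first_ms": t_first_ms,
        "interval_ms": interval_ms,
    }


def synthesize_fit_dataset(
    params: ModelParameters,
    ca_grid: np.ndarray | None = None,
    seed: int | None = None,
    rate_noise_cv: float = 0.1,
    rrp: RRPDistribution | None = None,
) -> LatencyRateDataset:
    """Synthetic uncaging dataset at known ground-truth parameters.

    Per concentration: one latency (a stochastic 5th-fusion draw with a
    gamma-distributed pool, plus the delay d) and one peak rate (the mean
    model prediction times multiplicative lognormal noise with coefficient
    of variation ``rate_noise_cv``), mirroring the single-measurement
    structure of experimental uncaging datasets.
    """
    if ca_grid is None:
        ca_grid = uncaging_grid()
    if rrp is None:
        rrp = RRPDistribution()
    rng = np.random.default_rng(seed)
    rows = []
    for ca in ca_grid:
        size = sample_rrp_sizes(rrp, 1, rng, min_size=MIN_POOL_FOR_LATENCY)
        tc = time_course(params, float(ca))
        lat = float(sample_release_latencies(tc, size, rng)[0])
        peak1, _ = peak_release_rate(params, float(ca), n_ves=1.0)
        rate = rrp.mean * peak1 * 1e-3
        if rate_noise_cv > 0:
            sig = np.sqrt(np.log1p(rate_noise_cv**2))
            rate *= rng.lognormal(-0.5 * sig**2, sig)
        rows.append({"ca_uM": float(ca), "latency_ms": lat,
                     "peak_rate_per_ms": float(rate)})
    return LatencyRateDataset(
        frame=pd.DataFrame(rows),
        provenance={
            "source": "synthetic",
            "params": params.to_dict(),
            "seed": seed,
            "rate_noise_cv": rate_noise_cv,
            "rrp_mean": rrp.mean,
            "rrp_sd": rrp.sd,
        },
    )
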