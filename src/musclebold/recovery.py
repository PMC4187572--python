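"""Mono-exponential recovery fitting and oxygenation metrics.

The post-exercise portion of the cycle-averaged percent-change time course
is fitted with a three-parameter exponential

    y(t) = plateau + (peak - plateau) * exp(-t / tau),

where t is time since the start of the recovery window. Two headline
metrics follow:

* maximal change — the peak amplitude of the cycle-averaged series, i.e.
  its maximum (% of baseline R2*);
* recovery change — peak minus the fitted value at the end of the recovery
  window ("trough"); also reported divided by the peak as a dimensionless
  normalized variant.

Fits are deterministic (fixed initialization, bounded tau) and failures are
flagged rather than hidden: a flat segment is marked degenerate, a
time constant pinned at its bound marks the fit unconverged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .paradigm import AcquisitionParams, ExerciseParadigm

__all__ = ["ExponentialFit", "OxygenationMetrics", "fit_recovery", "extract_metrics"]

TAU_BOUNDS = (0.1, 600.0)   # seconds; generous for a 120 s window
_FLAT_TOL = 1e-12


def _model(t: np.ndarray, peak: float, plateau: float, tau: float) -> np.ndarray:
    return plateau + (peak - plateau) * np.exp(-t / tau)


@dataclass(frozen=True)
class ExponentialFit:
    """Result of the recovery fit. ``converged`` is honest: bound-pinned or
    failed optimizations report False, degenerate (flat) inputs report
    ``degenerate=True`` with tau = NaN."""

    peak: float
    plateau: float
    tau: float
    rss: float
    converged: bool
    degenerate: bool = False

    def value_at(self, t: float) -> float:
        if self.degenerate:
            return self.plateau
        return float(_model(np.asarray(t, dtype=float), self.peak, self.plateau, self.tau))

    @property
    def amplitude(self) -> float:
        """Fitted decay amplitude, peak - plateau."""
        return self.peak - self.plateau


@dataclass(frozen=True)
class OxygenationMetrics:
    """Headline per-muscle metrics of one functional run."""

    muscle: str
    maximal_change: float
    recovery_change: float
    recovery_change_normalized: float
    tau: float
    converged: bool
    rss: float
    workload: Optional[float] = None
    visit: Optional[int] = None
    subject: Optional[str] = None


def fit_recovery(
    cycle_times: np.ndarray,
    cycle_avg: np.ndarray,
    paradigm: ExerciseParadigm,
    tau_bounds: tuple[float, float] = TAU_BOUNDS,
) -> ExponentialFit:
    """Fit the exponential to the recovery-phase frames of a cycle average.

    ``cycle_times`` are within-cycle frame onset times; frames with
    ``t >= exercise_duration`` form the recovery segment (t is re-zeroed at
    the exercise/recovery boundary for the fit). Requires >= 4 recovery
    frames for the 3-parameter model.
    """
    t = np.asarray(cycle_times, dtype=float)
    y = np.asarray(cycle_avg, dtype=float)
    rec = t >= paradigm.exercise_duration
    t_rec = t[rec] - paradigm.exercise_duration
    y_rec = y[rec]
    if t_rec.size < 4:
        raise ValueError(f"recovery segment has {t_rec.size} frames; need >= 4")

    if float(np.ptp(y_rec)) < _FLAT_TOL:
        c = float(y_rec.mean())
        return ExponentialFit(peak=c, plateau=c, tau=float("nan"),
                              rss=float(((y_rec - c) ** 2).sum()),
                              converged=True, degenerate=True)

    tail = y_rec[t_rec >= t_rec[-1] - 15.0]   # last 15 s of the window
    p0 = (float(y_rec[0]), float(tail.mean()), 30.0)
    lo = (-np.inf, -np.inf, tau_bounds[0])
    hi = (np.inf, np.inf, tau_bounds[1])
    try:
        popt, _ = curve_fit(_model, t_rec, y_rec, p0=p0, bounds=(lo, hi), maxfev=10000)
    except RuntimeError:
        return ExponentialFit(*p0, rss=float("inf"), converged=False)
    peak, plateau, tau = (float(p) for p in popt)
    rss = float(((y_rec - _model(t_rec, *popt)) ** 2).sum())
    # within 1% of a bound: the time constant was not identified by the data
    at_bound = tau >= tau_bounds[1] * 0.99 or tau <= tau_bounds[0] * 1.01
    return ExponentialFit(peak, plateau, tau, rss, converged=not at_bound)


def extract_metrics(
    cycle_times: np.ndarray,
    cycle_avg: np.ndarray,
    fit: ExponentialFit,
    paradigm: ExerciseParadigm,
    muscle: str = "",
    workload: Optional[float] = None,
    visit: Optional[int] = None,
    subject: Optional[str] = None,
    trough: str = "fitted",
) -> OxygenationMetrics:
    """Compute maximal change and recovery change from a cycle average + fit.

    The trough defaults to the fitted model value at the end of the
    recovery window; ``trough="raw"`` uses the raw minimum of the recovery
    segment instead.
    """
    y = np.asarray(cycle_avg, dtype=float)
    t = np.asarray(cycle_times, dtype=float)
    maximal = float(y.max())
    if trough == "fitted":
        trough_val = fit.value_at(paradigm.recovery_duration)
    elif trough == "raw":
        trough_val = float(y[t >= paradigm.exercise_duration].min())
    else:
        raise ValueError(f"trough must be 'fitted' or 'raw', got {trough!r}")
    rec_change = maximal - trough_val
    rec_norm = rec_change / maximal if maximal != 0 else float("nan")
    return OxygenationMetrics(
        muscle=muscle,
        maximal_change=maximal,
        recovery_change=rec_change,
        recovery_change_normalized=rec_norm,
        tau=fit.tau,
        converged=fit.converged and not fit.degenerate,
        rss=fit.rss,
        workload=workload,
        visit=visit,
        subject=subject,
    )
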