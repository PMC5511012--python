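"""Side quantifications: photobleaching decay, dye mass, behavioural stats.

These accompany the mechanical fingerprinting: an exponential fit to
normalised fluorescence decay (the standard photobleaching law), conversion
of the decay constant into an equivalent number of behavioural trials, the
percentage mass added by the dye, session percent-correct, and the all-pairs
before/after performance-difference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .synthetic import BehaviorSession, PhotobleachTrace

__all__ = [
    "ExpFitResult",
    "DiffDistribution",
    "fit_photobleach",
    "trials_per_time_constant",
    "mass_increment_pct",
    "session_performance",
    "pairwise_diff_distribution",
]


class FitFailureError(ValueError):
    pass


@dataclass(frozen=True)
class ExpFitResult:
    """a * exp(-t / tau) least-squares fit to a decay trace."""

    time_constant_tau: float
    amplitude: float
    residual_rms: float

    @property
    def tau_hours(self) -> float:
        return self.time_constant_tau / 3600.0


@dataclass(frozen=True)
class DiffDistribution:
    """All pairwise (after - before) performance differences, percentage points."""

    differences: np.ndarray

    def summary(self) -> dict:
        d = self.differences
        qs = np.percentile(d, [2.5, 25, 50, 75, 97.5])
        return {
            "n": int(d.size),
            "mean": float(d.mean()),
            "q025": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "q975": float(qs[4]),
        }


def fit_photobleach(trace: PhotobleachTrace) -> ExpFitResult:
    """Nonlinear least-squares fit of a*exp(-t/tau) to a bleaching trace.

    Initialised from a log-linear regression of ln(intensity) on time; a
    non-decaying trace (non-negative log-linear slope or non-positive fitted
    tau) raises ``FitFailureError``.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.normalized_intensity, dtype=float)
    if t.size < 3:
        raise FitFailureError("need at least 3 samples")
    if np.any(y <= 0):
        pos = y > 0
        if pos.sum() < 3:
            raise FitFailureError("too few positive intensities")
        t_init, y_init = t[pos], y[pos]
    else:
        t_init, y_init = t, y
    slope, intercept = np.polyfit(t_init, np.log(y_init), 1)
    if slope >= 0:
        raise FitFailureError("trace does not decay: exponential fit is ill-posed")
    tau0, a0 = -1.0 / slope, float(np.exp(intercept))

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = scipy.optimize.curve_fit(
            model, t, y, p0=(a0, tau0), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc
    a, tau = popt
    if not np.isfinite(tau) or tau <= 0:
        raise FitFailureError(f"fitted time constant {tau} is not positive")
    resid = y - model(t, a, tau)
    return ExpFitResult(float(tau), float(a), float(np.sqrt(np.mean(resid**2))))


def trials_per_time_constant(fit: ExpFitResult, trial_duration: float) -> float:
    """How many behavioural trials fit inside one bleaching time constant."""
    if trial_duration <= 0:
        raise ValueError("trial_duration must be positive")
    return fit.time_constant_tau / trial_duration


def mass_increment_pct(mass_before: float, mass_after: float) -> float:
    """Percent mass change, 100 * (after - before) / before."""
    if mass_before <= 0:
        raise ValueError("mass_before must be positive")
    return 100.0 * (mass_after - mass_before) / mass_before


def session_performance(session: BehaviorSession) -> float:
    """Percent of trials in which the chosen side was the rewarded side."""
    df = session.trials
    if len(df) < 1:
        raise ValueError("empty session")
    return 100.0 * float(np.mean(df["chosen"].to_numpy() == df["correct"].to_numpy()))


def pairwise_diff_distribution(before, after) -> DiffDistribution:
    """Every (after_j - before_i) difference, as plotted in permutation violins."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size == 0 or a.size == 0:
        raise ValueError("both performance lists must be non-empty")
    return DiffDistribution((a[:, np.newaxis] - b[np.newaxis, :]).ravel())
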