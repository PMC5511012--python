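"""Magnitude FRF estimation and whisker similarity fingerprinting.

Each whisker segment is treated as a linear time-invariant system driven by
the base motion.  Its transfer function is estimated with the H1
cross-spectral estimator, ``H_i(f) = S_{x y_i}(f) / S_{xx}(f)``, where ``x``
is the tracked base deflection and ``y_i`` the deflection of segment ``i``;
auto- and cross-spectral densities come from Welch averaging.  The magnitude
``|H_i(f)|`` over the (frequency, normalised position) grid — the mFRF — is
the whisker's mechanical fingerprint.

Two fingerprints are compared by vectorising both log10-magnitude matrices
and taking the squared Pearson correlation (the coefficient of determination
of a simple linear regression, symmetric in its arguments).  For a set of
whiskers ordered by length, the similarity matrix exhibits near-diagonal
blocks; the mean of each sub/super-diagonal band summarises how similarity
decays with length disparity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.signal

from .beam import ComplexFRF

__all__ = [
    "WelchSpec",
    "MagnitudeFRF",
    "SimilarityMatrix",
    "BandMeans",
    "estimate_mfrf",
    "average_mfrf",
    "magnitude_from_complex",
    "similarity_r2",
    "similarity_matrix",
    "band_means",
]


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class WelchSpec:
    """Welch cross-spectral estimation parameters.

    Defaults: Hann window, 1024-sample segments with 50% overlap (a 4500
    sample trial at 2 kHz yields ~7 averaged segments), one-sided spectra,
    comparison band 1-900 Hz (excludes the DC bin and near-Nyquist bins).
    """

    window: str = "hann"
    nperseg: int = 1024
    noverlap: int | None = None
    detrend: str = "constant"
    f_min: float = 1.0
    f_max: float = 900.0


@dataclass(frozen=True)
class MagnitudeFRF:
    """|H| on a frequency x normalised-position grid.

    ``magnitudes[k, i]`` is the gain at ``frequencies[k]`` (Hz) and
    ``positions[i]`` (arclength fraction in [0, 1], base = 0).
    """

    magnitudes: np.ndarray
    frequencies: np.ndarray
    positions: np.ndarray
    n_trials_averaged: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.shape != (self.frequencies.size, self.positions.size):
            raise SpectralError("magnitudes must be (n_frequencies, n_positions)")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise SpectralError("magnitudes must be finite and non-negative")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric K x K matrix of pairwise mFRF R^2 values."""

    r_squared: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        r = np.asarray(self.r_squared, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or len(self.labels) != r.shape[0]:
            raise SpectralError("r_squared must be square and match labels")


@dataclass(frozen=True)
class BandMeans:
    """theta[i-1] = mean similarity at diagonal offset i (i = 1 .. K-1)."""

    theta: np.ndarray


def estimate_mfrf(field, welch: WelchSpec | None = None) -> MagnitudeFRF:
    """Welch/H1 magnitude transfer-function estimate for every segment.

    ``field`` is a DeflectionField whose first row (position 0) is the base
    motion used as the input signal.  Raises if the input carries no power in
    any retained frequency bin.
    """
    welch = welch or WelchSpec()
    y = np.asarray(field.deflections, dtype=float)
    if y.shape[0] < 2:
        raise SpectralError("need the base row plus at least one output row")
    fs = field.frame_rate
    nperseg = min(welch.nperseg, y.shape[1])
    noverlap = welch.noverlap if welch.noverlap is not None else nperseg // 2
    if y.shape[1] < 2 * nperseg - noverlap:
        raise SpectralError("trial too short for at least 2 Welch segments")
    x = y[0]
    freqs, pxx = scipy.signal.welch(
        x, fs=fs, window=welch.window, nperseg=nperseg,
        noverlap=welch.noverlap, detrend=welch.detrend,
    )
    _, pxy = scipy.signal.csd(
        x[np.newaxis, :], y, fs=fs, window=welch.window, nperseg=nperseg,
        noverlap=welch.noverlap, detrend=welch.detrend,
    )
    keep = (freqs >= welch.f_min) & (freqs <= welch.f_max)
    if not np.any(keep):
        raise SpectralError("comparison band contains no Welch bins")
    bad = keep & (pxx <= 0)
    if np.any(bad):
        raise SpectralError(
            f"zero input power at {freqs[bad][0]:g} Hz: cannot form the H1 estimate"
        )
    mags = (np.abs(pxy[:, keep]) / pxx[keep]).T  # (F, N)
    return MagnitudeFRF(
        magnitudes=mags,
        frequencies=freqs[keep],
        positions=np.asarray(field.sample_positions, dtype=float),
        n_trials_averaged=1,
        label=getattr(field, "trial_id", "") or "",
    )


def average_mfrf(per_trial: Sequence[MagnitudeFRF]) -> MagnitudeFRF:
    """Element-wise mean of per-trial magnitude estimates on a common grid."""
    if not per_trial:
        raise SpectralError("empty trial list")
    first = per_trial[0]
    for m in per_trial[1:]:
        if (
            m.frequencies.shape != first.frequencies.shape
            or m.positions.shape != first.positions.shape
            or not np.allclose(m.frequencies, first.frequencies)
            or not np.allclose(m.positions, first.positions)
        ):
            raise SpectralError("trial mFRFs are on different grids")
    mean = np.mean([m.magnitudes for m in per_trial], axis=0)
    return replace(first, magnitudes=mean, n_trials_averaged=len(per_trial))


def magnitude_from_complex(
    frf: ComplexFRF,
    frequencies: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    label: str = "",
) -> MagnitudeFRF:
    """Analytic |H| resampled onto a (frequency, normalised position) grid.

    Positions are normalised by the shaft length; linear interpolation in
    both axes.  Used to compare FEM predictions with video estimates.
    """
    pos_norm = frf.positions / frf.positions[-1]
    mag = np.abs(frf.values)  # (n_pos, n_freq)
    if positions is None:
        positions = pos_norm
    out = np.empty((len(positions), frf.frequencies.size))
    for k in range(frf.frequencies.size):
        out[:, k] = np.interp(positions, pos_norm, mag[:, k])
    if frequencies is None:
        frequencies = frf.frequencies
        final = out.T
    else:
        final = np.empty((len(frequencies), len(positions)))
        for i in range(len(positions)):
            final[:, i] = np.interp(frequencies, frf.frequencies, out[i])
    return MagnitudeFRF(final, np.asarray(frequencies, float), np.asarray(positions, float),
                        n_trials_averaged=1, label=label)


_LOG_FLOOR = 1e-12


def _aligned_vectors(a: MagnitudeFRF, b: MagnitudeFRF, log: bool):
    """Resample b onto a's frequency grid and both onto a common position grid."""
    n_pos = max(a.positions.size, b.positions.size)
    pos = np.linspace(0.0, 1.0, n_pos)

    def _resample(m: MagnitudeFRF) -> np.ndarray:
        v = m.magnitudes
        if m.positions.size != n_pos or not np.allclose(m.positions, pos):
            v = np.vstack([np.interp(pos, m.positions, row) for row in v])
        if m.frequencies.size != a.frequencies.size or not np.allclose(
            m.frequencies, a.frequencies
        ):
            v = np.column_stack(
                [np.interp(a.frequencies, m.frequencies, col) for col in v.T]
            )
        return v

    va, vb = _resample(a).ravel(), _resample(b).ravel()
    if log:
        va = np.log10(np.maximum(va, _LOG_FLOOR))
        vb = np.log10(np.maximum(vb, _LOG_FLOOR))
    return va, vb


def similarity_r2(a: MagnitudeFRF, b: MagnitudeFRF, log: bool = True) -> float:
    """Squared Pearson correlation of the two vectorised (log-)mFRF matrices.

    R^2 = 1 means the fingerprints are affinely related (identical dynamic
    response up to gain/offset); 0 means uncorrelated responses.  Symmetric.
    """
    va, vb = _aligned_vectors(a, b, log)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise SpectralError("constant mFRF vector: R^2 undefined")
    r = np.corrcoef(va, vb)[0, 1]
    return float(r * r)


def similarity_matrix(
    items: Sequence[MagnitudeFRF],
    labels: Sequence[str] | None = None,
    log: bool = True,
) -> SimilarityMatrix:
    """All pairwise similarities; unit diagonal, exactly symmetric."""
    if len(items) < 2:
        raise SpectralError("need at least 2 mFRFs")
    if labels is None:
        labels = [m.label or f"W{i + 1}" for i, m in enumerate(items)]
    k = len(items)
    r2 = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r2[i, j] = r2[j, i] = similarity_r2(items[i], items[j], log=log)
    return SimilarityMatrix(r2, tuple(labels))


def band_means(m: SimilarityMatrix) -> BandMeans:
    """Mean of entries at each diagonal offset |row - col| = i, i = 1..K-1."""
    r = m.r_squared
    k = r.shape[0]
    if k < 2:
        raise SpectralError("need K >= 2")
    theta = np.array([np.mean(np.diag(r, i)) for i in range(1, k)])
    return BandMeans(theta)
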