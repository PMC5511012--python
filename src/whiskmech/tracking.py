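"""Whisker deflection tracking from high-speed grayscale frame stacks.

The pipeline mirrors a standard bright-filament tracker: per frame, pixels
belonging to the whisker are revealed by thresholding inside a region of
interest, a parametric planar B-spline is fitted to the thresholded point
cloud, and the curve is resampled at N equidistant arclength positions
ordered base to tip.  Stacking the transverse (image-row) coordinate of every
sample over frames, and removing each sample's temporal mean (the rest
shape), yields the deflection field v(x, t) in pixels; the base row doubles
as the estimate of the shaker input driving the whisker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.interpolate
from skimage.filters import threshold_otsu

__all__ = [
    "FrameStack",
    "WhiskerSpline",
    "WhiskerTrace",
    "DeflectionField",
    "TrackingError",
    "segment_whisker_pixels",
    "fit_whisker_spline",
    "resample_equidistant",
    "track_frames",
    "extract_deflections",
    "track_stack",
]


class TrackingError(ValueError):
    """Tracking failure; carries the offending frame index when known."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


@dataclass
class FrameStack:
    """T grayscale frames with acquisition metadata.

    ``frames``: (T, H, W) array, intensities in [0, 1] or [0, 255];
    ``roi``: (row_start, row_stop, col_start, col_stop) half-open bounds;
    ``base_edge``: which roi edge the whisker base abuts (left/right/top/bottom).
    """

    frames: np.ndarray
    frame_rate: float
    roi: tuple | None = None
    base_edge: str = "left"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 1:
            raise TrackingError("frames must be a (T, H, W) stack with T >= 1")
        self.frames = f
        if self.roi is None:
            self.roi = (0, f.shape[1], 0, f.shape[2])
        r0, r1, c0, c1 = self.roi
        if not (0 <= r0 < r1 <= f.shape[1] and 0 <= c0 < c1 <= f.shape[2]):
            raise TrackingError("roi outside image bounds")
        if self.base_edge not in ("left", "right", "top", "bottom"):
            raise TrackingError(f"unknown base_edge {self.base_edge!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class WhiskerSpline:
    """Fitted parametric planar B-spline (scipy tck) with its fit residual."""

    tck: tuple
    degree: int
    residual_rms: float

    def __call__(self, u: np.ndarray) -> np.ndarray:
        rr, cc = scipy.interpolate.splev(np.asarray(u, float), self.tck)
        return np.column_stack([rr, cc])


@dataclass
class WhiskerTrace:
    """Per-frame spline fits plus N equidistant arclength samples per frame.

    ``samples``: (T, N, 2) pixel coordinates (row, col), ordered base to tip.
    """

    splines: list
    samples: np.ndarray
    spline_degree: int

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class DeflectionField:
    """N x T matrix of transverse deflections (pixels) per arclength sample.

    Row 0 is the base segment (the tracked shaker input); values have each
    sample's temporal mean removed so the rest shape reads as zero.
    """

    deflections: np.ndarray
    sample_positions: np.ndarray
    frame_rate: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.deflections, dtype=float)
        if d.ndim != 2:
            raise TrackingError("deflections must be an (N, T) matrix")
        if not np.all(np.isfinite(d)):
            raise TrackingError("deflections contain non-finite values")
        self.deflections = d
        self.sample_positions = np.asarray(self.sample_positions, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.deflections.shape[0]

    @property
    def n_frames(self) -> int:
        return self.deflections.shape[1]

    def to_csv(self, path) -> None:
        n, t = self.deflections.shape
        idx = np.indices((n, t))
        pd.DataFrame(
            {
                "sample_index": idx[0].ravel(),
                "frame_index": idx[1].ravel(),
                "deflection": self.deflections.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float, trial_id: str = "") -> "DeflectionField":
        df = pd.read_csv(path)
        n = int(df["sample_index"].max()) + 1
        t = int(df["frame_index"].max()) + 1
        d = np.full((n, t), np.nan)
        d[df["sample_index"], df["frame_index"]] = df["deflection"]
        return cls(d, np.linspace(0, 1, n), frame_rate, trial_id)


def segment_whisker_pixels(stack: FrameStack, frame_index: int, threshold="otsu"):
    """Coordinates (and intensities) of above-threshold pixels in the roi.

    ``threshold`` is either the string "otsu" (per-frame Otsu's method inside
    the roi, robust to global lighting changes) or an absolute intensity.
    Returns ``(coords, intensities)`` with coords as (n, 2) (row, col) in
    full-image pixel coordinates; an empty result is valid.
    """
    frame = np.asarray(stack.frames[frame_index], dtype=float)
    r0, r1, c0, c1 = stack.roi
    sub = frame[r0:r1, c0:c1]
    if threshold == "otsu":
        if np.ptp(sub) == 0:
            return np.empty((0, 2)), np.empty(0)
        thr = threshold_otsu(sub)
        mask = sub > thr
    else:
        mask = sub >= float(threshold)
    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr + r0, cc + c0]).astype(float)
    return coords, sub[rr, cc]


def _order_points(points: np.ndarray) -> np.ndarray:
    """Order a filament point cloud by projection onto its principal axis."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    return np.argsort(proj, kind="stable")


def fit_whisker_spline(
    points: np.ndarray,
    degree: int = 3,
    smoothing: float | None = None,
    weights: np.ndarray | None = None,
    frame_index: int | None = None,
) -> WhiskerSpline:
    """Fit a parametric planar B-spline to a whisker point cloud.

    Points are ordered by projection onto the cloud's first principal axis
    (whiskers are elongated) before fitting.  ``smoothing`` follows the
    scipy ``splprep`` convention (an upper bound on the weighted sum of
    squared residuals); the default scales with the point count, allowing
    roughly half-pixel residuals from thresholding quantisation.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < degree + 1:
        raise TrackingError(
            f"too few points ({points.shape[0]}) for a degree-{degree} spline",
            frame_index=frame_index,
        )
    order = _order_points(points)
    pts = points[order]
    w = None
    if weights is not None:
        w = np.asarray(weights, float)[order]
        peak = w.max()
        if peak > 0:
            w = w / peak  # invariant under global intensity rescaling
        else:
            w = None
    if smoothing is None:
        # allow ~half-pixel RMS residual from thresholding quantisation
        smoothing = 0.25 * points.shape[0]
    tck, u = scipy.interpolate.splprep(
        [pts[:, 0], pts[:, 1]], w=w, k=degree, s=smoothing
    )
    fitted = np.column_stack(scipy.interpolate.splev(u, tck))
    resid = np.sqrt(np.mean(np.sum((fitted - pts) ** 2, axis=1)))
    return WhiskerSpline(tck=tck, degree=degree, residual_rms=float(resid))


def resample_equidistant(curve: WhiskerSpline, n_samples: int, n_dense: int = 2000):
    """N points equally spaced in arclength along the fitted curve.

    Arclength is computed by dense evaluation and trapezoidal accumulation;
    parameter values at the target arclengths are found by monotone
    interpolation.  The first returned point is the curve's u = 0 end (caller
    fixes base orientation).
    """
    if n_samples < 2:
        raise TrackingError("need at least 2 samples")
    u = np.linspace(0.0, 1.0, n_dense)
    xy = curve(u)
    seg = np.sqrt(np.sum(np.diff(xy, axis=0) ** 2, axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise TrackingError("zero-length curve")
    targets = np.linspace(0.0, arc[-1], n_samples)
    u_t = np.interp(targets, arc, u)
    return curve(u_t)


def _orient_base_first(samples: np.ndarray, stack: FrameStack) -> np.ndarray:
    """Flip the sample order so index 0 is nearest the designated base edge."""
    r0, r1, c0, c1 = stack.roi
    edge = stack.base_edge
    first, last = samples[0], samples[-1]
    if edge == "left":
        d_first, d_last = first[1] - c0, last[1] - c0
    elif edge == "right":
        d_first, d_last = c1 - first[1], c1 - last[1]
    elif edge == "top":
        d_first, d_last = first[0] - r0, last[0] - r0
    else:
        d_first, d_last = r1 - first[0], r1 - last[0]
    return samples[::-1] if d_last < d_first else samples


def track_frames(
    stack: FrameStack,
    n_samples: int = 25,
    degree: int = 3,
    smoothing: float | None = None,
    threshold="otsu",
) -> WhiskerTrace:
    """Segment, spline-fit, and equidistantly resample every frame."""
    splines = []
    all_samples = np.empty((stack.n_frames, n_samples, 2))
    for t in range(stack.n_frames):
        coords, intens = segment_whisker_pixels(stack, t, threshold=threshold)
        if coords.shape[0] < degree + 1:
            raise TrackingError(
                f"frame {t}: only {coords.shape[0]} whisker pixels found",
                frame_index=t,
            )
        spline = fit_whisker_spline(
            coords, degree=degree, smoothing=smoothing, weights=intens, frame_index=t
        )
        samples = resample_equidistant(spline, n_samples)
        all_samples[t] = _orient_base_first(samples, stack)
        splines.append(spline)
    return WhiskerTrace(splines=splines, samples=all_samples, spline_degree=degree)


def extract_deflections(
    stack: FrameStack, trace: WhiskerTrace, trial_id: str = ""
) -> DeflectionField:
    """Transverse deflection of each arclength sample over time.

    Deflection of sample i at frame t is the image-row coordinate of that
    sample minus its temporal mean across the trial (rest-shape removal).
    """
    rows = trace.samples[:, :, 0].T  # (N, T)
    deflections = rows - rows.mean(axis=1, keepdims=True)
    positions = np.linspace(0.0, 1.0, trace.n_samples)
    return DeflectionField(deflections, positions, stack.frame_rate, trial_id)


def track_stack(stack: FrameStack, trial_id: str = "", **kwargs) -> DeflectionField:
    """Convenience wrapper: track all frames and return the deflection field."""
    trace = track_frames(stack, **kwargs)
    return extract_deflections(stack, trace, trial_id=trial_id)


def load_frame_stack(frames_path, meta_path=None) -> FrameStack:
    """Read a multi-page TIFF or a directory of numbered PNG/TIFF frames.

    The optional JSON sidecar provides frame_rate, roi and base_edge.
    """
    import imageio.v3 as iio
    import tifffile

    p = Path(frames_path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise TrackingError(f"no frames found in {p}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    return FrameStack(
        frames=frames,
        frame_rate=float(meta.get("frame_rate", 2000.0)),
        roi=tuple(meta["roi"]) if "roi" in meta else None,
        base_edge=meta.get("base_edge", "left"),
        metadata=meta,
    )


def save_frame_stack(stack: FrameStack, frames_path, meta_path=None) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    frames = stack.frames
    if frames.dtype != np.uint8:
        scale = 255.0 if frames.max() <= 1.0 else 1.0
        frames = np.clip(frames * scale, 0, 255).astype(np.uint8)
    tifffile.imwrite(frames_path, frames, photometric="minisblack")
    if meta_path is not None:
        meta = {
            "frame_rate": stack.frame_rate,
            "roi": list(stack.roi),
            "base_edge": stack.base_edge,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))
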