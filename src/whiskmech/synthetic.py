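"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the ex vivo shaker-and-camera experiment: band-limited
white-noise base displacement (2 kHz sampling, Gaussian low-pass at 1 kHz,
2.25 s trials), linear-time-invariant beam responses along the shaft derived
from a simulated FRF, rendered bright-whisker-on-dark-background frame
stacks at 2000 fps, exponential photobleaching intensity traces, treatment
perturbations of whisker parameters (fluorescent dye vs. a severe nail-polish
analog), and two-alternative vibrotactile behavioural sessions.

All randomness is driven by a single integer seed per call; multi-trial sets
split streams as seed + trial index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal

from .beam import ComplexFRF, MaterialParams, WhiskerGeometry
from .tracking import DeflectionField, FrameStack

__all__ = [
    "StimulusTrace",
    "PhotobleachTrace",
    "BehaviorSession",
    "gen_stimulus",
    "synth_deflection_field",
    "render_frames",
    "perturb_whisker",
    "gen_photobleach_trace",
    "gen_behavior_session",
]

# Measured photobleaching decay of the fluorescent dye under the blue lamp:
# about 14 hours, i.e. about 50,000 seconds.
DEFAULT_BLEACH_TAU_S = 50_000.0

# Allometric taper rule for simulated whisker sets: base radius grows with
# shaft length at ~2 um per mm (the 30 mm D2 default has a 60 um base); the
# tip stays a few microns regardless of length.
ALLOMETRY_UM_PER_MM = 2.0

# Canonical simulated whisker sets.  The trio mirrors the classic two-long /
# one-short length comparison (lengths in mm); the ladder is a length-ordered
# set with uniform ~4.5% length steps, the regime in which pairwise mFRF
# similarity resolves length disparity (see docs/methods.md).
LENGTH_TRIO_MM = (53.0, 56.0, 23.0)
LENGTH_LADDER_MM = (45.0, 47.0, 49.1, 51.3, 53.6, 56.0)


def whisker_set_configs(lengths_mm, tip_radius_um: float = 3.0) -> list:
    """Per-whisker config dicts for a simulated set, allometric radii."""
    return [
        {
            "label": f"W{length:g}",
            "length_mm": float(length),
            "base_radius_um": ALLOMETRY_UM_PER_MM * float(length),
            "tip_radius_um": tip_radius_um,
        }
        for length in lengths_mm
    ]


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class StimulusTrace:
    """Sampled base displacement delta(t) in arbitrary amplitude units."""

    displacement: np.ndarray
    sample_rate: float
    duration: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.displacement.size) / self.sample_rate


@dataclass(frozen=True)
class PhotobleachTrace:
    """Fluorescence intensity normalised to its initial value."""

    times: np.ndarray
    normalized_intensity: np.ndarray


@dataclass(frozen=True)
class BehaviorSession:
    """Two-alternative vibrotactile discrimination trials.

    ``trials`` columns: trial, speed_left, speed_right, correct, chosen
    (sides are "left"/"right"; correct is the side with larger mean speed).
    """

    trials: pd.DataFrame
    agent: str


def gen_stimulus(
    sample_rate: float = 2000.0,
    duration: float = 2.25,
    cutoff: float = 1000.0,
    seed=None,
    amplitude: float = 1.0,
) -> StimulusTrace:
    """Gaussian-filtered white-noise base displacement.

    White Gaussian noise is shaped in the frequency domain by a Gaussian
    transfer function with gain 1/2 at ``cutoff``; the trace is de-meaned and
    rescaled to standard deviation ``amplitude``.  Bit-reproducible by seed.
    """
    if duration <= 0 or sample_rate <= 0:
        raise SynthesisError("duration and sample_rate must be positive")
    if cutoff > sample_rate / 2:
        raise SynthesisError("cutoff above Nyquist")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = np.exp2(-((freqs / cutoff) ** 2))  # gain 0.5 at the cutoff
    shaped = np.fft.irfft(np.fft.rfft(white) * gain, n=n)
    shaped -= shaped.mean()
    sd = shaped.std()
    if sd > 0:
        shaped *= amplitude / sd
    return StimulusTrace(shaped, sample_rate, duration)


def _interp_complex_frf(
    frf: ComplexFRF, positions_norm: np.ndarray, frequencies: np.ndarray
) -> np.ndarray:
    """H interpolated to normalised positions x arbitrary frequencies.

    Below the FRF grid the quasi-static limit H = 1 applies; above it the
    edge value is held.
    """
    src_pos = frf.positions / frf.positions[-1]
    h_pos = np.empty((positions_norm.size, frf.frequencies.size), dtype=complex)
    for k in range(frf.frequencies.size):
        h_pos[:, k] = np.interp(positions_norm, src_pos, frf.values[:, k].real) + 1j * np.interp(
            positions_norm, src_pos, frf.values[:, k].imag
        )
    out = np.empty((positions_norm.size, frequencies.size), dtype=complex)
    for i in range(positions_norm.size):
        out[i] = np.interp(
            frequencies, frf.frequencies, h_pos[i].real, left=1.0
        ) + 1j * np.interp(frequencies, frf.frequencies, h_pos[i].imag, left=0.0)
    return out


def synth_deflection_field(
    frf: ComplexFRF,
    stimulus: StimulusTrace,
    n_positions: int = 25,
    seed_noise=None,
    pixel_noise_sd: float = 0.0,
    trial_id: str = "",
) -> DeflectionField:
    """LTI response of every shaft position to the base stimulus.

    Each position's series is the inverse FFT of the stimulus spectrum times
    H at that position (H interpolated to ``n_positions`` equidistant
    normalised arclengths).  The base row is the stimulus itself; optional
    additive Gaussian measurement noise emulates tracking error.
    """
    if stimulus.sample_rate / 2 < frf.frequencies[-1] * (1 - 1e-9):
        raise SynthesisError("stimulus Nyquist below the FRF's maximum frequency")
    x = stimulus.displacement
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / stimulus.sample_rate)
    positions = np.linspace(0.0, 1.0, n_positions)
    h = _interp_complex_frf(frf, positions, freqs)
    spectrum = np.fft.rfft(x)
    field = np.fft.irfft(h * spectrum[np.newaxis, :], n=n, axis=1)
    field[0] = x  # base row is the input by definition
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed_noise)
        field = field + rng.normal(0.0, pixel_noise_sd, size=field.shape)
    return DeflectionField(field, positions, stimulus.sample_rate, trial_id)


def _default_rest_curve(image_size, margin: int = 6, n_points: int = 200) -> np.ndarray:
    h, w = image_size
    cols = np.linspace(margin, w - 1 - margin, n_points)
    rows = np.full_like(cols, h / 2.0)
    return np.column_stack([rows, cols])


def render_frames(
    field: DeflectionField,
    rest_curve: np.ndarray | None = None,
    image_size=(128, 256),
    line_brightness: float = 1.0,
    background_noise_sd: float = 0.01,
    seed=None,
    line_sigma: float = 0.8,
) -> FrameStack:
    """Render a deflection field as a bright-curve-on-dark-noise frame stack.

    Per frame the rest curve (base at the left by default, columns strictly
    increasing base to tip) is displaced vertically by the frame's
    deflections, interpolated along normalised arclength, and drawn as an
    anti-aliased Gaussian-profile ridge: intensity in each occupied column is
    ``brightness * exp(-d^2 / (2 sigma^2))`` with ``d`` the vertical distance
    to the curve (near-exact for the shallow slopes of a shaken whisker).
    Metadata records the frame rate and a reference to the ground-truth
    field.
    """
    h, w = image_size
    if rest_curve is None:
        rest_curve = _default_rest_curve(image_size)
    rest_curve = np.asarray(rest_curve, dtype=float)
    if np.any(np.diff(rest_curve[:, 1]) <= 0):
        raise SynthesisError("rest curve columns must strictly increase base to tip")
    seg = np.sqrt(np.sum(np.diff(rest_curve, axis=0) ** 2, axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    arc_norm = arc / arc[-1]
    c_lo = int(np.ceil(rest_curve[0, 1]))
    c_hi = int(np.floor(rest_curve[-1, 1]))
    if c_lo < 1 or c_hi > w - 2:
        raise SynthesisError("rest curve leaves image bounds")
    cols = np.arange(c_lo, c_hi + 1)
    rest_rows = np.interp(cols, rest_curve[:, 1], rest_curve[:, 0])
    arc_at_cols = np.interp(cols, rest_curve[:, 1], arc_norm)
    rng = np.random.default_rng(seed)
    t_frames = field.n_frames
    frames = np.empty((t_frames, h, w))
    pad = int(np.ceil(4.0 * line_sigma))  # ridge support half-width in rows
    offsets = np.arange(-pad, pad + 1)[:, np.newaxis]
    col_idx = np.broadcast_to(cols, (offsets.size, cols.size))
    for t in range(t_frames):
        defl = np.interp(arc_at_cols, field.sample_positions, field.deflections[:, t])
        rows = rest_rows + defl
        if rows.min() < pad or rows.max() > h - 1 - pad:
            raise SynthesisError(f"rendered curve leaves image bounds at frame {t}")
        ri = np.round(rows).astype(int)
        win = ri[np.newaxis, :] + offsets
        vals = line_brightness * np.exp(
            -((win - rows[np.newaxis, :]) ** 2) / (2 * line_sigma**2)
        )
        if background_noise_sd > 0:
            img = rng.normal(0.0, background_noise_sd, size=(h, w))
        else:
            img = np.zeros((h, w))
        img[win, col_idx] += vals
        frames[t] = np.clip(img, 0.0, 1.0)
    return FrameStack(
        frames=frames,
        frame_rate=field.frame_rate,
        roi=None,
        base_edge="left",
        metadata={"ground_truth_field": field, "seed": seed},
    )


def perturb_whisker(
    geom: WhiskerGeometry,
    mat: MaterialParams,
    treatment: str,
    magnitude: float | None = None,
):
    """Parameter change modelling a whisker surface treatment.

    ``dye``: the fluorescent dye deposits a mass bounded by 0.7% of the
    shaft, modelled as a uniform density increase by ``magnitude`` (default
    0.007) with geometry and stiffness unchanged.  ``polish``: a severe
    coating analog scaling density by ``1 + 0.3*magnitude`` and Young's
    modulus by ``1 + 2.0*magnitude`` (defaults +30% and +200% at
    magnitude 1), used only for qualitative contrast.
    """
    if treatment == "dye":
        m = 0.007 if magnitude is None else magnitude
        if m < 0:
            raise SynthesisError("magnitude must be >= 0")
        return geom, replace(mat, density_rho=mat.density_rho * (1.0 + m))
    if treatment == "polish":
        m = 1.0 if magnitude is None else magnitude
        if m < 0:
            raise SynthesisError("magnitude must be >= 0")
        return geom, replace(
            mat,
            density_rho=mat.density_rho * (1.0 + 0.3 * m),
            youngs_E=mat.youngs_E * (1.0 + 2.0 * m),
        )
    raise SynthesisError(f"unknown treatment {treatment!r}")


def gen_photobleach_trace(
    time_constant: float = DEFAULT_BLEACH_TAU_S,
    duration: float = 7 * 3600.0,
    sampling: float = 60.0,
    noise_sd: float = 0.01,
    seed=None,
) -> PhotobleachTrace:
    """Exponentially decaying normalised fluorescence with Gaussian noise.

    ``intensity(t) = exp(-t / tau) + noise``, clipped to stay positive;
    samples run from 0 to ``duration`` inclusive every ``sampling`` seconds.
    """
    if time_constant <= 0 or duration <= 0 or sampling <= 0:
        raise SynthesisError("time constant, duration and sampling must be positive")
    times = np.arange(0.0, duration + sampling / 2, sampling)
    intensity = np.exp(-times / time_constant)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=times.size)
    intensity = np.maximum(intensity, 1e-6)
    return PhotobleachTrace(times, intensity)


@dataclass(frozen=True)
class BehaviorStimulusSpec:
    """Vibrotactile stimulus recipe: Gaussian position noise, Butterworth
    low-pass at 150 Hz (order 4, zero-phase), amplitudes drawn per trial."""

    sample_rate: float = 2000.0
    duration: float = 0.5
    cutoff: float = 150.0
    order: int = 4
    amplitude_range: tuple = (0.5, 2.0)


def gen_behavior_session(
    n_trials: int,
    agent: str = "random",
    stimulus_spec: BehaviorStimulusSpec | None = None,
    seed=None,
    agent_noise_sd: float = 0.5,
) -> BehaviorSession:
    """Simulate a two-alternative mean-speed discrimination session.

    Per trial two stochastic vibrations with distinct nominal amplitudes are
    generated; the mean speed of a stimulus is its time-averaged absolute
    velocity and the rewarded side is the one with the larger mean speed.
    Agents: ``random`` flips a coin, ``ideal`` always picks the rewarded
    side, ``noisy`` picks it iff the observed speed difference plus Gaussian
    noise (sd ``agent_noise_sd``, in speed units) has the right sign.
    """
    if n_trials < 1:
        raise SynthesisError("n_trials must be >= 1")
    if agent not in ("random", "ideal", "noisy"):
        raise SynthesisError(f"unknown agent {agent!r}")
    spec = stimulus_spec or BehaviorStimulusSpec()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.sample_rate))
    sos = scipy.signal.butter(
        spec.order, spec.cutoff, btype="low", fs=spec.sample_rate, output="sos"
    )
    lo, hi = spec.amplitude_range

    def _draw(count: int) -> np.ndarray:
        amps = rng.uniform(lo, hi, size=(count, 2, 1))
        raw = rng.standard_normal((count, 2, n)) * amps
        filtered = scipy.signal.sosfiltfilt(sos, raw, axis=-1)
        return np.mean(np.abs(np.diff(filtered, axis=-1)), axis=-1) * spec.sample_rate

    speeds = _draw(n_trials)
    tied = speeds[:, 0] == speeds[:, 1]
    while np.any(tied):  # equal nominal speeds: reject and resample
        speeds[tied] = _draw(int(tied.sum()))
        tied = speeds[:, 0] == speeds[:, 1]
    correct = np.where(speeds[:, 0] > speeds[:, 1], "left", "right")
    if agent == "ideal":
        chosen = correct.copy()
    elif agent == "random":
        chosen = np.where(rng.random(n_trials) < 0.5, "left", "right")
    else:
        observed = speeds[:, 0] - speeds[:, 1] + rng.normal(0.0, agent_noise_sd, n_trials)
        chosen = np.where(observed > 0, "left", "right")
    df = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "speed_left": speeds[:, 0],
            "speed_right": speeds[:, 1],
            "correct": correct,
            "chosen": chosen,
        }
    )
    return BehaviorSession(df, agent)
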