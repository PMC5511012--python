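"""End-to-end workflows: simulation study and video-to-similarity analysis.

``run_simulation_study`` goes whisker parameters -> FEM FRF -> synthesized
noise trials -> Welch/H1 mFRF estimates -> pairwise similarity matrix
(whiskers ordered by length) with diagonal-band means, mirroring the
simulated arm of the fingerprinting experiment.  ``run_video_analysis`` runs
the measurement arm: tracked frame stacks -> deflection fields -> averaged
mFRFs -> the same similarity outputs.  Both emit a machine-readable report
of every setting and seed so a run can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beam import FEMesh, FrequencyGrid, solve_frf
from .config import DEFAULT_CONFIG, geometry_from_config, material_from_config
from .spectral import (
    MagnitudeFRF,
    SimilarityMatrix,
    WelchSpec,
    average_mfrf,
    band_means,
    estimate_mfrf,
    similarity_matrix,
)
from .synthetic import gen_stimulus, synth_deflection_field
from .tracking import track_stack

__all__ = ["RunConfig", "StudyResult", "run_simulation_study", "run_video_analysis"]

logger = logging.getLogger("whiskmech")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Settings for a multi-whisker study.

    ``whiskers`` is a list of per-whisker config dicts (unit keys as in
    :mod:`whiskmech.config`; unspecified keys fall back to the defaults).
    Every stochastic stage derives its stream from ``seed``.
    """

    whiskers: list
    seed: int = 0
    n_trials: int = 10
    sample_rate: float = 2000.0
    trial_duration: float = 2.25
    stimulus_cutoff: float = 1000.0
    n_positions: int = 25
    pixel_noise_sd: float = 0.0
    welch: WelchSpec = dc_field(default_factory=WelchSpec)
    tracking: dict = dc_field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        labels = [w.get("label", f"W{i + 1}") for i, w in enumerate(self.whiskers)]
        if len(set(labels)) != len(labels):
            raise PipelineError("whisker labels must be unique")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        welch = WelchSpec(**raw.pop("welch", {}))
        return cls(welch=welch, **raw)


@dataclass
class StudyResult:
    similarity: SimilarityMatrix
    band_theta: np.ndarray
    mfrfs: list
    report: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labels = list(self.similarity.labels)
        pd.DataFrame(self.similarity.r_squared, index=labels, columns=labels).to_csv(
            out / "similarity.csv"
        )
        pd.DataFrame(
            {"offset": np.arange(1, len(self.band_theta) + 1), "theta": self.band_theta}
        ).to_csv(out / "band_means.csv", index=False)
        for m in self.mfrfs:
            mfrf_to_csv(m, out / f"mfrf_{m.label}.csv")
        (out / "report.json").write_text(json.dumps(self.report, indent=2, sort_keys=True))


def mfrf_to_csv(m: MagnitudeFRF, path) -> None:
    ff, pp = np.meshgrid(m.frequencies, m.positions, indexing="ij")
    pd.DataFrame(
        {
            "frequency_hz": ff.ravel(),
            "position_norm": pp.ravel(),
            "magnitude": m.magnitudes.ravel(),
        }
    ).to_csv(path, index=False)


def mfrf_from_csv(path, label: str = "", n_trials_averaged: int = 1) -> MagnitudeFRF:
    df = pd.read_csv(path)
    freqs = np.unique(df["frequency_hz"])
    pos = np.unique(df["position_norm"])
    mags = (
        df.sort_values(["frequency_hz", "position_norm"])["magnitude"]
        .to_numpy()
        .reshape(freqs.size, pos.size)
    )
    return MagnitudeFRF(mags, freqs, pos, n_trials_averaged, label or Path(path).stem)


def _full_whisker_config(w: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(w)
    return cfg


def _config_digest(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _trial_seed(base_seed: int, whisker_idx: int, trial: int) -> int:
    # deterministic per-(whisker, trial) stream; stays below 2**31
    return (base_seed * 1_000_003 + whisker_idx * 1_009 + trial) % (2**31 - 1)


def simulate_whisker_mfrf(
    cfg: dict,
    config: RunConfig,
    whisker_idx: int,
) -> MagnitudeFRF:
    """FEM FRF -> n_trials synthesized noise trials -> averaged mFRF."""
    geom = geometry_from_config(cfg)
    mat = material_from_config(cfg)
    mesh = FEMesh.uniform(geom.length_L, int(cfg["n_elements"]))
    grid = FrequencyGrid.regular(cfg["f_min_hz"], cfg["f_max_hz"], cfg["df_hz"])
    frf = solve_frf(geom, mat, mesh, grid)
    per_trial = []
    for t in range(config.n_trials):
        seed = _trial_seed(config.seed, whisker_idx, t)
        stim = gen_stimulus(
            sample_rate=config.sample_rate,
            duration=config.trial_duration,
            cutoff=config.stimulus_cutoff,
            seed=seed,
        )
        fld = synth_deflection_field(
            frf,
            stim,
            n_positions=config.n_positions,
            seed_noise=seed + 1,
            pixel_noise_sd=config.pixel_noise_sd,
            trial_id=f"{cfg.get('label', whisker_idx)}_t{t}",
        )
        per_trial.append(estimate_mfrf(fld, config.welch))
    avg = average_mfrf(per_trial)
    return replace(avg, label=str(cfg.get("label", f"W{whisker_idx + 1}")))


def _report(config: RunConfig, kind: str, labels) -> dict:
    payload = {
        "kind": kind,
        "whiskmech_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_trials": config.n_trials,
        "sample_rate": config.sample_rate,
        "trial_duration": config.trial_duration,
        "stimulus_cutoff": config.stimulus_cutoff,
        "n_positions": config.n_positions,
        "pixel_noise_sd": config.pixel_noise_sd,
        "welch": asdict(config.welch),
        "whiskers": [_full_whisker_config(w) for w in config.whiskers],
        "labels_by_length": list(labels),
    }
    payload["config_hash"] = _config_digest(payload)
    return payload


def _stage(name: str, t0: float) -> None:
    logger.info("%s finished in %.2f s", name, time.perf_counter() - t0)


def run_simulation_study(config: RunConfig) -> StudyResult:
    """Similarity fingerprint of a simulated whisker set, ordered by length."""
    if len(config.whiskers) < 2:
        raise PipelineError("need at least 2 whiskers")
    cfgs = [_full_whisker_config(w) for w in config.whiskers]
    order = np.argsort([c["length_mm"] for c in cfgs], kind="stable")
    cfgs = [cfgs[i] for i in order]
    mfrfs = []
    for i, cfg in enumerate(cfgs):
        t0 = time.perf_counter()
        try:
            mfrfs.append(simulate_whisker_mfrf(cfg, config, i))
        except Exception as exc:
            raise PipelineError(
                f"simulation stage failed for whisker {cfg.get('label', i)}: {exc}"
            ) from exc
        _stage(f"whisker {cfg.get('label', i)}", t0)
    labels = [m.label for m in mfrfs]
    sim = similarity_matrix(mfrfs, labels)
    theta = band_means(sim).theta
    result = StudyResult(sim, theta, mfrfs, _report(config, "simulation_study", labels))
    if config.out_dir:
        result.save(config.out_dir)
    return result


def run_video_analysis(config: RunConfig, stacks: dict) -> StudyResult:
    """Similarity fingerprint from tracked frame stacks.

    ``stacks`` maps whisker label -> list of FrameStack trials.  A whisker is
    dropped only if every one of its trials fails tracking; per-trial
    failures are logged and reported.
    """
    if not stacks:
        raise PipelineError("empty trial list")
    cfg_by_label = {
        str(w.get("label", f"W{i + 1}")): _full_whisker_config(w)
        for i, w in enumerate(config.whiskers)
    }
    order = sorted(
        stacks.keys(), key=lambda lab: cfg_by_label.get(lab, {}).get("length_mm", 0.0)
    )
    mfrfs, failures = [], {}
    for label in order:
        trials = stacks[label]
        if not trials:
            raise PipelineError(f"whisker {label}: empty trial list")
        per_trial = []
        for t, stack in enumerate(trials):
            t0 = time.perf_counter()
            try:
                fld = track_stack(stack, trial_id=f"{label}_t{t}", **config.tracking)
                per_trial.append(estimate_mfrf(fld, config.welch))
            except Exception as exc:
                failures.setdefault(label, []).append(f"trial {t}: {exc}")
                logger.warning("whisker %s trial %d failed: %s", label, t, exc)
                continue
            _stage(f"whisker {label} trial {t}", t0)
        if not per_trial:
            logger.warning("whisker %s dropped: all trials failed", label)
            continue
        mfrfs.append(replace(average_mfrf(per_trial), label=label))
    if len(mfrfs) < 2:
        raise PipelineError("fewer than 2 whiskers tracked successfully")
    labels = [m.label for m in mfrfs]
    sim = similarity_matrix(mfrfs, labels)
    theta = band_means(sim).theta
    report = _report(config, "video_analysis", labels)
    report["tracking_failures"] = failures
    result = StudyResult(sim, theta, mfrfs, report)
    if config.out_dir:
        result.save(config.out_dir)
    return result


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
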