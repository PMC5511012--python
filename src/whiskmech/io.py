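"""Plain-text table readers/writers for the pipeline's intermediate objects."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beam import ComplexFRF, ModalSet

__all__ = ["frf_to_csv", "frf_from_csv", "modes_to_frame"]


def frf_to_csv(frf: ComplexFRF, path) -> None:
    """Long-format FRF table: position_m, frequency_hz, re_H, im_H, abs_H."""
    pp, ff = np.meshgrid(frf.positions, frf.frequencies, indexing="ij")
    pd.DataFrame(
        {
            "position_m": pp.ravel(),
            "frequency_hz": ff.ravel(),
            "re_H": frf.values.real.ravel(),
            "im_H": frf.values.imag.ravel(),
            "abs_H": np.abs(frf.values).ravel(),
        }
    ).to_csv(path, index=False)


def frf_from_csv(path) -> ComplexFRF:
    df = pd.read_csv(path)
    pos = np.unique(df["position_m"])
    freqs = np.unique(df["frequency_hz"])
    df = df.sort_values(["position_m", "frequency_hz"])
    vals = (df["re_H"].to_numpy() + 1j * df["im_H"].to_numpy()).reshape(pos.size, freqs.size)
    return ComplexFRF(pos, freqs, vals)


def modes_to_frame(modes: ModalSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": np.arange(1, modes.modal_frequencies.size + 1),
            "frequency_hz": modes.modal_frequencies,
        }
    )
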