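"""Configuration loading with explicit unit keys.

Internally everything is strict SI (metres, pascals, kg/m^3, seconds); config
files speak the lab's units (mm, um, GPa) through explicit key names.  JSON
and YAML are both accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .beam import FEMesh, FrequencyGrid, MaterialParams, WhiskerGeometry

__all__ = [
    "DEFAULT_CONFIG",
    "load_config_file",
    "geometry_from_config",
    "material_from_config",
    "mesh_from_config",
    "grid_from_config",
    "beam_setup",
]

# Default D2-like whisker: order-of-magnitude literature geometry, keratin-like
# elastic parameters, light Rayleigh damping; FRF grid up to the 2000 fps
# camera Nyquist.
DEFAULT_CONFIG = {
    "label": "D2",
    "length_mm": 30.0,
    "base_radius_um": 60.0,
    "tip_radius_um": 3.0,
    "E_GPa": 3.0,
    "rho_kg_m3": 1200.0,
    "alpha_per_s": 10.0,
    "beta_s": 2e-5,
    "n_elements": 200,
    "f_min_hz": 1.0,
    "f_max_hz": 1000.0,
    "df_hz": 1.0,
}


def load_config_file(path) -> dict:
    """Read a JSON or YAML config and fill unspecified keys with defaults."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        user = json.loads(text)
    else:
        user = yaml.safe_load(text)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user or {})
    return cfg


def geometry_from_config(cfg: dict) -> WhiskerGeometry:
    return WhiskerGeometry(
        length_L=cfg["length_mm"] * 1e-3,
        base_radius_rb=cfg["base_radius_um"] * 1e-6,
        tip_radius_rt=cfg["tip_radius_um"] * 1e-6,
        label=str(cfg.get("label", "")),
    )


def material_from_config(cfg: dict) -> MaterialParams:
    return MaterialParams(
        youngs_E=cfg["E_GPa"] * 1e9,
        density_rho=cfg["rho_kg_m3"],
        alpha_mass_damping=cfg["alpha_per_s"],
        beta_stiffness_damping=cfg["beta_s"],
    )


def mesh_from_config(cfg: dict) -> FEMesh:
    return FEMesh.uniform(cfg["length_mm"] * 1e-3, int(cfg["n_elements"]))


def grid_from_config(cfg: dict) -> FrequencyGrid:
    return FrequencyGrid.regular(cfg["f_min_hz"], cfg["f_max_hz"], cfg["df_hz"])


def beam_setup(cfg: dict | None = None):
    """(geometry, material, mesh, grid) from a config dict (defaults if None)."""
    full = dict(DEFAULT_CONFIG)
    full.update(cfg or {})
    return (
        geometry_from_config(full),
        material_from_config(full),
        mesh_from_config(full),
        grid_from_config(full),
    )
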