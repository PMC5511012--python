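"""Shared fixtures: default whisker, FEM solutions, and rendered videos.

Expensive FEM solves and renders are session-scoped so the suite reuses
them; everything is generated programmatically with fixed seeds.
"""

import numpy as np
import pytest

import whiskmech as wm
from whiskmech.config import beam_setup


@pytest.fixture(scope="session")
def d2_geometry():
    return wm.WhiskerGeometry(0.03, 60e-6, 3e-6, label="D2")


@pytest.fixture(scope="session")
def d2_material():
    return wm.MaterialParams(3.0e9, 1200.0, 10.0, 2e-5)


@pytest.fixture(scope="session")
def d2_mesh(d2_geometry):
    return wm.FEMesh.uniform(d2_geometry.length_L, 200)


@pytest.fixture(scope="session")
def default_grid():
    return wm.FrequencyGrid.regular(1.0, 1000.0, 1.0)


@pytest.fixture(scope="session")
def d2_frf(d2_geometry, d2_material, d2_mesh, default_grid):
    return wm.solve_frf(d2_geometry, d2_material, d2_mesh, default_grid)


@pytest.fixture(scope="session")
def uniform_geometry():
    # untapered rod: closed-form clamped-free frequencies apply
    return wm.WhiskerGeometry(0.03, 60e-6, 60e-6, label="uniform")


@pytest.fixture(scope="session")
def damped_video_material():
    # video round-trip fixture: heavier stiffness damping keeps resonant tip
    # excursions inside the frame while the base stays resolvable
    return wm.MaterialParams(3.0e9, 1200.0, 10.0, 3e-4)


@pytest.fixture(scope="session")
def damped_video_frf(d2_geometry, damped_video_material, d2_mesh, default_grid):
    return wm.solve_frf(d2_geometry, damped_video_material, d2_mesh, default_grid)


@pytest.fixture(scope="session")
def sine_translation_stack():
    """200-frame video of a whisker rigidly translating as a 37 Hz sine."""
    fps, n, t_frames = 2000.0, 25, 200
    t = np.arange(t_frames) / fps
    motion = 6.0 * np.sin(2 * np.pi * 37.0 * t)
    motion = motion - motion.mean()
    field = wm.DeflectionField(
        np.tile(motion, (n, 1)), np.linspace(0, 1, n), fps, "sine"
    )
    stack = wm.render_frames(
        field, image_size=(128, 256), background_noise_sd=0.01, seed=3
    )
    return stack, field


def closed_form_cantilever_lambdas(n: int):
    """Roots of cos(lam)*cosh(lam) = -1 by bisection (independent oracle)."""
    roots = []
    f = lambda lam: np.cos(lam) * np.cosh(lam) + 1.0
    lo = 1e-6
    step = 0.05
    x = lo
    while len(roots) < n:
        if f(x) * f(x + step) < 0:
            a, b = x, x + step
            for _ in range(200):
                m = 0.5 * (a + b)
                if f(a) * f(m) <= 0:
                    b = m
                else:
                    a = m
            roots.append(0.5 * (a + b))
        x += step
    return np.array(roots)


def uniform_cantilever_frequencies(geom, mat, n: int):
    """Closed-form clamped-free frequencies f_n = lam_n^2/(2 pi L^2) sqrt(EJ/(rho A))."""
    lam = closed_form_cantilever_lambdas(n)
    r = geom.base_radius_rb
    area = np.pi * r**2
    inertia = np.pi * r**4 / 4
    return (
        lam**2
        / (2 * np.pi * geom.length_L**2)
        * np.sqrt(mat.youngs_E * inertia / (mat.density_rho * area))
    )


@pytest.fixture(scope="session")
def beam_defaults():
    return beam_setup(None)
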