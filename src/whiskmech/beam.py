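"""Frequency-domain finite-element model of a tapered whisker.

A rodent whisker is modelled as a linearly tapered Euler-Bernoulli cantilever
with Rayleigh (mass- and stiffness-proportional) viscous damping, clamped at
the follicle end and driven by an imposed transverse base displacement, with a
free tip.  The governing equation for the transverse deflection ``v(x, t)`` is

    rho*A(x) * (v_tt + alpha*v_t) + d^2/dx^2 [ E*J(x) * (v_xx + beta*v_txx) ] = 0

with boundary conditions ``v(0,t) = delta(t)``, ``v_x(0,t) = 0`` (clamped,
shaken base) and ``v_xx(L,t) = v_xxx(L,t) = 0`` (free tip).  The radius tapers
linearly from base to tip, ``r(x) = rb - (rb - rt) x / L``, giving the
cross-section area ``A(x) = pi r^2`` and second moment ``J(x) = pi r^4 / 4``.

In the Laplace domain the response to a unit base displacement defines the
frequency response function (FRF) ``H(x, s) = V(x, s) / Delta(s)`` evaluated
at ``s = i omega``.  The beam is discretised with two-node Hermite-cubic beam
elements (deflection + rotation per node); the FRF is obtained by solving the
complex banded system ``[(s^2 + s alpha) M + (1 + s beta) K] u = 0`` with the
base deflection constrained to one and the base rotation to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse

__all__ = [
    "WhiskerGeometry",
    "MaterialParams",
    "FrequencyGrid",
    "FEMesh",
    "ComplexFRF",
    "ModalSet",
    "taper_profile",
    "assemble_beam_system",
    "solve_frf",
    "modal_frequencies",
]


class BeamModelError(ValueError):
    """Invalid geometry, mesh, or an unsolvable (singular) frequency point."""


@dataclass(frozen=True)
class WhiskerGeometry:
    """Length and linear taper of a whisker shaft, in metres."""

    length_L: float
    base_radius_rb: float
    tip_radius_rt: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.length_L > 0:
            raise BeamModelError(f"length_L must be > 0, got {self.length_L}")
        if not self.tip_radius_rt > 0:
            raise BeamModelError(f"tip_radius_rt must be > 0, got {self.tip_radius_rt}")
        if self.base_radius_rb < self.tip_radius_rt:
            raise BeamModelError("base_radius_rb must be >= tip_radius_rt")


@dataclass(frozen=True)
class MaterialParams:
    """Elastic and Rayleigh-damping parameters of the keratinous shaft.

    alpha_mass_damping has units 1/s, beta_stiffness_damping has units s.
    """

    youngs_E: float
    density_rho: float
    alpha_mass_damping: float = 0.0
    beta_stiffness_damping: float = 0.0

    def __post_init__(self) -> None:
        if not self.youngs_E > 0:
            raise BeamModelError("youngs_E must be > 0")
        if not self.density_rho > 0:
            raise BeamModelError("density_rho must be > 0")
        if self.alpha_mass_damping < 0 or self.beta_stiffness_damping < 0:
            raise BeamModelError("damping coefficients must be >= 0")


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, non-negative evaluation frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.size < 2:
            raise BeamModelError("frequency grid needs at least 2 points")
        if f[0] < 0 or np.any(np.diff(f) <= 0):
            raise BeamModelError("frequencies must be non-negative and strictly increasing")

    @classmethod
    def regular(cls, f_min: float, f_max: float, df: float) -> "FrequencyGrid":
        n = int(np.floor((f_max - f_min) / df + 1e-9)) + 1
        return cls(f_min + df * np.arange(n))

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies


@dataclass(frozen=True)
class FEMesh:
    """Node positions along the shaft, base (0) to tip (L), metres."""

    node_positions: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.node_positions, dtype=float)
        object.__setattr__(self, "node_positions", x)
        if x.size < 5:
            raise BeamModelError("mesh needs at least 4 elements")
        if x[0] != 0 or np.any(np.diff(x) <= 0):
            raise BeamModelError("node positions must strictly increase from 0")

    @classmethod
    def uniform(cls, length: float, n_elements: int = 200) -> "FEMesh":
        return cls(np.linspace(0.0, length, n_elements + 1))

    @property
    def element_count(self) -> int:
        return self.node_positions.size - 1


@dataclass(frozen=True)
class ComplexFRF:
    """H(x, omega): complex displacement ratio on a position x frequency grid.

    ``values[i, k]`` is the response at ``positions[i]`` (metres from the
    base) and ``frequencies[k]`` (Hz), normalised by the base displacement, so
    ``values[0] == 1`` identically.
    """

    positions: np.ndarray
    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.positions.size, self.frequencies.size):
            raise BeamModelError("FRF values must be (n_positions, n_frequencies)")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class ModalSet:
    """Undamped clamped-free modal frequencies (Hz) and deflection shapes.

    ``mode_shapes[:, j]`` is the transverse deflection profile of mode ``j``
    over the mesh nodes, normalised to unit maximum amplitude; the underlying
    (deflection, rotation) eigenvectors are mass-orthonormal.
    """

    modal_frequencies: np.ndarray
    mode_shapes: np.ndarray
    node_positions: np.ndarray
    eigenvectors: np.ndarray = field(repr=False, default=None)


def taper_profile(geom: WhiskerGeometry, x):
    """Radius, cross-section area and second moment of area at position x.

    x may be a scalar or array in [0, L].  Returns ``(r, A, J)`` with
    ``A = pi r^2`` and ``J = pi r^4 / 4``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > geom.length_L * (1 + 1e-12)):
        raise BeamModelError("position outside [0, L]")
    r = geom.base_radius_rb - (geom.base_radius_rb - geom.tip_radius_rt) * x / geom.length_L
    area = np.pi * r**2
    inertia = np.pi * r**4 / 4.0
    return r, area, inertia


# 6-point Gauss-Legendre on [0, 1]; exact through degree 11, enough for the
# degree-8 integrands arising from cubic shapes times the quartic J(x).
_GP, _GW = np.polynomial.legendre.leggauss(6)
_GP = 0.5 * (_GP + 1.0)
_GW = 0.5 * _GW


def _hermite_basis(xi: np.ndarray, h: float):
    """Hermite cubic shape functions and their second xi-derivatives.

    DOF order per element: (v1, theta1, v2, theta2); rotations are scaled by
    the element length so that theta carries units of slope.
    """
    n = np.stack(
        [
            1 - 3 * xi**2 + 2 * xi**3,
            h * (xi - 2 * xi**2 + xi**3),
            3 * xi**2 - 2 * xi**3,
            h * (-(xi**2) + xi**3),
        ]
    )
    d2 = np.stack(
        [
            -6 + 12 * xi,
            h * (-4 + 6 * xi),
            6 - 12 * xi,
            h * (-2 + 6 * xi),
        ]
    )
    return n, d2


def assemble_beam_system(geom: WhiskerGeometry, mat: MaterialParams, mesh: FEMesh):
    """Assemble consistent mass and stiffness matrices of the free-free beam.

    Returns ``(M, K)`` as sparse CSR matrices over the 2*(n_nodes) DOFs
    (deflection, rotation per node).  Boundary conditions are NOT applied:
    ``K`` retains the rigid-body null space, ``M`` is positive definite.
    """
    x = mesh.node_positions
    if x[-1] < geom.length_L * (1 - 1e-9) or x[-1] > geom.length_L * (1 + 1e-9):
        raise BeamModelError("mesh must span [0, L]")
    h_all = np.diff(x)
    if np.any(h_all <= 0):
        raise BeamModelError("degenerate element with non-positive length")
    ndof = 2 * x.size
    rows, cols, mdat, kdat = [], [], [], []
    for e, h in enumerate(h_all):
        xg = x[e] + h * _GP
        _, area, inertia = taper_profile(geom, xg)
        n, d2 = _hermite_basis(_GP, h)
        # local mass: rho * int A(x) N N^T dx ; stiffness: E * int J(x) N'' N''^T dx
        me = mat.density_rho * h * np.einsum("g,ig,jg->ij", _GW * area, n, n)
        ke = (mat.youngs_E / h**3) * np.einsum("g,ig,jg->ij", _GW * inertia, d2, d2)
        dofs = np.array([2 * e, 2 * e + 1, 2 * e + 2, 2 * e + 3])
        rr, cc = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        mdat.append(me.ravel())
        kdat.append(ke.ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    shape = (ndof, ndof)
    mass = scipy.sparse.coo_matrix((np.concatenate(mdat), (rows, cols)), shape=shape).tocsr()
    stiff = scipy.sparse.coo_matrix((np.concatenate(kdat), (rows, cols)), shape=shape).tocsr()
    return mass, stiff


_BW = 3  # DOF coupling half-bandwidth of two-node beam elements


def _to_banded(a: scipy.sparse.spmatrix) -> np.ndarray:
    """LAPACK banded storage ab[bw + i - j, j] = A[i, j] for solve_banded."""
    coo = a.tocsr().tocoo()
    ab = np.zeros((2 * _BW + 1, a.shape[0]))
    ab[_BW + coo.row - coo.col, coo.col] = coo.data
    return ab


def solve_frf(
    geom: WhiskerGeometry,
    mat: MaterialParams,
    mesh: FEMesh | None = None,
    grid: FrequencyGrid | None = None,
) -> ComplexFRF:
    """Solve the damped beam in the frequency domain under unit base motion.

    For every grid frequency the complex system
    ``[(s^2 + s*alpha) M + (1 + s*beta) K] u = 0`` with ``s = i omega`` is
    solved subject to base deflection 1 and base rotation 0 (free-tip
    conditions are natural).  Returns the FRF at all mesh nodes.
    """
    if mesh is None:
        mesh = FEMesh.uniform(geom.length_L)
    if grid is None:
        grid = FrequencyGrid.regular(1.0, 1000.0, 1.0)
    mass, stiff = assemble_beam_system(geom, mat, mesh)
    mab = _to_banded(mass)
    kab = _to_banded(stiff)
    mcol = mass[:, 0].toarray().ravel()
    kcol = stiff[:, 0].toarray().ravel()
    n_nodes = mesh.node_positions.size
    values = np.empty((n_nodes, grid.frequencies.size), dtype=complex)
    values[0] = 1.0
    for k, w in enumerate(grid.omega):
        s = 1j * w
        cm = s * s + s * mat.alpha_mass_damping
        ck = 1.0 + s * mat.beta_stiffness_damping
        ab = cm * mab + ck * kab
        rhs = -(cm * mcol + ck * kcol)[2:]
        try:
            u = scipy.linalg.solve_banded((_BW, _BW), ab[:, 2:], rhs)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise BeamModelError(
                f"singular system at f = {grid.frequencies[k]:g} Hz "
                "(undamped resonance?)"
            ) from exc
        if not np.all(np.isfinite(u)):
            raise BeamModelError(
                f"non-finite FRF solution at f = {grid.frequencies[k]:g} Hz "
                "(undamped resonance?)"
            )
        values[1:, k] = u[::2]
    return ComplexFRF(mesh.node_positions.copy(), grid.frequencies.copy(), values)


def modal_frequencies(
    geom: WhiskerGeometry,
    mat: MaterialParams,
    mesh: FEMesh | None = None,
    n_modes: int = 3,
) -> ModalSet:
    """First undamped modal frequencies and shapes of the clamped-free beam.

    Solves the generalised eigenproblem ``K phi = omega^2 M phi`` of the
    system with the base deflection and rotation constrained to zero.
    """
    if mesh is None:
        mesh = FEMesh.uniform(geom.length_L)
    mass, stiff = assemble_beam_system(geom, mat, mesh)
    kd = stiff.toarray()[2:, 2:]
    md = mass.toarray()[2:, 2:]
    if n_modes > kd.shape[0]:
        raise BeamModelError(f"n_modes = {n_modes} exceeds the {kd.shape[0]} discrete modes")
    w2, vec = scipy.linalg.eigh(kd, md, subset_by_index=(0, n_modes - 1))
    freqs = np.sqrt(np.maximum(w2, 0.0)) / (2.0 * np.pi)
    full = np.zeros((2 * mesh.node_positions.size, n_modes))
    full[2:, :] = vec  # eigh returns M-orthonormal vectors
    shapes = full[::2, :].copy()
    peak = np.abs(shapes).max(axis=0)
    shapes /= np.where(peak > 0, peak, 1.0)
    # sign convention: tip deflection positive
    shapes *= np.where(shapes[-1] >= 0, 1.0, -1.0)
    return ModalSet(freqs, shapes, mesh.node_positions.copy(), full)


def total_mass(geom: WhiskerGeometry, mat: MaterialParams) -> float:
    """Closed-form mass of the truncated-cone shaft, rho*pi*L*(rb^2+rb*rt+rt^2)/3."""
    rb, rt = geom.base_radius_rb, geom.tip_radius_rt
    return mat.density_rho * np.pi * geom.length_L * (rb**2 + rb * rt + rt**2) / 3.0
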