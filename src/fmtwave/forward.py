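"""Frequency-domain diffusion forward model on simplicial meshes.

The excitation fluence Phi_x and emission fluence Phi_m obey a pair of
coupled diffusion equations,

    -div(D_x grad Phi_x) + k_x Phi_x = S_x,
    -div(D_m grad Phi_m) + k_m Phi_m = alpha * Phi_x,

with Robin boundary conditions Phi + 2 A D dPhi/dn = 0, where

    D  = 1 / (3 (mu_ai + mu_af + mu_s')),      [mm]
    k  = i*omega/c + mu_ai + mu_af,            [1/mm]
    alpha = eta * mu_axf / (1 - i*omega*tau),  [1/mm]

evaluated nodewise for the excitation (x) and emission (m) bands.  Galerkin
P1 finite elements give the sparse systems (D + K + B) Phi = S with exact
element integrals for piecewise-linear bases and element-averaged nodal
coefficients.  Angular frequency ``omega`` is in rad/ns and defaults to 0
(continuous wave), in which case every assembled system is real SPD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    AssemblyError,
    ContractError,
    InvalidParameterError,
    PlacementError,
    SolverError,
)
from .mesh import Mesh, boundary_interpolator, locate

__all__ = [
    "SPEED_OF_LIGHT_MM_NS",
    "TissueProperties",
    "DerivedCoefficients",
    "SourceSet",
    "DetectorSet",
    "AssembledSystem",
    "ForwardSolution",
    "derive_coefficients",
    "assemble",
    "weighted_mass_matrix",
    "source_vector",
    "solve_excitation",
    "solve_emission",
    "measurement_pairs",
    "detector_matrix",
    "forward_map",
]

#: speed of light in vacuum divided by a tissue refractive index of 1.4, mm/ns
SPEED_OF_LIGHT_MM_NS = 299.792458 / 1.4


def _nodal(value, n):
    a = np.asarray(value, dtype=float)
    if a.ndim == 0:
        return np.full(n, float(a))
    if a.shape != (n,):
        raise ContractError(f"nodal field has shape {a.shape}, expected ({n},)")
    return a


@dataclass
class TissueProperties:
    """Nodal optical and fluorescence parameter maps.

    Absorption (mu_a*, 1/mm) splits into an intrinsic chromophore part
    (``mu_axi``/``mu_ami``) and the fluorophore part (``mu_axf``/``mu_amf``);
    ``mu_axf`` is the unknown image in reconstruction.  ``eta`` is the
    fluorescence quantum efficiency, ``tau`` the lifetime in ns, ``A_x``/
    ``A_m`` the Robin internal-reflection parameters and ``c`` the speed of
    light in the medium (mm/ns).
    """

    n_nodes: int
    mu_axi: np.ndarray = 0.0
    mu_axf: np.ndarray = 0.0
    mu_ami: np.ndarray = 0.0
    mu_amf: np.ndarray = 0.0
    mu_sx_prime: np.ndarray = 1.0
    mu_sm_prime: np.ndarray = 1.0
    eta: np.ndarray = 0.0
    tau: np.ndarray = 0.0
    A_x: float = 1.0
    A_m: float = 1.0
    c: float = SPEED_OF_LIGHT_MM_NS

    def __post_init__(self):
        n = self.n_nodes
        for name in ("mu_axi", "mu_axf", "mu_ami", "mu_amf",
                     "mu_sx_prime", "mu_sm_prime", "eta", "tau"):
            a = _nodal(getattr(self, name), n)
            if np.any(a < 0):
                raise InvalidParameterError(f"{name} must be >= 0")
            setattr(self, name, a)
        if np.any(self.eta > 1):
            raise InvalidParameterError("eta must lie in [0, 1]")
        if self.A_x <= 0 or self.A_m <= 0 or self.c <= 0:
            raise InvalidParameterError("A_x, A_m and c must be > 0")

    def with_mu_axf(self, x: np.ndarray) -> "TissueProperties":
        return replace(self, mu_axf=np.asarray(x, dtype=float))


@dataclass
class DerivedCoefficients:
    """Nodal PDE coefficients for both bands (real when omega == 0)."""

    D_x: np.ndarray
    D_m: np.ndarray
    k_x: np.ndarray
    k_m: np.ndarray
    alpha: np.ndarray
    omega: float
    robin_b_x: float
    robin_b_m: float

    @property
    def is_complex(self) -> bool:
        return self.omega != 0.0


def derive_coefficients(props: TissueProperties, omega: float = 0.0) -> DerivedCoefficients:
    """Diffusion, decay and emission-source coefficients from tissue maps."""
    tx = props.mu_axi + props.mu_axf + props.mu_sx_prime
    tm = props.mu_ami + props.mu_amf + props.mu_sm_prime
    for t, band in ((tx, "x"), (tm, "m")):
        bad = np.nonzero(t <= 0)[0]
        if bad.size:
            raise InvalidParameterError(
                f"zero total attenuation in band {band} at node {bad[0]}"
            )
    D_x = 1.0 / (3.0 * tx)
    D_m = 1.0 / (3.0 * tm)
    mu_ax = props.mu_axi + props.mu_axf
    mu_am = props.mu_ami + props.mu_amf
    if omega == 0.0:
        k_x, k_m = mu_ax, mu_am
        alpha = props.eta * props.mu_axf
    else:
        iw_c = 1j * omega / props.c
        k_x = iw_c + mu_ax
        k_m = iw_c + mu_am
        alpha = props.eta * props.mu_axf / (1.0 - 1j * omega * props.tau)
    return DerivedCoefficients(
        D_x=D_x, D_m=D_m, k_x=k_x, k_m=k_m, alpha=alpha, omega=omega,
        robin_b_x=1.0 / (2.0 * props.A_x), robin_b_m=1.0 / (2.0 * props.A_m),
    )


# ---------------------------------------------------------------------------
# P1 assembly


def _element_geometry(mesh: Mesh):
    """Element measures and P1 basis gradients (cached)."""
    if not hasattr(mesh, "_p1_cache"):
        p = mesh.nodes[mesh.elements]  # (P, nv, dim)
        T = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)
        det = np.linalg.det(T)
        if np.any(np.abs(det) < 1e-14):
            raise AssemblyError(
                f"degenerate element {int(np.argmin(np.abs(det)))}"
            )
        Tinv = np.linalg.inv(T)
        # gradients of barycentric coords: lambda_1..d rows of Tinv, lambda_0 = -sum
        g_rest = np.swapaxes(Tinv, 1, 2)  # (P, dim, dim): column i -> grad lambda_{i+1}
        g0 = -g_rest.sum(axis=2, keepdims=True)
        grads = np.concatenate([g0, g_rest], axis=2)  # (P, dim, nv)
        meas = np.abs(det) / (2.0 if mesh.dimension == 2 else 6.0)
        mesh._p1_cache = (meas, grads)
    return mesh._p1_cache


def _mass_local(dim: int) -> np.ndarray:
    nv = dim + 1
    denom = 12.0 if dim == 2 else 20.0
    return (np.ones((nv, nv)) + np.eye(nv)) / denom


@dataclass
class AssembledSystem:
    """Sparse Galerkin system A = D + K + B with a lazy direct factorization."""

    A: sp.csc_matrix
    band: str
    _lu: object = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.A.shape[0]

    def factor(self):
        if self._lu is None:
            try:
                self._lu = spla.splu(self.A.tocsc())
            except RuntimeError as exc:  # pragma: no cover - singular input
                raise SolverError(f"singular system ({self.band}): {exc}") from exc
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        lu = self.factor()
        rhs = np.asarray(rhs)
        if np.iscomplexobj(self.A) and not np.iscomplexobj(rhs):
            rhs = rhs.astype(complex)
        out = lu.solve(rhs)
        if not np.all(np.isfinite(np.atleast_1d(out).ravel())):
            raise SolverError(f"non-finite solution in band {self.band}")
        return out


def assemble(mesh: Mesh, coeffs: DerivedCoefficients, band: str) -> AssembledSystem:
    """Assemble A = D + K + B for one band with element-averaged coefficients."""
    if band not in ("x", "m"):
        raise ContractError("band must be 'x' or 'm'")
    D_nodal = coeffs.D_x if band == "x" else coeffs.D_m
    k_nodal = coeffs.k_x if band == "x" else coeffs.k_m
    b_const = coeffs.robin_b_x if band == "x" else coeffs.robin_b_m

    meas, grads = _element_geometry(mesh)
    el = mesh.elements
    nv = mesh.dimension + 1

    D_e = D_nodal[el].mean(axis=1)
    k_e = k_nodal[el].mean(axis=1)

    stiff = np.einsum("pdi,pdj->pij", grads, grads) * meas[:, None, None]
    mass = _mass_local(mesh.dimension)[None] * meas[:, None, None]
    loc = D_e[:, None, None] * stiff + k_e[:, None, None] * mass

    rows = np.repeat(el, nv, axis=1).ravel()
    cols = np.tile(el, (1, nv)).ravel()
    A = sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(mesh.N, mesh.N))

    # Robin boundary term
    bf = mesh.boundary_facets
    if bf.size:
        fmeas = mesh.facet_measures()
        nf = bf.shape[1]
        denom = 6.0 if nf == 2 else 12.0
        floc = (np.ones((nf, nf)) + np.eye(nf)) / denom
        bloc = b_const * fmeas[:, None, None] * floc[None]
        rows_b = np.repeat(bf, nf, axis=1).ravel()
        cols_b = np.tile(bf, (1, nf)).ravel()
        A = A + sp.coo_matrix((bloc.ravel(), (rows_b, cols_b)), shape=(mesh.N, mesh.N))

    return AssembledSystem(A.tocsc(), band)


def weighted_mass_matrix(mesh: Mesh, weight: np.ndarray) -> sp.csc_matrix:
    """Mass matrix with an element-averaged nodal weight field."""
    meas, _ = _element_geometry(mesh)
    el = mesh.elements
    nv = mesh.dimension + 1
    w_e = np.asarray(weight)[el].mean(axis=1)
    loc = w_e[:, None, None] * _mass_local(mesh.dimension)[None] * meas[:, None, None]
    rows = np.repeat(el, nv, axis=1).ravel()
    cols = np.tile(el, (1, nv)).ravel()
    return sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(mesh.N, mesh.N)).tocsc()


# ---------------------------------------------------------------------------
# sources and detectors


@dataclass
class SourceSet:
    """Collimated sources on the lateral boundary, modelled as isotropic
    point sources offset one transport mean free path into the domain.

    ``angles_deg`` are polar angles on the circular boundary of radius
    ``boundary_radius_mm``; ``z_mm`` is None for 2D discs or one axial
    coordinate per source for cylinders.
    """

    angles_deg: np.ndarray
    boundary_radius_mm: float
    amplitude: float = 1.0
    offset_depth_mm: float = 0.25
    z_mm: np.ndarray | None = None
    plane: np.ndarray | None = None  # measurement-plane id (3D), else None

    def __post_init__(self):
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if self.offset_depth_mm <= 0:
            raise InvalidParameterError("offset depth must be > 0")
        if self.z_mm is not None:
            self.z_mm = np.atleast_1d(np.asarray(self.z_mm, dtype=float))
            if self.z_mm.shape != self.angles_deg.shape:
                raise ContractError("z_mm must match angles_deg")
        if self.plane is not None:
            self.plane = np.atleast_1d(np.asarray(self.plane))

    def __len__(self) -> int:
        return len(self.angles_deg)

    def positions(self) -> np.ndarray:
        r = self.boundary_radius_mm - self.offset_depth_mm
        t = np.deg2rad(self.angles_deg)
        xy = np.column_stack([r * np.cos(t), r * np.sin(t)])
        if self.z_mm is None:
            return xy
        return np.column_stack([xy, self.z_mm])


@dataclass
class DetectorSet:
    """Detector positions on the boundary; ordering fixes the measurement
    layout (detector-major within each source)."""

    angles_deg: np.ndarray
    boundary_radius_mm: float
    z_mm: np.ndarray | None = None
    plane: np.ndarray | None = None

    def __post_init__(self):
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if self.z_mm is not None:
            self.z_mm = np.atleast_1d(np.asarray(self.z_mm, dtype=float))
            if self.z_mm.shape != self.angles_deg.shape:
                raise ContractError("z_mm must match angles_deg")
        if self.plane is not None:
            self.plane = np.atleast_1d(np.asarray(self.plane))

    def __len__(self) -> int:
        return len(self.angles_deg)

    def positions(self) -> np.ndarray:
        t = np.deg2rad(self.angles_deg)
        r = self.boundary_radius_mm
        xy = np.column_stack([r * np.cos(t), r * np.sin(t)])
        if self.z_mm is None:
            return xy
        return np.column_stack([xy, self.z_mm])


def measurement_pairs(sources: SourceSet, detectors: DetectorSet) -> np.ndarray:
    """(source, detector) index pairs defining the measurement vector.

    All pairs when no plane ids are set; same-plane pairs only otherwise.
    Detector-major within each source, sources outermost.
    """
    pairs = []
    for s in range(len(sources)):
        for d in range(len(detectors)):
            if sources.plane is not None and detectors.plane is not None:
                if sources.plane[s] != detectors.plane[d]:
                    continue
            pairs.append((s, d))
    return np.asarray(pairs, dtype=np.intp)


def source_vector(mesh: Mesh, position, amplitude: float = 1.0) -> np.ndarray:
    """Unit point source distributed to the containing element's nodes.

    A position that falls in the sliver between the curved boundary and the
    polygonal mesh hull (possible on coarse meshes) is clamped into the
    nearest element; positions further than ~a mesh spacing outside raise a
    placement error.
    """
    from .mesh import _all_barycentric

    position = np.asarray(position, dtype=float)
    w_all = _all_barycentric(mesh, position)
    k = int(np.argmax(w_all.min(axis=1)))
    if w_all[k].min() < -0.5:
        raise PlacementError(f"source position {position.tolist()} outside domain")
    w = np.clip(w_all[k], 0.0, None)
    w /= w.sum()
    rhs = np.zeros(mesh.N)
    rhs[mesh.elements[k]] = amplitude * w
    return rhs


def detector_matrix(mesh: Mesh, detectors: DetectorSet) -> sp.csr_matrix:
    """Sparse (n_det x N) sampling operator via boundary-facet interpolation."""
    rows, cols, vals = [], [], []
    for d, pos in enumerate(detectors.positions()):
        idx, w = boundary_interpolator(mesh, pos)
        rows.extend([d] * len(idx))
        cols.extend(idx.tolist())
        vals.extend(w.tolist())
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(detectors), mesh.N)
    ).tocsr()


# ---------------------------------------------------------------------------
# solves


def solve_excitation(system: AssembledSystem, rhs: np.ndarray) -> np.ndarray:
    """Direct sparse solve of (D_x + K_x + B_x) Phi_x = S_x."""
    phi = system.solve(rhs)
    nrm = np.linalg.norm(np.atleast_1d(rhs).ravel())
    if nrm > 0:
        res = np.linalg.norm((system.A @ phi - rhs).ravel()) / nrm
        if res > 1e-8:
            raise SolverError(f"excitation residual {res:.2e} too large")
    return phi


def solve_emission(
    system_m: AssembledSystem,
    phi_x: np.ndarray,
    coeffs: DerivedCoefficients,
    mesh: Mesh,
) -> np.ndarray:
    """Solve the emission system with source term alpha * Phi_x.

    The load vector is the weighted mass-matrix action M_alpha @ Phi_x.
    """
    M_alpha = weighted_mass_matrix(mesh, coeffs.alpha)
    return system_m.solve(M_alpha @ phi_x)


@dataclass
class ForwardSolution:
    phi_x: np.ndarray  # (N, n_sources)
    phi_m: np.ndarray  # (N, n_sources)
    y: np.ndarray  # measurement vector, stacked per measurement_pairs
    pairs: np.ndarray


def forward_map(
    mesh: Mesh,
    props: TissueProperties,
    sources: SourceSet,
    detectors: DetectorSet,
    omega: float = 0.0,
    full: bool = False,
):
    """Simulate detector measurements of the emission fluence.

    Returns the measurement vector y (complex for omega != 0), or the full
    :class:`ForwardSolution` when ``full=True``.
    """
    coeffs = derive_coefficients(props, omega)
    sys_x = assemble(mesh, coeffs, "x")
    sys_m = assemble(mesh, coeffs, "m")
    S = np.column_stack(
        [source_vector(mesh, p, sources.amplitude) for p in sources.positions()]
    )
    phi_x = solve_excitation(sys_x, S)
    M_alpha = weighted_mass_matrix(mesh, coeffs.alpha)
    phi_m = sys_m.solve(M_alpha @ phi_x)
    G = detector_matrix(mesh, detectors)
    samp = G @ phi_m  # (n_det, n_src)
    pairs = measurement_pairs(sources, detectors)
    y = samp[pairs[:, 1], pairs[:, 0]]
    if not np.all(np.isfinite(np.abs(y))):
        raise SolverError("non-finite measurement")
    if full:
        return ForwardSolution(phi_x=phi_x, phi_m=phi_m, y=y, pairs=pairs)
    return y
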