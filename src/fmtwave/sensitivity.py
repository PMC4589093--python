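"""Linearized inverse problem: Jacobian, residual and Tikhonov normal equations.

The unknown image x is the nodal fluorophore absorption map mu_axf.  A
measurement y_{s,d} = g_d^T A_m^{-1} M_alpha A_x^{-1} s_s depends on x through
three paths: the excitation decay k_x, the excitation diffusion D_x and the
emission source coefficient alpha.  Writing the emission adjoint
psi_d = A_m^{-1} g_d and the excitation adjoint w_d = A_x^{-1} M_alpha^T psi_d
(A is complex-symmetric, so no conjugation is needed), the row (s, d) of the
Jacobian is

    dy/dx_n = psi_d^T (dM_alpha/dx_n) Phi_x,s  -  w_d^T (dA_x/dx_n) Phi_x,s,

assembled element-by-element with the same element-averaged coefficient
convention as the forward model.  One excitation solve per source plus two
adjoint solves per detector (reusing each band's factorization) produce the
whole matrix.

Complex measurements (omega != 0) are handled by stacking real and imaginary
residual parts into real rows; at omega = 0 only the real block exists, which
keeps K = J^T J + xi*I and b = J^T dy in real arithmetic.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .errors import ContractError, SolverError
from .forward import (
    DetectorSet,
    SourceSet,
    TissueProperties,
    assemble,
    derive_coefficients,
    detector_matrix,
    forward_map,
    measurement_pairs,
    solve_excitation,
    source_vector,
    weighted_mass_matrix,
    _element_geometry,
    _mass_local,
)
from .mesh import Mesh

log = logging.getLogger(__name__)

__all__ = [
    "jacobian_adjoint",
    "forward_and_jacobian",
    "jacobian_fd",
    "stack_real",
    "normal_system",
    "tikhonov_solve",
]


def forward_and_jacobian(
    mesh: Mesh,
    props: TissueProperties,
    sources: SourceSet,
    detectors: DetectorSet,
    omega: float = 0.0,
):
    """Predicted measurements and the (complex) Jacobian dy/dmu_axf.

    Returns ``(y, J)`` with J of shape (n_measurements, N); J is real when
    omega == 0.  The forward fields are computed once and shared with the
    sensitivity assembly.
    """
    coeffs = derive_coefficients(props, omega)
    sys_x = assemble(mesh, coeffs, "x")
    sys_m = assemble(mesh, coeffs, "m")

    S = np.column_stack(
        [source_vector(mesh, p, sources.amplitude) for p in sources.positions()]
    )
    phi_x = solve_excitation(sys_x, S)  # (N, n_src)
    M_alpha = weighted_mass_matrix(mesh, coeffs.alpha)
    phi_m = sys_m.solve(M_alpha @ phi_x)

    G = detector_matrix(mesh, detectors)  # (n_det, N)
    pairs = measurement_pairs(sources, detectors)
    y = (G @ phi_m)[pairs[:, 1], pairs[:, 0]]

    # adjoint fields (A_x, A_m are complex-symmetric: A^{-T} = A^{-1})
    Gd = np.asarray(G.T.todense())
    if np.iscomplexobj(sys_m.A):
        Gd = Gd.astype(complex)
    psi = sys_m.solve(Gd)  # (N, n_det) emission adjoints
    w = sys_x.solve(M_alpha.T @ psi)  # (N, n_det) excitation adjoints

    # nodal derivative factors
    tx = props.mu_axi + props.mu_axf + props.mu_sx_prime
    dD = -1.0 / (3.0 * tx * tx)  # d D_x / d mu_axf per node
    if omega == 0.0:
        dalpha = props.eta.copy()
    else:
        dalpha = props.eta / (1.0 - 1j * omega * props.tau)
    # d k_x / d mu_axf = 1

    meas, grads = _element_geometry(mesh)
    el = mesh.elements
    nv = mesh.dimension + 1
    stiff = np.einsum("pdi,pdj->pij", grads, grads) * meas[:, None, None]
    mass = _mass_local(mesh.dimension)[None] * meas[:, None, None]

    phx_e = phi_x[el]  # (P, nv, n_src)
    psi_e = psi[el]  # (P, nv, n_det)
    w_e = w[el]

    # per-element bilinear forms for every (source, detector) combination
    uS = np.einsum("pad,pab,pbs->psd", w_e, stiff, phx_e)
    uM = np.einsum("pad,pab,pbs->psd", w_e, mass, phx_e)
    vM = np.einsum("pad,pab,pbs->psd", psi_e, mass, phx_e)

    n_pairs = len(pairs)
    n_det = len(detectors)
    dtype = complex if omega != 0.0 else float
    s_idx, d_idx = pairs[:, 0], pairs[:, 1]
    flat_pair = s_idx * n_det + d_idx
    P = len(el)
    uS_p = uS.reshape(P, -1)[:, flat_pair]  # (P, n_pairs)
    uM_p = uM.reshape(P, -1)[:, flat_pair]
    vM_p = vM.reshape(P, -1)[:, flat_pair]
    # element contribution to measurement row r for node n in the element:
    #   (1/nv) * [ dalpha_n * vM - dD_n * uS - 1 * uM ](element, s_r, d_r)
    JT = np.zeros((mesh.N, n_pairs), dtype=dtype)
    for a in range(nv):
        n_a = el[:, a]
        contrib = (
            dalpha[n_a][:, None] * vM_p - dD[n_a][:, None] * uS_p - uM_p
        ) / nv
        np.add.at(JT, n_a, contrib)
    return y, JT.T


def jacobian_adjoint(
    mesh: Mesh,
    props: TissueProperties,
    sources: SourceSet,
    detectors: DetectorSet,
    omega: float = 0.0,
) -> np.ndarray:
    """Jacobian of the measurement vector with respect to nodal mu_axf."""
    _, J = forward_and_jacobian(mesh, props, sources, detectors, omega)
    return J


def jacobian_fd(
    mesh: Mesh,
    props: TissueProperties,
    sources: SourceSet,
    detectors: DetectorSet,
    omega: float = 0.0,
    step: float = 1e-6,
) -> np.ndarray:
    """Brute-force central-difference Jacobian (test oracle, O(N) solves)."""
    if step <= 0:
        raise ContractError("step must be > 0")
    x0 = props.mu_axf.copy()
    cols = []
    for n in range(mesh.N):
        h = step
        lo = x0[n] - h
        if lo < 0:
            log.warning("jacobian_fd: clipping step at node %d to keep mu_axf >= 0", n)
            h = x0[n] / 2.0 if x0[n] > 0 else step
            lo = x0[n] - h
        xp = x0.copy()
        xp[n] = x0[n] + h
        xm = x0.copy()
        xm[n] = lo
        yp = forward_map(mesh, props.with_mu_axf(xp), sources, detectors, omega)
        ym = forward_map(mesh, props.with_mu_axf(xm), sources, detectors, omega)
        cols.append((yp - ym) / (2.0 * h))
    return np.column_stack(cols)


def stack_real(y: np.ndarray, omega: float) -> np.ndarray:
    """Stack a (possibly complex) measurement vector into real rows."""
    y = np.asarray(y)
    if omega == 0.0:
        return np.real(y)
    return np.concatenate([np.real(y), np.imag(y)])


def normal_system(J: np.ndarray, delta_y: np.ndarray, xi: float):
    """Tikhonov normal equations K = J^T J + xi*I, b = J^T dy (real, dense)."""
    if xi < 0:
        raise ContractError("xi must be >= 0")
    J = np.asarray(J, dtype=float)
    delta_y = np.asarray(delta_y, dtype=float)
    if J.ndim != 2 or delta_y.shape != (J.shape[0],):
        raise ContractError(
            f"shape mismatch: J {J.shape} vs delta_y {delta_y.shape}"
        )
    K = J.T @ J + xi * np.eye(J.shape[1])
    b = J.T @ delta_y
    return K, b


def tikhonov_solve(K: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve K dx = b by Cholesky factorization (K symmetric positive definite)."""
    K = np.asarray(K, dtype=float)
    b = np.asarray(b, dtype=float)
    if K.shape[0] != K.shape[1] or b.shape != (K.shape[0],):
        raise ContractError(f"shape mismatch: K {K.shape}, b {b.shape}")
    try:
        c = scipy.linalg.cho_factor(K)
    except np.linalg.LinAlgError as exc:
        raise SolverError(
            "normal matrix not positive definite; use xi > 0"
        ) from exc
    dx = scipy.linalg.cho_solve(c, b)
    nb = np.linalg.norm(b)
    if nb > 0:
        res = np.linalg.norm(K @ dx - b) / nb
        if res > 1e-10:
            dx, _, _, _ = np.linalg.lstsq(K, b, rcond=None)
    return dx
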