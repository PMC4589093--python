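"""Accelerated solution of the Tikhonov normal equations K dx = b.

The system is compressed by an orthonormal discrete wavelet transform
(K_hat = W K W^T, b_hat = W b, after zero-padding to a power of two), its
approximation-approximation block is reduced further by projecting onto the
leading principal components of the block's column covariance, the reduced
least-squares problem is solved, and the solution is prolongated by zero
padding and inverse-transformed to warm-start a conjugate-gradient solve of
the original system.  The compression changes the path, not the fixed point:
the final iterate solves K dx = b to the CG tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, ContractError, SolverError

log = logging.getLogger(__name__)

__all__ = [
    "WaveletOperator",
    "PCAReduction",
    "SolverConfig",
    "build_wavelet_operator",
    "compress_system",
    "pca_reduce",
    "solve_reduced",
    "algorithm1_solve",
]

SUPPORTED_FAMILIES = ("haar", "db2", "db4")


@dataclass
class WaveletOperator:
    """Orthonormal DWT matrix acting on zero-padded length-n vectors.

    Rows are ordered approximation-first; ``n1 = n_pad / 2**level`` is the
    approximation block size.
    """

    W: np.ndarray
    family: str
    level: int
    n: int
    n_pad: int
    n1: int

    def pad(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape[-1] == self.n_pad:
            return v
        if v.shape[-1] != self.n:
            raise ContractError(f"vector length {v.shape[-1]} != {self.n}")
        widths = [(0, 0)] * (v.ndim - 1) + [(0, self.n_pad - self.n)]
        return np.pad(v, widths)

    def forward(self, v: np.ndarray) -> np.ndarray:
        """Pad then transform: W @ [v; 0]."""
        return self.pad(v) @ self.W.T

    def inverse(self, vhat: np.ndarray, truncate: bool = True) -> np.ndarray:
        out = np.asarray(vhat) @ self.W
        return out[..., : self.n] if truncate else out


def build_wavelet_operator(n: int, family: str = "haar", level: int = 1) -> WaveletOperator:
    """Dense orthonormal wavelet transform for length-n vectors.

    Periodized orthogonal filters keep W exactly orthonormal; the input is
    zero-padded from n to the next power of two.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if family not in SUPPORTED_FAMILIES:
        raise ConfigurationError(
            f"unsupported wavelet family {family!r}; choose from {SUPPORTED_FAMILIES}"
        )
    n_pad = 1 << max(1, math.ceil(math.log2(n)))
    if level < 1 or (1 << level) > n_pad:
        raise ConfigurationError(f"level {level} invalid for padded length {n_pad}")
    coeffs = pywt.wavedec(
        np.eye(n_pad), family, mode="periodization", level=level, axis=0
    )
    W = np.concatenate(coeffs, axis=0)
    n1 = n_pad >> level
    return WaveletOperator(W=W, family=family, level=level, n=n, n_pad=n_pad, n1=n1)


def compress_system(
    K: np.ndarray, b: np.ndarray, W_x: WaveletOperator, W_b: WaveletOperator
):
    """Approximation block of the wavelet-transformed system.

    K_hat = W_b K W_x^T and b_hat = W_b b (zero-padded); returns the
    approximation-approximation block K_hat_1 (n1 x n1) and the approximation
    half b_hat_1.
    """
    K = np.asarray(K, dtype=float)
    b = np.asarray(b, dtype=float)
    if K.shape != (W_b.n, W_x.n) or b.shape != (W_b.n,):
        raise ContractError(
            f"size mismatch: K {K.shape}, b {b.shape} vs operators "
            f"({W_b.n}, {W_x.n})"
        )
    K_pad = np.zeros((W_b.n_pad, W_x.n_pad))
    K_pad[: W_b.n, : W_x.n] = K
    K_hat = W_b.W @ K_pad @ W_x.W.T
    b_hat = W_b.W @ W_b.pad(b)
    return K_hat[: W_b.n1, : W_x.n1], b_hat[: W_b.n1]


@dataclass
class PCAReduction:
    """Principal-component projection of the compressed block."""

    L: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    q: int
    K_red: np.ndarray
    b_red: np.ndarray


def pca_reduce(
    K1: np.ndarray,
    b1: np.ndarray,
    energy_fraction: float | None = None,
    q: int | None = None,
) -> PCAReduction:
    """Project the block system onto leading principal components.

    The covariance is taken over the columns of K1 (centered by the column
    average); the projection applies the *uncentered* K1 and b1 to the top-q
    eigenvector rows.  ``q`` is either given or chosen as the smallest count
    whose eigenvalue mass reaches ``energy_fraction``.
    """
    K1 = np.asarray(K1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    n1 = K1.shape[0]
    if K1.shape != (n1, n1) or b1.shape != (n1,):
        raise ContractError(f"shape mismatch: K1 {K1.shape}, b1 {b1.shape}")
    if (energy_fraction is None) == (q is None):
        raise ConfigurationError("give exactly one of energy_fraction or q")
    if energy_fraction is not None and not (0.0 < energy_fraction <= 1.0):
        raise ConfigurationError("energy_fraction must be in (0, 1]")
    if q is not None and not (1 <= q <= n1):
        raise ConfigurationError(f"q must be in [1, {n1}]")

    col_mean = K1.mean(axis=1)
    C = K1 - col_mean[:, None]
    L = (C @ C.T) / n1
    lam, psi = np.linalg.eigh(L)
    lam = lam[::-1]
    psi = psi[:, ::-1]
    lam = np.clip(lam, 0.0, None)

    if q is None:
        total = lam.sum()
        if total <= 1e-12 * max(1.0, abs(K1).max() ** 2):
            log.warning("pca_reduce: zero-variance block; retaining q = 1")
            q = 1
        else:
            cum = np.cumsum(lam) / total
            q = int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)
            q = min(q, n1)
            if energy_fraction >= 1.0:
                q = int((lam > 1e-12 * total).sum()) or 1

    psi_q = psi[:, :q]
    return PCAReduction(
        L=L,
        eigenvalues=lam,
        eigenvectors=psi,
        q=q,
        K_red=psi_q.T @ K1,
        b_red=psi_q.T @ b1,
    )


def solve_reduced(reduction: PCAReduction) -> np.ndarray:
    """Minimum-norm least-squares solution of the q x n1 reduced system."""
    K_red, b_red = reduction.K_red, reduction.b_red
    if not np.any(K_red):
        if np.any(b_red):
            raise SolverError("inconsistent reduced system: K_red = 0, b_red != 0")
        return np.zeros(K_red.shape[1])
    dx, *_ = np.linalg.lstsq(K_red, b_red, rcond=None)
    return dx


@dataclass
class SolverConfig:
    """Inner-solver settings (wavelet family/level, PCA retention, CG)."""

    family: str = "haar"
    level: int = 1
    energy_fraction: float | None = 0.95
    q: int | None = None
    tol: float = 1e-8
    maxiter_factor: int = 10
    ordering: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.q is not None:  # an explicit rank overrides the energy rule
            self.energy_fraction = None


@dataclass
class SolveInfo:
    cg_iterations: int
    warm_start_norm: float
    converged: bool
    q: int
    n1: int


def _cg_with_count(K, b, x0, rtol, maxiter):
    it = 0

    def cb(_):
        nonlocal it
        it += 1

    x, info = spla.cg(K, b, x0=x0, rtol=rtol, maxiter=maxiter, callback=cb)
    return x, info, it


def algorithm1_solve(K: np.ndarray, b: np.ndarray, config: SolverConfig | None = None):
    """Wavelet-PCA compressed solve of K dx = b (K symmetric positive definite).

    Steps: (1) wavelet-compress to the approximation block; (2) PCA-reduce
    and solve the block by minimum-norm least squares; (3) prolongate with
    zeros; (4) inverse-transform and polish with warm-started CG.  Returns
    ``(dx, SolveInfo)``; a CG failure to reach tolerance within
    ``maxiter_factor * N`` iterations returns the best iterate with
    ``converged=False``.
    """
    if config is None:
        config = SolverConfig()
    K = np.asarray(K, dtype=float)
    b = np.asarray(b, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or b.shape != (n,):
        raise ContractError(f"shape mismatch: K {K.shape}, b {b.shape}")

    perm = config.ordering
    if perm is not None:
        perm = np.asarray(perm, dtype=np.intp)
        Kp = K[np.ix_(perm, perm)]
        bp = b[perm]
    else:
        Kp, bp = K, b

    W = build_wavelet_operator(n, config.family, config.level)
    K1, b1 = compress_system(Kp, bp, W, W)
    red = pca_reduce(K1, b1, energy_fraction=config.energy_fraction, q=config.q)
    dx1 = solve_reduced(red)

    dx_hat0 = np.zeros(W.n_pad)
    dx_hat0[: W.n1] = dx1
    x0 = W.inverse(dx_hat0)

    maxiter = max(1, config.maxiter_factor * n)
    x, info_flag, iters = _cg_with_count(Kp, bp, x0, config.tol, maxiter)
    converged = info_flag == 0
    if not converged:
        log.warning("algorithm1_solve: CG stopped at cap (%d iterations)", iters)
    if perm is not None:
        out = np.empty_like(x)
        out[perm] = x
        x = out
    info = SolveInfo(
        cg_iterations=iters,
        warm_start_norm=float(np.linalg.norm(x0)),
        converged=converged,
        q=red.q,
        n1=W.n1,
    )
    return x, info


def wavelet_only_solve(K: np.ndarray, b: np.ndarray, config: SolverConfig | None = None):
    """Approximation-block solve without PCA and without the full polish.

    Solves K_hat_1 dx_hat_1 = b_hat_1 directly, prolongates with zeros and
    inverse-transforms — the single-level compressed update used as the
    wavelet-method ablation.
    """
    if config is None:
        config = SolverConfig()
    K = np.asarray(K, dtype=float)
    b = np.asarray(b, dtype=float)
    n = K.shape[0]
    perm = config.ordering
    if perm is not None:
        perm = np.asarray(perm, dtype=np.intp)
        Kp = K[np.ix_(perm, perm)]
        bp = b[perm]
    else:
        Kp, bp = K, b
    W = build_wavelet_operator(n, config.family, config.level)
    K1, b1 = compress_system(Kp, bp, W, W)
    dx1, *_ = np.linalg.lstsq(K1, b1, rcond=None)
    dx_hat0 = np.zeros(W.n_pad)
    dx_hat0[: W.n1] = dx1
    x = W.inverse(dx_hat0)
    if perm is not None:
        out = np.empty_like(x)
        out[perm] = x
        x = out
    return x, SolveInfo(0, float(np.linalg.norm(x)), True, 0, W.n1)


def pca_only_solve(K: np.ndarray, b: np.ndarray, config: SolverConfig | None = None):
    """PCA reduction of the full (uncompressed) system — the PCA ablation."""
    if config is None:
        config = SolverConfig()
    K = np.asarray(K, dtype=float)
    b = np.asarray(b, dtype=float)
    red = pca_reduce(K, b, energy_fraction=config.energy_fraction, q=config.q)
    dx = solve_reduced(red)
    return dx, SolveInfo(0, 0.0, True, red.q, K.shape[0])
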