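"""Chebyshev-polynomial spectral graph convolution.

A filter on the mesh graph is a degree-(K-1) polynomial of the shifted and
rescaled normalized Laplacian  Lbar = 2 L / lambda_max - I  (spectrum in
[-1, 1]):

    f_theta(L) = sum_k theta_k T_k(Lbar),    T_0 = I, T_1 = Lbar,
    T_k = 2 Lbar T_{k-1} - T_{k-2},

applied channel-wise:  Y^j = sum_i f_{theta_{i,j}}(L) X^i.  The recursion is
always carried on the *filtered signal* (sparse matrix-vector products,
O(K E F)); no dense matrix polynomial is ever formed.  Because Lbar is
symmetric, the map X -> T_k(Lbar) X is self-adjoint, which gives the exact
gradient rules implemented in :func:`cheb_backward`:

    dL/dtheta_k = T_k(Lbar, X)^T dY,     dL/dX = sum_k T_k(Lbar, dY) theta_k^T.

The polynomial order K is a config knob (default 6, the customary choice in
the convolutional mesh-autoencoder lineage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_core import MeshGraph

__all__ = [
    "ChebKernel",
    "rescale_laplacian",
    "cheb_basis",
    "cheb_apply",
    "cheb_forward",
    "cheb_backward",
]


@dataclass
class ChebKernel:
    """Learnable filter coefficients theta: (K, F_in, F_out), optional bias."""

    theta: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        if self.theta.ndim != 3 or min(self.theta.shape) < 1:
            raise ValueError("theta must be a (K, F_in, F_out) tensor")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite coefficients")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, float).ravel()
            if len(self.bias) != self.theta.shape[2]:
                raise ValueError("bias length must equal F_out")

    @property
    def order(self) -> int:
        return self.theta.shape[0]


def rescale_laplacian(graph: MeshGraph | sp.spmatrix,
                      lambda_max: float | None = None) -> sp.csr_matrix:
    """Lbar = 2 L / lambda_max - I, mapping the spectrum into [-1, 1]."""
    if isinstance(graph, MeshGraph):
        lap, lam = graph.laplacian, graph.lambda_max
    else:
        lap = sp.csr_matrix(graph)
        lam = lambda_max if lambda_max is not None else 2.0
    if lam <= 0:
        raise ValueError("lambda_max must be positive")
    n = lap.shape[0]
    out = sp.csr_matrix((2.0 / lam) * lap - sp.identity(n, format="csr"))
    out.eliminate_zeros()
    return out


def _to_2d(x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """View (N, F) or (B, N, F) input as (N, cols) for sparse products."""
    x = np.asarray(x)
    if x.dtype.kind != "f":
        x = x.astype(float)
    if x.ndim == 2:
        return x, x.shape
    if x.ndim == 3:
        b, n, f = x.shape
        return np.ascontiguousarray(np.moveaxis(x, 0, 1)).reshape(n, b * f), x.shape
    raise ValueError("signal must be (N, F) or (B, N, F)")


def _basis_2d(lbar: sp.spmatrix, x2d: np.ndarray, order: int) -> np.ndarray:
    """(K, N, cols) Chebyshev stack on a flat 2-D signal."""
    n, cols = x2d.shape
    out = np.empty((order, n, cols), dtype=x2d.dtype)
    out[0] = x2d
    if order > 1:
        out[1] = lbar @ x2d
    for k in range(2, order):
        out[k] = 2.0 * (lbar @ out[k - 1]) - out[k - 2]
    return out


def cheb_basis(lbar: sp.spmatrix, x: np.ndarray, order: int) -> np.ndarray:
    """Stack [T_0 x, ..., T_{K-1} x] via the three-term recursion.

    Returns shape (K,) + x.shape; accepts (N, F) or batched (B, N, F).
    """
    x2d, shape = _to_2d(x)
    stack = _basis_2d(lbar, x2d, order)  # (K, N, cols)
    if len(shape) == 3:
        b, n, f = shape
        stack = np.moveaxis(stack.reshape(order, n, b, f), 2, 1)  # (K, B, N, F)
    return stack


def cheb_forward(lbar: sp.spmatrix, kernel: ChebKernel, x: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Filter a node signal; returns (output, cached Chebyshev basis).

    Output Y = sum_k T_k(Lbar) X theta_k (+ bias), shapes (..., N, F_out).
    """
    k = kernel.order
    if x.shape[-1] != kernel.theta.shape[1]:
        raise ValueError(
            f"signal has {x.shape[-1]} features, kernel expects {kernel.theta.shape[1]}")
    f_in, f_out = kernel.theta.shape[1:]
    x2d, shape = _to_2d(x)  # (N, cols); batched cols = B * F_in, n-major layout
    basis = _basis_2d(lbar, x2d, k)
    n = x2d.shape[0]
    rows = x2d.size // f_in
    # per-order GEMMs on contiguous (rows, F_in) views of each T_k x
    y = np.zeros((rows, f_out), dtype=np.result_type(x2d, kernel.theta))
    for kk in range(k):
        y += basis[kk].reshape(rows, f_in) @ kernel.theta[kk]
    if len(shape) == 3:
        b = shape[0]
        y = np.moveaxis(y.reshape(n, b, f_out), 0, 1)
    else:
        y = y.reshape(n, f_out)
    if kernel.bias is not None:
        y = y + kernel.bias
    return y, (basis, shape)


def cheb_backward(lbar: sp.spmatrix, kernel: ChebKernel, basis, dy: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Adjoint of :func:`cheb_forward`: (dX, dtheta, dbias).

    ``basis`` is the cache returned by :func:`cheb_forward`.
    """
    k = kernel.order
    f_in, f_out = kernel.theta.shape[1:]
    basis2d, shape = basis
    dy2d, _ = _to_2d(dy)
    dual = _basis_2d(lbar, dy2d, k)  # T_k applied to the upstream gradient
    n = dy2d.shape[0]
    rows = dy2d.size // f_out
    dy_flat = dy2d.reshape(rows, f_out)
    dtheta = np.empty_like(kernel.theta)
    dx = np.zeros((rows, f_in), dtype=np.result_type(dy2d, kernel.theta))
    for kk in range(k):
        bk = basis2d[kk].reshape(rows, f_in)
        dtheta[kk] = bk.T @ dy_flat
        dx += dual[kk].reshape(rows, f_out) @ kernel.theta[kk].T
    if len(shape) == 3:
        b = shape[0]
        dx = np.moveaxis(dx.reshape(n, b, f_in), 0, 1)
        dbias = dy.sum(axis=(0, 1)) if kernel.bias is not None else None
    else:
        dx = dx.reshape(n, f_in)
        dbias = dy.sum(axis=0) if kernel.bias is not None else None
    return dx, dtheta, dbias


def cheb_apply(graph: MeshGraph, kernel: ChebKernel, signal: np.ndarray) -> np.ndarray:
    """Apply a Chebyshev spectral filter to a node signal on ``graph``."""
    if signal.shape[-2] != graph.n:
        raise ValueError("signal row count must equal graph size")
    lbar = rescale_laplacian(graph)
    y, _ = cheb_forward(lbar, kernel, np.asarray(signal, float))
    return y
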