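"""Evaluation metrics, the k-fold protocol and the PCA baseline.

Reconstruction quality is scored by the L2 reconstruction percentage

    E = (1 - ||M - M*||_2 / ||M*||_2) x 100

(Frobenius norm over all vertex coordinates; E = 100 iff the reconstruction
is exact, and E can go negative for reconstructions worse than predicting
zero), by the Chamfer error Err_CD (identical to the Chamfer loss term) and
by its square root, the Root Chamfer Distance RCD (cm), which puts the
Chamfer error on the same scale as an L2 norm.

Latent disentanglement is quantified by det(R) x 100, where R is the
correlation matrix of n latent-mean observations: a perfectly independent
latent space gives det(R) = 1, any linear redundancy drives it toward 0.

The PCA baseline fits an orthonormal basis of the flattened training
coordinates and reconstructs test shapes by projection, mean + W^T W (x -
mean) — the classical linear statistical shape model the nonlinear model is
compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .recon_losses import chamfer_loss

__all__ = [
    "DisentanglementReport",
    "PcaModel",
    "reconstruction_percentage",
    "chamfer_error",
    "rcd",
    "disentanglement_report",
    "kfold_split",
    "fit_pca",
    "pca_reconstruct",
]


@dataclass
class DisentanglementReport:
    latent_matrix: np.ndarray   # (n, d) observations of mu
    covariance: np.ndarray      # (d, d), 1/(n-1) estimator
    correlation: np.ndarray     # (d, d), unit diagonal
    det_r_times_100: float


@dataclass
class PcaModel:
    mean: np.ndarray        # (3N,)
    components: np.ndarray  # (d, 3N), orthonormal rows
    d: int


def _flat(m) -> np.ndarray:
    v = m.vertices if hasattr(m, "vertices") else np.asarray(m, float)
    return np.asarray(v, float).ravel()


def reconstruction_percentage(m, m_star) -> float:
    """E = (1 - ||M - M*|| / ||M*||) x 100."""
    x = _flat(m)
    x_star = _flat(m_star)
    denom = np.linalg.norm(x_star)
    if denom == 0:
        raise ValueError("ground truth has zero norm")
    return float((1.0 - np.linalg.norm(x - x_star) / denom) * 100.0)


def chamfer_error(m, m_star) -> float:
    """Err_CD — the Chamfer loss treated as an absolute error."""
    v = m.vertices if hasattr(m, "vertices") else np.asarray(m, float)
    v_star = m_star.vertices if hasattr(m_star, "vertices") else np.asarray(m_star, float)
    return chamfer_loss(v, v_star)


def rcd(m, m_star) -> float:
    """Root Chamfer Distance = sqrt(Err_CD), in cm."""
    return float(np.sqrt(chamfer_error(m, m_star)))


def disentanglement_report(latents: np.ndarray) -> DisentanglementReport:
    """Correlation structure of latent observations and det(R) x 100."""
    x = np.asarray(latents, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2, d) latent matrix")
    var = x.var(axis=0, ddof=1)
    dead = np.where(var == 0)[0]
    if len(dead):
        raise ValueError(f"zero-variance latent dimension(s): {dead.tolist()}")
    cov = np.cov(x, rowvar=False, ddof=1).reshape(x.shape[1], x.shape[1])
    denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    corr = cov / denom
    np.fill_diagonal(corr, 1.0)
    det = float(np.linalg.det(corr))
    return DisentanglementReport(x, cov, corr, det * 100.0)


def kfold_split(n_or_dataset, k: int = 10, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition: disjoint test folds covering all indices."""
    n = n_or_dataset if isinstance(n_or_dataset, int) else len(n_or_dataset)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in kf.split(np.arange(n))]


def fit_pca(train_meshes: list, d: int) -> PcaModel:
    """Top-d eigenvectors of the covariance of flattened vertex coordinates."""
    x = np.stack([_flat(m) for m in train_meshes])
    n, p = x.shape
    if d > min(n - 1, p):
        raise ValueError(f"d={d} exceeds min(n_train - 1, 3N) = {min(n - 1, p)}")
    mean = x.mean(axis=0)
    if d == 0:
        return PcaModel(mean, np.empty((0, p)), 0)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(x)
    return PcaModel(mean, pca.components_, d)


def pca_reconstruct(model: PcaModel, mesh) -> np.ndarray:
    """mean + W^T W (x - mean), reshaped to (N, 3)."""
    x = _flat(mesh)
    rec = model.mean + (x - model.mean) @ model.components.T @ model.components
    return rec.reshape(-1, 3)
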