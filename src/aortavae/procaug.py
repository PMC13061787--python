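"""Procrustes alignment and the ProcAug online augmentation policy.

Each training shape is compared against a reference geometry by orthogonal
Procrustes analysis: both point sets are centered and scaled to unit
Frobenius norm, and the proper rotation minimizing ||M R - M_ref||_F is
recovered from the SVD of M^T M_ref (with the Kabsch sign correction so the
solution stays in SO(3) — anatomical mirror images are not valid
augmentations).  The rotations are decomposed into ZYX Euler angles
(R = Rz(gamma) Ry(xi) Rx(psi)) and, together with the spread of
pre-normalization Frobenius norms, define per-dataset uniform sampling
ranges.  During training one of {identity, scaling, rotation} is drawn with
probability 1/K (K = 3) per sample and applied on the fly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .mesh_core import SurfaceMesh

__all__ = [
    "ProcrustesResult",
    "AugmentPolicy",
    "Transform",
    "unit_normalize",
    "rotation_from_euler",
    "euler_from_rotation",
    "procrustes_rotation",
    "fit_policy",
    "sample_augmentation",
    "apply_augmentation",
]


@dataclass
class ProcrustesResult:
    rotation: np.ndarray          # 3x3, orthogonal, det +1
    euler_zyx: tuple[float, float, float]  # (psi, xi, gamma) radians
    residual: float               # ||M R - M_ref||_F after alignment


@dataclass
class AugmentPolicy:
    """Uniform sampling ranges discovered by Procrustes analysis."""

    psi_range: tuple[float, float] = (0.0, 0.0)
    xi_range: tuple[float, float] = (0.0, 0.0)
    gamma_range: tuple[float, float] = (0.0, 0.0)
    norm_range: tuple[float, float] = (1.0, 1.0)
    n_transforms: int = 3

    def __post_init__(self) -> None:
        for name in ("psi_range", "xi_range", "gamma_range", "norm_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} has min > max")
        if self.norm_range[0] <= 0:
            raise ValueError("norms must be positive")


@dataclass
class Transform:
    """One sampled augmentation: 'identity', 'scale' (s_rand) or 'rotation'."""

    kind: str
    scale: float | None = None
    rotation: np.ndarray | None = None


def unit_normalize(m: np.ndarray) -> np.ndarray:
    """Scale a point matrix to unit Frobenius norm."""
    m = np.asarray(m, float)
    norm = np.linalg.norm(m)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero point matrix")
    return m / norm


def rotation_from_euler(psi: float, xi: float, gamma: float) -> np.ndarray:
    """R = Rz(gamma) Ry(xi) Rx(psi), angles in radians."""
    cx, sx = np.cos(psi), np.sin(psi)
    cy, sy = np.cos(xi), np.sin(xi)
    cz, sz = np.cos(gamma), np.sin(gamma)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_from_rotation(r: np.ndarray) -> tuple[float, float, float]:
    """ZYX Euler decomposition with xi on the canonical branch [-pi/2, pi/2].

    At gimbal lock (|xi| = pi/2 so cos(xi) = 0) psi and gamma are not
    separately identifiable; the convention here sets gamma = 0 and absorbs
    the remaining angle into psi.
    """
    r = np.asarray(r, float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
        raise ValueError("input is not a proper rotation")
    sin_xi = -r[2, 0]
    sin_xi = np.clip(sin_xi, -1.0, 1.0)
    xi = float(np.arcsin(sin_xi))
    if abs(abs(sin_xi) - 1.0) < 1e-10:  # gimbal lock
        gamma = 0.0
        if sin_xi > 0:   # xi = +pi/2: R[0,1] = sin(psi+gamma), R[1,1] = cos(..)
            psi = float(np.arctan2(r[0, 1], r[1, 1]))
        else:            # xi = -pi/2
            psi = float(np.arctan2(-r[0, 1], r[1, 1]))
        return psi, xi, gamma
    psi = float(np.arctan2(r[2, 1], r[2, 2]))
    gamma = float(np.arctan2(r[1, 0], r[0, 0]))
    return psi, xi, gamma


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, SurfaceMesh):
        return m.vertices
    return np.asarray(m, float)


def procrustes_rotation(m, m_ref, center: bool = True) -> ProcrustesResult:
    """Optimal proper rotation mapping ``m`` onto ``m_ref``.

    Both point sets are (defensively) centered and unit-normalized; the
    rotation comes from the SVD of M^T M_ref with the last singular vector
    sign-flipped when det(U V^T) = -1.  Repeated singular values make the
    optimum non-unique; the SVD's deterministic ordering provides a stable
    tie-break, and a warning is emitted when the cross-covariance is
    rank-deficient.
    """
    m = _as_matrix(m)
    m_ref = _as_matrix(m_ref)
    if m.shape != m_ref.shape:
        raise ValueError("point sets must share shape and correspondence")
    if center:
        m = m - m.mean(axis=0)
        m_ref = m_ref - m_ref.mean(axis=0)
    m = unit_normalize(m)
    m_ref = unit_normalize(m_ref)
    h = m.T @ m_ref
    u, s, vt = np.linalg.svd(h)
    if np.linalg.matrix_rank(h, tol=1e-12) < 3:
        warnings.warn("rank-deficient cross-covariance; rotation not unique",
                      RuntimeWarning, stacklevel=2)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        u = u.copy()
        u[:, -1] *= -1.0
    rot = u @ vt
    residual = float(np.linalg.norm(m @ rot - m_ref))
    return ProcrustesResult(rotation=rot,
                            euler_zyx=euler_from_rotation(rot),
                            residual=residual)


def fit_policy(dataset: list, reference=None, center: bool = True) -> AugmentPolicy:
    """Derive the augmentation policy from a training set.

    Angle ranges are elementwise min/max of the per-shape ZYX Euler angles
    against the reference (default: dataset element 0); the norm range spans
    the pre-normalization Frobenius norms of the centered shapes.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    if reference is None:
        reference = dataset[0]
    ref = _as_matrix(reference)
    if center:
        ref = ref - ref.mean(axis=0)
    if len(dataset) == 1:
        warnings.warn("single-mesh dataset: identity-only augmentation policy",
                      RuntimeWarning, stacklevel=2)
    angles = []
    norms = []
    for item in dataset:
        m = _as_matrix(item)
        if center:
            m = m - m.mean(axis=0)
        norms.append(float(np.linalg.norm(m)))
        res = procrustes_rotation(m, ref, center=False)
        angles.append(res.euler_zyx)
    ang = np.asarray(angles)
    return AugmentPolicy(
        psi_range=(float(ang[:, 0].min()), float(ang[:, 0].max())),
        xi_range=(float(ang[:, 1].min()), float(ang[:, 1].max())),
        gamma_range=(float(ang[:, 2].min()), float(ang[:, 2].max())),
        norm_range=(float(min(norms)), float(max(norms))),
        n_transforms=3,
    )


def sample_augmentation(policy: AugmentPolicy, rng: np.random.Generator) -> Transform:
    """Draw one transform: each of {identity, scale, rotation} with prob 1/K."""
    kind = ("identity", "scale", "rotation")[int(rng.integers(policy.n_transforms))]
    if kind == "identity":
        return Transform("identity")
    if kind == "scale":
        return Transform("scale", scale=float(rng.uniform(*policy.norm_range)))
    psi = float(rng.uniform(*policy.psi_range))
    xi = float(rng.uniform(*policy.xi_range))
    gamma = float(rng.uniform(*policy.gamma_range))
    return Transform("rotation", rotation=rotation_from_euler(psi, xi, gamma))


def apply_augmentation(mesh, transform: Transform):
    """Apply a sampled transform; faces and vertex count never change.

    Rotation: M_aug = M R^T.  Scale: M_aug = M * s_rand / ||M||_F (the output
    norm equals s_rand exactly).
    """
    verts = _as_matrix(mesh)
    if transform.kind == "identity":
        out = verts.copy()
    elif transform.kind == "scale":
        norm = np.linalg.norm(verts)
        if norm == 0:
            raise ValueError("cannot rescale an all-zero mesh")
        out = verts * (transform.scale / norm)
    elif transform.kind == "rotation":
        out = verts @ transform.rotation.T
    else:
        raise ValueError(f"unknown transform kind {transform.kind!r}")
    if isinstance(mesh, SurfaceMesh):
        return mesh.with_vertices(out)
    return out
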