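"""Triangle-mesh data model, standard-format I/O and graph primitives.

Every stage of the shape-modelling pipeline consumes meshes that share one
fixed template connectivity: ``N`` vertices (coordinates in cm) and ``T``
triangular faces whose indices never change across a dataset.  This module
provides that container (:class:`SurfaceMesh`), readers/writers for the OBJ,
PLY and OFF formats, and the graph quantities the spectral layers need —
binary adjacency, the symmetric normalized Laplacian

    L = I_N - (D+)^{1/2} A (D+)^{1/2}

(with the Moore–Penrose inverse of the degree matrix, so isolated vertices
are handled by the formula itself) and its largest eigenvalue.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh


class MeshFormatError(ValueError):
    """Raised when a mesh file violates the triangle-mesh contract."""


_FORMATS = ("obj", "ply", "off")


@dataclass
class SurfaceMesh:
    """Fixed-topology triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array, coordinates in cm.
    faces : (T, 3) int array, 0-based vertex indices.
    template_id : opaque identifier of the shared connectivity.
    """

    vertices: np.ndarray
    faces: np.ndarray
    template_id: str = "template"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be a (T, 3) array of triangles")
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                bad = np.where((self.faces < 0) | (self.faces >= n))[0][0]
                raise MeshFormatError(f"face {bad} has out-of-range vertex index")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise MeshFormatError(
                    f"face {np.where(same)[0][0]} is degenerate (repeated vertex)"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.template_id)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity, new coordinates."""
        return SurfaceMesh(np.asarray(vertices, float), self.faces, self.template_id)


@dataclass
class MeshGraph:
    """Graph view of a mesh: adjacency, degrees, normalized Laplacian, λ_max."""

    adjacency: sp.csr_matrix
    degree: np.ndarray
    laplacian: sp.csr_matrix
    lambda_max: float

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_ascii_triangles(path: str, fmt: str) -> None:
    """Reject non-triangular faces in ASCII files before trimesh triangulates
    them silently."""
    if fmt == "obj":
        with open(path, "r", errors="replace") as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("f ") or line.startswith("f\t"):
                    n_idx = len(line.split()) - 1
                    if n_idx != 3:
                        raise MeshFormatError(
                            f"{path}:{lineno}: face has {n_idx} vertices; "
                            "only triangles are supported"
                        )
    elif fmt == "off":
        with open(path, "r", errors="replace") as fh:
            tokens: list[str] = []
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    tokens.extend(line.split())
        if tokens and tokens[0] == "OFF":
            tokens = tokens[1:]
        if len(tokens) < 3:
            raise MeshFormatError(f"{path}: truncated OFF header")
        nv, nf = int(tokens[0]), int(tokens[1])
        pos = 3 + 3 * nv
        for f in range(nf):
            if pos >= len(tokens):
                raise MeshFormatError(f"{path}: truncated OFF face block")
            cnt = int(tokens[pos])
            if cnt != 3:
                raise MeshFormatError(
                    f"{path}: face {f} has {cnt} vertices; only triangles are supported"
                )
            pos += 1 + cnt
    elif fmt == "ply":
        with open(path, "rb") as fh:
            header = fh.read(4096).decode("ascii", errors="replace")
        if "format ascii" not in header:
            return  # binary PLY: written by this package as triangles
        with open(path, "r", errors="replace") as fh:
            lines = fh.read().splitlines()
        n_vert = n_face = 0
        body_at = 0
        for i, line in enumerate(lines):
            parts = line.split()
            if parts[:2] == ["element", "vertex"]:
                n_vert = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                n_face = int(parts[2])
            elif parts[:1] == ["end_header"]:
                body_at = i + 1
                break
        for f in range(n_face):
            row = lines[body_at + n_vert + f].split()
            if row and int(row[0]) != 3:
                raise MeshFormatError(
                    f"{path}: face {f} has {row[0]} vertices; only triangles are supported"
                )


def read_mesh(path: str, fmt: str | None = None) -> SurfaceMesh:
    """Read a triangle mesh from OBJ, PLY or OFF.

    Non-triangular faces are rejected (never silently triangulated), and any
    out-of-range face index raises :class:`MeshFormatError` naming the face.
    """
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_ascii_triangles(path, fmt)
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or tm.faces.shape[1] != 3:
        raise MeshFormatError(f"{path} is not a triangle mesh")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64),
                       template_id=os.path.basename(path))


def write_mesh(mesh: SurfaceMesh, path: str, fmt: str | None = None,
               binary: bool = False) -> None:
    """Write a mesh; the file round-trips through :func:`read_mesh`.

    ``binary`` selects binary little-endian PLY (ignored for OBJ/OFF).
    """
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if mesh.n_vertices == 0:
        raise MeshFormatError("refusing to write a mesh with no vertices")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(
            tm, encoding="binary_little_endian" if binary else "ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        tm.export(path, file_type=fmt)


# ---------------------------------------------------------------------------
# Graph / geometry primitives
# ---------------------------------------------------------------------------

def edge_list(mesh: SurfaceMesh) -> np.ndarray:
    """Unique undirected edges as a sorted (E, 2) array of index pairs."""
    f = mesh.faces
    if f.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def adjacency_matrix(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Binary symmetric adjacency: a_ij = 1 iff i and j share a face edge."""
    n = mesh.n_vertices
    e = edge_list(mesh)
    if len(e) == 0:
        return sp.csr_matrix((n, n))
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    return sp.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))


def normalized_laplacian(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """L = I - (D+)^{1/2} A (D+)^{1/2}; zero-degree vertices get L_ii = 1."""
    adjacency = sp.csr_matrix(adjacency)
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    d_half = sp.diags(inv_sqrt)
    n = adjacency.shape[0]
    lap = sp.identity(n, format="csr") - d_half @ adjacency @ d_half
    # enforce exact symmetry against rounding in the triple product
    return sp.csr_matrix((lap + lap.T) * 0.5)


def largest_eigenvalue(laplacian: sp.spmatrix, tol: float = 1e-6) -> float:
    """Largest Laplacian eigenvalue via an iterative sparse solver.

    Falls back to the analytic bound 2.0 for a normalized Laplacian when the
    solver cannot converge; the Chebyshev rescaling stays well-defined either
    way.
    """
    n = laplacian.shape[0]
    if n <= 2:
        return float(np.linalg.eigvalsh(laplacian.toarray()).max())
    try:
        val = spla.eigsh(
            laplacian.asfptype(), k=1, which="LA", tol=tol,
            return_eigenvectors=False, maxiter=50 * n,
            v0=np.ones(n) / np.sqrt(n),
        )
        lam = float(val[0])
    except (spla.ArpackNoConvergence, RuntimeError):
        return 2.0
    # guard against an iterative under-estimate exceeding the analytic bound
    return float(min(max(lam, 0.0), 2.0))


def build_graph(mesh: SurfaceMesh) -> MeshGraph:
    """Adjacency, degrees, symmetric normalized Laplacian and λ_max."""
    adj = adjacency_matrix(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = normalized_laplacian(adj)
    lam = largest_eigenvalue(lap)
    return MeshGraph(adjacency=adj, degree=deg, laplacian=lap, lambda_max=lam)


def face_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit face normals by the right-hand rule on the face vertex order."""
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norms = np.linalg.norm(n, axis=1)
    bad = norms < 1e-14
    if bad.any():
        raise MeshFormatError(
            f"zero-area face(s) at indices {np.where(bad)[0].tolist()}")
    return n / norms[:, None]


__all__ = [
    "SurfaceMesh",
    "MeshGraph",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "edge_list",
    "adjacency_matrix",
    "normalized_laplacian",
    "largest_eigenvalue",
    "build_graph",
    "face_normals",
]
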