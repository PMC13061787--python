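"""Quadric-error mesh simplification and the pooling/unpooling matrices.

Spatial pooling on a fixed-topology mesh is precomputed once per template:
iterative vertex-pair contraction ranked by quadric error produces a chain
of simplified meshes, and each level carries a binary down-sampling matrix
Q_d (selecting the retained vertex subset V_d of V) plus a barycentric
up-sampling matrix Q_u (retained vertices map back one-hot; each discarded
vertex is projected onto its nearest coarse triangle and re-expressed as
convex weights w_i + w_j + w_k = 1 over that triangle's vertices), so that
pooled signals are recovered as V_u = Q_u V_d.

Contractions are restricted to mesh edges, the retained endpoint keeps its
original position (subset semantics — required for Q_d to be a 0/1 selector)
while the quadric error of the merged pair still ranks the queue, and pairs
whose contraction would break local manifoldness are skipped.  Ties break by
(error, lower retained index) so the whole hierarchy is a deterministic pure
function of the template.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh_core import SurfaceMesh, face_normals

__all__ = [
    "PoolingLevel",
    "MeshHierarchy",
    "quadric_simplify",
    "build_matrices",
    "build_hierarchy",
    "pool",
    "unpool",
    "save_hierarchy",
    "load_hierarchy",
]


@dataclass
class PoolingLevel:
    mesh_fine: SurfaceMesh
    mesh_coarse: SurfaceMesh
    retained: np.ndarray       # coarse index -> fine index (ascending)
    q_d: sp.csr_matrix         # (n, N) binary selector
    q_u: sp.csr_matrix         # (N, n) barycentric up-sampler


@dataclass
class MeshHierarchy:
    levels: list[PoolingLevel] = field(default_factory=list)
    factor: int = 4

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def vertex_counts(self) -> list[int]:
        if not self.levels:
            return []
        return [self.levels[0].mesh_fine.n_vertices] + [
            lv.mesh_coarse.n_vertices for lv in self.levels]


# ---------------------------------------------------------------------------
# quadric-error pair contraction
# ---------------------------------------------------------------------------

def _vertex_quadrics(mesh: SurfaceMesh) -> np.ndarray:
    """4x4 plane quadric per vertex: sum over incident face planes."""
    normals = face_normals(mesh)
    v = mesh.vertices
    f = mesh.faces
    d = -np.einsum("ij,ij->i", normals, v[f[:, 0]])
    planes = np.concatenate([normals, d[:, None]], axis=1)  # (T, 4)
    face_q = planes[:, :, None] * planes[:, None, :]        # (T, 4, 4)
    q = np.zeros((mesh.n_vertices, 4, 4))
    for c in range(3):
        np.add.at(q, f[:, c], face_q)
    return q


def _quadric_cost(q: np.ndarray, pos: np.ndarray) -> float:
    h = np.append(pos, 1.0)
    return float(h @ q @ h)


def quadric_simplify(mesh: SurfaceMesh, target_n: int, best_effort: bool = False
                     ) -> tuple[SurfaceMesh, np.ndarray]:
    """Contract minimal-error edges until ``target_n`` vertices remain.

    Returns the coarse mesh plus the retained-vertex index map (coarse index
    -> original fine index).  The retained endpoint of each contraction keeps
    its original coordinates, so coarse vertices are a strict subset of fine
    vertices.  Pairs whose contraction would break local manifoldness (link
    condition) are skipped in favour of the next candidate.
    """
    n = mesh.n_vertices
    if target_n < 4:
        raise ValueError("cannot simplify below 4 vertices")
    if target_n >= n:
        raise ValueError("target_n must be smaller than the vertex count")

    quadrics = _vertex_quadrics(mesh)
    verts = mesh.vertices
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces.tolist())}
    vertex_faces: dict[int, set[int]] = {i: set() for i in range(n)}
    for fi, f in faces.items():
        for vi in f:
            vertex_faces[vi].add(fi)
    neighbors: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b, c in faces.values():
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))

    version = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    heap: list[tuple[float, int, int, int, int]] = []

    def push_edge(i: int, j: int) -> None:
        qsum = quadrics[i] + quadrics[j]
        ci = _quadric_cost(qsum, verts[i])
        cj = _quadric_cost(qsum, verts[j])
        # keep the endpoint whose original position carries less error;
        # ties keep the lower index
        if cj < ci or (cj == ci and j < i):
            keep, rem, cost = j, i, cj
        else:
            keep, rem, cost = i, j, ci
        heapq.heappush(heap, (cost, keep, rem, int(version[i]), int(version[j])))

    seen = set()
    for a, b, c in faces.values():
        for i, j in ((a, b), (b, c), (a, c)):
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                push_edge(*key)

    n_alive = n
    while n_alive > target_n:
        if not heap:
            # every remaining pair would break local manifoldness
            if best_effort:
                import warnings

                warnings.warn(
                    f"simplification stopped at {n_alive} vertices "
                    f"(target {target_n}): manifold-safety skips",
                    RuntimeWarning, stacklevel=2)
                break
            raise RuntimeError(
                f"simplification stalled at {n_alive} vertices (target {target_n})")
        cost, keep, rem, vi, vj = heapq.heappop(heap)
        if not (alive[keep] and alive[rem]):
            continue
        if version[keep] + version[rem] != vi + vj or rem not in neighbors[keep]:
            continue
        # link condition: common neighbours must all belong to shared faces
        shared_faces = vertex_faces[keep] & vertex_faces[rem]
        common = neighbors[keep] & neighbors[rem]
        face_common = set()
        for fi in shared_faces:
            face_common.update(v for v in faces[fi] if v not in (keep, rem))
        if common != face_common or not shared_faces:
            continue
        if len(faces) - len(shared_faces) < 2:
            continue  # never consume the last faces of the coarse mesh

        # contract rem -> keep
        alive[rem] = False
        n_alive -= 1
        quadrics[keep] = quadrics[keep] + quadrics[rem]
        for fi in list(shared_faces):  # faces on the collapsing edge die
            for vv in faces[fi]:
                vertex_faces[vv].discard(fi)
            del faces[fi]
        for fi in list(vertex_faces[rem]):  # remaining faces: rem -> keep
            f = faces[fi]
            newf = tuple(keep if v == rem else v for v in f)
            faces[fi] = newf
            vertex_faces[rem].discard(fi)
            vertex_faces[keep].add(fi)
        for x in neighbors[rem]:
            neighbors[x].discard(rem)
            if x != keep:
                neighbors[x].add(keep)
                neighbors[keep].add(x)
        neighbors[keep].discard(keep)
        del neighbors[rem]
        vertex_faces[rem] = set()
        version[keep] += 1
        for x in neighbors[keep]:
            version[x] += 1
        for x in sorted(neighbors[keep]):
            push_edge(min(keep, x), max(keep, x))

    retained = np.flatnonzero(alive)
    fine_to_coarse = -np.ones(n, dtype=np.int64)
    fine_to_coarse[retained] = np.arange(len(retained))
    out_faces = []
    seen_f = set()
    for fi in sorted(faces):
        f = tuple(int(fine_to_coarse[v]) for v in faces[fi])
        if len(set(f)) < 3:
            continue
        key = frozenset(f)
        if key in seen_f:
            continue
        seen_f.add(key)
        out_faces.append(f)
    coarse = SurfaceMesh(verts[retained],
                         np.asarray(out_faces, np.int64).reshape(-1, 3),
                         template_id=mesh.template_id + f"|n{len(retained)}")
    return coarse, retained


# ---------------------------------------------------------------------------
# pooling matrices
# ---------------------------------------------------------------------------

def _closest_point_barycentric(p: np.ndarray, tri: np.ndarray
                               ) -> tuple[float, np.ndarray]:
    """Squared distance and clamped barycentric weights of the closest point
    of triangle ``tri`` (3x3) to point ``p``."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        w = np.array([1.0, 0.0, 0.0])
    else:
        bp = p - b
        d3, d4 = ab @ bp, ac @ bp
        if d3 >= 0 and d4 <= d3:
            w = np.array([0.0, 1.0, 0.0])
        else:
            cp = p - c
            d5, d6 = ab @ cp, ac @ cp
            if d6 >= 0 and d5 <= d6:
                w = np.array([0.0, 0.0, 1.0])
            else:
                vc = d1 * d4 - d3 * d2
                if vc <= 0 and d1 >= 0 and d3 <= 0:
                    t = d1 / (d1 - d3)
                    w = np.array([1.0 - t, t, 0.0])
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0 and d2 >= 0 and d6 <= 0:
                        t = d2 / (d2 - d6)
                        w = np.array([1.0 - t, 0.0, t])
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
                            t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            w = np.array([0.0, 1.0 - t, t])
                        else:
                            denom = va + vb + vc
                            v = vb / denom
                            u = vc / denom
                            w = np.array([1.0 - u - v, u, v])
    closest = w @ tri
    return float(np.sum((p - closest) ** 2)), w


def build_matrices(fine: SurfaceMesh, coarse: SurfaceMesh, retained: np.ndarray
                   ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """(Q_d, Q_u) for one pooling level.

    Q_d is the 0/1 selector of retained vertices (Q_d V = V_d exactly); Q_u
    maps coarse signals back: one-hot rows for retained vertices, clamped
    barycentric weights over the nearest coarse triangle for discarded ones
    (brute-force point-to-triangle search — template-only cost).
    """
    retained = np.asarray(retained, np.int64)
    if len(np.unique(retained)) != len(retained):
        raise ValueError("retained map must be injective")
    if coarse.n_vertices == 0:
        raise ValueError("coarse mesh is empty")
    n_fine, n_coarse = fine.n_vertices, coarse.n_vertices
    q_d = sp.csr_matrix(
        (np.ones(n_coarse), (np.arange(n_coarse), retained)),
        shape=(n_coarse, n_fine))

    rows, cols, vals = [], [], []
    coarse_of_fine = -np.ones(n_fine, dtype=np.int64)
    coarse_of_fine[retained] = np.arange(n_coarse)
    tri_pts = coarse.vertices[coarse.faces]  # (T, 3, 3)
    for p_idx in range(n_fine):
        ci = coarse_of_fine[p_idx]
        if ci >= 0:
            rows.append(p_idx)
            cols.append(ci)
            vals.append(1.0)
            continue
        p = fine.vertices[p_idx]
        best = (np.inf, None, None)
        for t_idx in range(len(tri_pts)):
            d2, w = _closest_point_barycentric(p, tri_pts[t_idx])
            if d2 < best[0] - 1e-15:
                best = (d2, t_idx, w)
        _, t_idx, w = best
        w = np.clip(w, 0.0, 1.0)
        w = w / w.sum()
        for local, wt in enumerate(w):
            if wt > 0:
                rows.append(p_idx)
                cols.append(int(coarse.faces[t_idx, local]))
                vals.append(float(wt))
    q_u = sp.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))
    q_u.sum_duplicates()
    return q_d, q_u


def build_hierarchy(template: SurfaceMesh, n_levels: int = 4, factor: int = 4
                    ) -> MeshHierarchy:
    """Chain of pooling levels, each reducing the vertex count by ``factor``
    (per-level targets clamped at 4 vertices).  Deterministic in the template."""
    if n_levels == 0:
        return MeshHierarchy(levels=[], factor=factor)
    hier = MeshHierarchy(levels=[], factor=factor)
    current = template
    for _ in range(n_levels):
        target = max(4, int(np.ceil(current.n_vertices / factor)))
        if target >= current.n_vertices:
            raise ValueError(
                f"template too small: cannot pool {current.n_vertices} vertices "
                f"by a factor of {factor}")
        coarse, retained = quadric_simplify(current, target, best_effort=True)
        q_d, q_u = build_matrices(current, coarse, retained)
        hier.levels.append(PoolingLevel(current, coarse, retained, q_d, q_u))
        current = coarse
    return hier


def _apply_sparse(mat: sp.spmatrix, signal: np.ndarray) -> np.ndarray:
    signal = np.asarray(signal)
    if signal.dtype.kind != "f":
        signal = signal.astype(float)
    if signal.ndim == 2:
        return mat @ signal
    if signal.ndim == 3:
        b, n, f = signal.shape
        flat = np.ascontiguousarray(np.moveaxis(signal, 0, 1)).reshape(n, b * f)
        out = mat @ flat
        return np.moveaxis(out.reshape(mat.shape[0], b, f), 0, 1)
    raise ValueError("signal must be (N, F) or (B, N, F)")


def pool(signal: np.ndarray, q_d: sp.spmatrix) -> np.ndarray:
    """Down-sample a node signal: exact sparse product Q_d S."""
    if signal.shape[-2] != q_d.shape[1]:
        raise ValueError("signal rows do not match Q_d columns")
    return _apply_sparse(q_d, signal)


def unpool(signal: np.ndarray, q_u: sp.spmatrix) -> np.ndarray:
    """Up-sample a coarse node signal: exact sparse product Q_u S."""
    if signal.shape[-2] != q_u.shape[1]:
        raise ValueError("signal rows do not match Q_u columns")
    return _apply_sparse(q_u, signal)


# ---------------------------------------------------------------------------
# serialization: one archive per template, keyed by a content hash
# ---------------------------------------------------------------------------

def template_hash(mesh: SurfaceMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]


def save_hierarchy(hier: MeshHierarchy, path: str) -> None:
    """Store all levels (meshes + sparse triplets) in one .npz archive."""
    arrays: dict[str, np.ndarray] = {
        "factor": np.array(hier.factor),
        "n_levels": np.array(hier.n_levels),
    }
    if hier.levels:
        arrays["template_hash"] = np.array(template_hash(hier.levels[0].mesh_fine))
    for i, lv in enumerate(hier.levels):
        arrays[f"l{i}_fine_v"] = lv.mesh_fine.vertices
        arrays[f"l{i}_fine_f"] = lv.mesh_fine.faces
        arrays[f"l{i}_coarse_v"] = lv.mesh_coarse.vertices
        arrays[f"l{i}_coarse_f"] = lv.mesh_coarse.faces
        arrays[f"l{i}_retained"] = lv.retained
        for name, mat in (("qd", lv.q_d), ("qu", lv.q_u)):
            coo = mat.tocoo()
            arrays[f"l{i}_{name}_ijv"] = np.stack(
                [coo.row.astype(float), coo.col.astype(float), coo.data])
            arrays[f"l{i}_{name}_shape"] = np.array(mat.shape)
    np.savez(path, **arrays)


def load_hierarchy(path: str) -> MeshHierarchy:
    data = np.load(path, allow_pickle=False)
    hier = MeshHierarchy(levels=[], factor=int(data["factor"]))
    for i in range(int(data["n_levels"])):
        mats = {}
        for name in ("qd", "qu"):
            i_, j_, v_ = data[f"l{i}_{name}_ijv"]
            shape = tuple(data[f"l{i}_{name}_shape"])
            mats[name] = sp.csr_matrix(
                (v_, (i_.astype(int), j_.astype(int))), shape=shape)
        hier.levels.append(PoolingLevel(
            SurfaceMesh(data[f"l{i}_fine_v"], data[f"l{i}_fine_f"]),
            SurfaceMesh(data[f"l{i}_coarse_v"], data[f"l{i}_coarse_f"]),
            data[f"l{i}_retained"], mats["qd"], mats["qu"]))
    return hier
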