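"""Synthetic abdominal-aortic-aneurysm cohort generator.

Generates tube-like vessel surfaces with a fixed template triangulation and
controlled anatomical factors: an aneurysm sac (Gaussian radial bulge of a
given amplitude, axial position and width), proximal neck angulation, axial
torsion, trunk length, vertex-wise radial noise, plus dataset-level global
scale and orientation.  The global scale/rotation factors exist precisely so
that Procrustes-based augmentation has real nuisance transformations to
discover and re-sample.

The radius profile along the normalized axial coordinate t in [0, 1] is

    r(t) = base_radius + sac_amplitude * exp(-(t - sac_center)^2 / (2 sac_width'^2))

with the axial Gaussian width expressed in cm of arclength and converted to
the t scale internally.  Default factor ranges are sized for an infrarenal
aortic segment (lengths ~10 cm, healthy lumen radius ~1 cm, sacs up to
~2.5 cm radius) — the vertex count (40 rings x 16 vertices = 640) keeps four
factor-4 pooling levels meaningful while training stays a desk-scale job.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import numpy as np

from .mesh_core import SurfaceMesh

__all__ = [
    "ShapeParams",
    "TemplateSpec",
    "DEFAULT_RANGES",
    "sample_params",
    "generate_mesh",
    "generate_dataset",
    "params_to_frame",
]


@dataclass
class ShapeParams:
    """Generative factors of one synthetic vessel (lengths in cm, angles deg)."""

    length: float = 10.0          # trunk arclength
    base_radius: float = 1.0      # healthy lumen radius
    sac_amplitude: float = 1.0    # added radius at the sac peak
    sac_center: float = 0.5       # sac position as a fraction of length
    sac_width: float = 1.5        # axial Gaussian width of the sac
    neck_angle: float = 0.0       # centerline bend near the proximal neck
    torsion: float = 0.0          # total axial twist along the trunk
    noise_sd: float = 0.0         # radial vertex jitter (cm)
    global_scale: float = 1.0
    global_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # ZYX Euler, deg

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.sac_amplitude < 0:
            raise ValueError("sac_amplitude must be nonnegative")
        if not 0.0 < self.sac_center < 1.0:
            raise ValueError("sac_center must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.global_rotation = tuple(float(a) for a in np.atleast_1d(
            np.asarray(self.global_rotation, float)).reshape(3))


@dataclass
class TemplateSpec:
    """Connectivity template: faces depend only on this, never on ShapeParams."""

    n_axial: int = 40
    n_circ: int = 16
    closed_ends: bool = False

    @property
    def n_vertices(self) -> int:
        return self.n_axial * self.n_circ + (2 if self.closed_ends else 0)

    def build_faces(self) -> np.ndarray:
        """Triangulate the tube: two triangles per quad, optional apex fans."""
        na, nc = self.n_axial, self.n_circ
        faces = []
        for i in range(na - 1):
            for j in range(nc):
                a = i * nc + j
                b = i * nc + (j + 1) % nc
                c = (i + 1) * nc + j
                d = (i + 1) * nc + (j + 1) % nc
                faces.append((a, d, b))
                faces.append((a, c, d))
        if self.closed_ends:
            apex0 = na * nc
            apex1 = na * nc + 1
            for j in range(nc):
                faces.append((apex0, j, (j + 1) % nc))
                base = (na - 1) * nc
                faces.append((apex1, base + (j + 1) % nc, base + j))
        return np.asarray(faces, dtype=np.int64)


#: Study-condition ranges the 60-mesh cohort is drawn from.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "length": (8.0, 12.0),
    "base_radius": (0.8, 1.2),
    "sac_amplitude": (0.5, 1.5),
    "sac_center": (0.4, 0.6),
    "sac_width": (1.0, 2.0),
    "neck_angle": (0.0, 30.0),
    "torsion": (0.0, 20.0),
    "noise_sd": (0.02, 0.02),
    "global_scale": (0.8, 1.2),
    "global_rotation": (-15.0, 15.0),
}


def sample_params(rng_seed: int | np.random.Generator,
                  ranges: dict[str, tuple[float, float]] | None = None) -> ShapeParams:
    """Draw one ShapeParams with each field uniform over its range."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    values: dict[str, object] = {}
    for f in fields(ShapeParams):
        lo, hi = ranges[f.name]
        if hi < lo:
            raise ValueError(f"inverted range for {f.name}: ({lo}, {hi})")
        if f.name == "global_rotation":
            values[f.name] = tuple(rng.uniform(lo, hi, size=3))
        else:
            values[f.name] = float(rng.uniform(lo, hi))
    return ShapeParams(**values)


def _rotation_zyx(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """R = Rz(gamma) Ry(xi) Rx(psi), angles given as (psi, xi, gamma) degrees."""
    psi, xi, gamma = np.deg2rad(np.asarray(angles_deg, float))
    cx, sx = np.cos(psi), np.sin(psi)
    cy, sy = np.cos(xi), np.sin(xi)
    cz, sz = np.cos(gamma), np.sin(gamma)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def generate_mesh(params: ShapeParams, template: TemplateSpec | None = None,
                  rng: np.random.Generator | None = None) -> SurfaceMesh:
    """Sweep rings of radius r(t) along a bent, twisted centerline.

    The proximal third of the centerline carries the neck bend (tangent
    rotated in the x-z plane by an angle decaying linearly from
    ``neck_angle`` to zero); torsion rotates the ring phase linearly with t.
    Radial Gaussian noise (sd ``noise_sd``) is applied along each vertex's
    outward ring direction, then global scale and ZYX-Euler rotation act on
    the centered coordinates.  Self-intersection is not checked.
    """
    template = template or TemplateSpec()
    rng = rng or np.random.default_rng(0)
    na, nc = template.n_axial, template.n_circ
    t = np.linspace(0.0, 1.0, na)

    # centerline: integrate unit tangents bent in the x-z plane near the neck
    bend = np.deg2rad(params.neck_angle) * np.clip(1.0 - t / 0.3, 0.0, 1.0)
    tangents = np.stack([np.sin(bend), np.zeros_like(bend), np.cos(bend)], axis=1)
    ds = params.length / (na - 1)
    center = np.concatenate([
        np.zeros((1, 3)), np.cumsum(tangents[:-1] * ds, axis=0)])
    center -= center.mean(axis=0)

    # orthonormal ring frames perpendicular to the tangent
    up = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(up, tangents)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tangents, e1)

    width_t = max(params.sac_width / max(params.length, 1e-9), 1e-9)
    radius = params.base_radius + params.sac_amplitude * np.exp(
        -((t - params.sac_center) ** 2) / (2.0 * width_t**2))

    theta = (2.0 * np.pi * np.arange(nc) / nc)[None, :] \
        + np.deg2rad(params.torsion) * t[:, None]
    radial_dir = (np.cos(theta)[..., None] * e1[:, None, :]
                  + np.sin(theta)[..., None] * e2[:, None, :])
    r = radius[:, None, None]
    if params.noise_sd > 0:
        r = r + params.noise_sd * rng.standard_normal((na, nc, 1))
    verts = (center[:, None, :] + r * radial_dir).reshape(na * nc, 3)

    if template.closed_ends:
        verts = np.concatenate([verts, center[[0]], center[[-1]]])

    verts = verts - verts.mean(axis=0)
    verts = params.global_scale * (verts @ _rotation_zyx(params.global_rotation).T)
    return SurfaceMesh(verts, template.build_faces(),
                       template_id=f"tube-{na}x{nc}-{template.closed_ends}")


def generate_dataset(n: int = 60, seed: int = 0,
                     ranges: dict[str, tuple[float, float]] | None = None,
                     template: TemplateSpec | None = None,
                     ) -> tuple[list[SurfaceMesh], list[ShapeParams]]:
    """Generate a cohort of ``n`` meshes sharing one faces array.

    The stored ShapeParams allow parameter-recovery experiments (does a
    learned latent mode track a planted factor?) and give the augmentation
    module planted transformations to rediscover.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = template or TemplateSpec()
    root = np.random.SeedSequence(seed)
    meshes: list[SurfaceMesh] = []
    params_list: list[ShapeParams] = []
    for child in root.spawn(n):
        rng = np.random.default_rng(child)
        p = sample_params(rng, ranges)
        meshes.append(generate_mesh(p, template, rng))
        params_list.append(p)
    return meshes, params_list


def params_to_frame(params_list: list[ShapeParams]):
    """Flatten ShapeParams into a pandas DataFrame (one column per factor)."""
    import pandas as pd

    rows = []
    for p in params_list:
        d = asdict(p)
        rot = d.pop("global_rotation")
        d["rot_psi"], d["rot_xi"], d["rot_gamma"] = rot
        rows.append(d)
    return pd.DataFrame(rows)
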