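"""Latent-space tools: greedy mode ranking, extrapolation, interpolation.

A trained beta-VAE does not order its latent coordinates the way PCA orders
principal components.  The greedy ranking implemented here recovers such an
order: at each step, every still-unranked coordinate j is tried with the
already-ranked set (all other coordinates of each sample's latent mean
zeroed), the dataset-mean reconstruction percentage E is evaluated, and the
argmax is appended (ties broken by lower index).  The resulting cumulative
E / Chamfer-error curves play the role of PCA's explained-variance curves.

Two generation strategies act on latent means:

* extrapolation — z = mu + S * eps with eps ~ N(0, I); the amplitude S
  controls deviation from the source shape, and samples are rejected (and
  redrawn) whenever any coordinate leaves the mean +/- 3 sd box of the
  training latent distribution, keeping generated anatomy plausible;
* interpolation — the affine path mu(i) = mu1 + (i/n)(mu2 - mu1),
  i = 0..n, decoded step by step into a smooth shape transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn_bvae_model import GCNBetaVAE
from .mesh_core import SurfaceMesh
from .metrics_eval import chamfer_error, rcd, reconstruction_percentage

__all__ = [
    "RankedModes",
    "LatentStats",
    "latent_stats",
    "rank_modes",
    "extrapolate",
    "interpolate",
    "generate_meshes",
]


@dataclass
class RankedModes:
    order: np.ndarray             # permutation of 0..d-1, best first
    cumulative_e: np.ndarray      # (d,) mean E with the first l modes active
    cumulative_err_cd: np.ndarray  # (d,) mean Chamfer error likewise


@dataclass
class LatentStats:
    mean: np.ndarray
    sd: np.ndarray


def latent_stats(model: GCNBetaVAE, meshes: list[SurfaceMesh]) -> LatentStats:
    """Per-dimension empirical mean/sd of training latent means."""
    mus = np.stack([model.encode(m).mu for m in meshes])
    return LatentStats(mus.mean(axis=0), mus.std(axis=0, ddof=0))


def _masked_scores(model: GCNBetaVAE, mus: np.ndarray, targets: np.ndarray,
                   active: list[int]) -> tuple[float, float]:
    mask = np.zeros(mus.shape[1])
    mask[active] = 1.0
    recon = model.decode_batch(mus * mask)
    e_vals = [reconstruction_percentage(recon[i], targets[i])
              for i in range(len(targets))]
    cd_vals = [chamfer_error(recon[i], targets[i]) for i in range(len(targets))]
    return float(np.mean(e_vals)), float(np.mean(cd_vals))


def rank_modes(model: GCNBetaVAE, meshes: list[SurfaceMesh]) -> RankedModes:
    """Greedy ranking of latent modes by dataset-mean reconstruction E.

    Encodings use z = mu; masking zeroes every coordinate outside the active
    set.  Deterministic: ties break by lower mode index (np.argmax).
    """
    if not meshes:
        raise ValueError("dataset must be nonempty")
    mus = np.stack([model.encode(m).mu for m in meshes])
    if not np.all(np.isfinite(mus)):
        raise ValueError("encoder produced non-finite latents")
    targets = np.stack([model._prep(m) for m in meshes])
    d = mus.shape[1]
    ranked: list[int] = []
    cum_e = np.zeros(d)
    cum_cd = np.zeros(d)
    remaining = list(range(d))
    for step in range(d):
        scores = np.full(d, -np.inf)
        cds = np.zeros(d)
        for j in remaining:
            e, cd = _masked_scores(model, mus, targets, ranked + [j])
            scores[j] = e
            cds[j] = cd
        best = int(np.argmax(scores))
        ranked.append(best)
        remaining.remove(best)
        cum_e[step] = scores[best]
        cum_cd[step] = cds[best]
    return RankedModes(np.asarray(ranked), cum_e, cum_cd)


def extrapolate(mu: np.ndarray, s: float, n_samples: int,
                rng: np.random.Generator, stats: LatentStats,
                sd_clip: float = 3.0, max_tries: int = 10_000) -> np.ndarray:
    """Draw z = mu + S * eps, eps ~ N(0, I), inside the latent 3-sd box.

    Samples with any coordinate outside stats.mean +/- sd_clip * stats.sd
    are rejected and redrawn; a rejection rate above 99% raises with advice
    to lower S.
    """
    if s < 0:
        raise ValueError("S must be nonnegative")
    mu = np.asarray(mu, float)
    lo = stats.mean - sd_clip * stats.sd
    hi = stats.mean + sd_clip * stats.sd
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n_samples:
        if tries >= max_tries:
            rate = 1.0 - len(out) / tries
            raise RuntimeError(
                f"latent rejection rate {rate:.1%} exceeds the sampling budget; "
                f"decrease S (currently {s})")
        z = mu + s * rng.standard_normal(mu.shape)
        tries += 1
        if np.all(z >= lo) and np.all(z <= hi):
            out.append(z)
    return np.stack(out)


def interpolate(mu1: np.ndarray, mu2: np.ndarray, n_steps: int) -> np.ndarray:
    """Affine path mu(i) = mu1 + (i/n)(mu2 - mu1), i = 0..n (n+1 vectors)."""
    mu1 = np.asarray(mu1, float)
    mu2 = np.asarray(mu2, float)
    if mu1.shape != mu2.shape:
        raise ValueError("latent vectors must share dimension")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    t = np.arange(n_steps + 1)[:, None] / n_steps
    return mu1[None] + t * (mu2 - mu1)[None]


def generate_meshes(model: GCNBetaVAE, latents: np.ndarray,
                    reference: SurfaceMesh) -> tuple[list[SurfaceMesh], np.ndarray]:
    """Decode latent vectors and score each mesh's RCD against a reference."""
    latents = np.atleast_2d(np.asarray(latents, float))
    faces = model.hierarchy.levels[0].mesh_fine.faces
    ref = model._prep(reference)
    meshes = []
    rcds = []
    for z in latents:
        verts = model.decode(z)
        meshes.append(SurfaceMesh(verts, faces, template_id=reference.template_id))
        rcds.append(rcd(verts, ref))
    return meshes, np.asarray(rcds)
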