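"""Graph-convolutional beta-VAE: architecture, training, checkpoints.

The encoder consumes raw vertex coordinates (N x 3, cm, optionally centered)
on the fixed template and applies four blocks of Chebyshev spectral
convolution -> ELU -> pooling (Q_d), with channel widths 3 -> 32 -> 32 ->
32 -> 64 and a factor-4 vertex reduction per block.  The coarsest features
are flattened through a linear hidden layer into two parallel heads
producing the latent mean mu and log-variance (sigma is parameterized as
exp(half log sigma^2) for numerical stability).  The decoder mirrors the
encoder: linear layers map z back to coarsest-level features, four blocks of
unpooling (Q_u) -> convolution -> ELU restore the template resolution, and a
final convolution with no activation emits the reconstructed coordinates.

Sampling uses the reparameterization z = mu + sigma * eps with
eps ~ N(0, I); deterministic reconstruction uses z = mu.  The KL term
against the standard-normal prior has the closed form

    KL = -1/2 sum_i (1 + log sigma_i^2 - mu_i^2 - sigma_i^2).

Everything — forward, adjoint, Adam — is plain NumPy/SciPy on the sparse
template operators; the whole network is small enough that desk-scale CPU
training takes seconds per epoch.  Training defaults (Adam, lr 1e-3, batch
16) live in :class:`TrainConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .mesh_core import SurfaceMesh, build_graph
from .mesh_pooling import MeshHierarchy, pool, unpool, save_hierarchy, load_hierarchy
from .procaug import AugmentPolicy, Transform, sample_augmentation, apply_augmentation
from .recon_losses import (
    LossWeights,
    vertex_loss_grad,
    chamfer_loss_grad,
    edge_loss_grad,
    normal_loss_grad,
)
from .spectral_conv import ChebKernel, cheb_backward, cheb_forward, rescale_laplacian

__all__ = [
    "LatentDistribution",
    "ModelConfig",
    "TrainConfig",
    "GCNBetaVAE",
    "kl_divergence",
    "reparameterize",
    "reconstruct",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class LatentDistribution:
    """Per-sample encoder output: mean and standard deviation of q(z|x)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float).ravel()
        self.sigma = np.asarray(self.sigma, float).ravel()
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    @property
    def d(self) -> int:
        return len(self.mu)


@dataclass
class ModelConfig:
    latent_d: int = 8
    conv_channels: tuple[int, ...] = (32, 32, 32, 64)
    pool_factor: int = 4
    cheb_order: int = 6
    hidden_width: int = 64
    center_inputs: bool = True
    dtype: str = "float64"  # "float32" roughly halves CPU training time

    def __post_init__(self) -> None:
        if self.latent_d < 1:
            raise ValueError("latent_d must be >= 1")
        if self.dtype not in ("float64", "float32"):
            raise ValueError("dtype must be 'float64' or 'float32'")


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1.0e-3
    augmentation: str = "none"  # none | procaug | scaling | rotation

    def __post_init__(self) -> None:
        if self.augmentation not in ("none", "procaug", "scaling", "rotation"):
            raise ValueError(f"unknown augmentation arm {self.augmentation!r}")


def kl_divergence(mu, sigma=None) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)); always >= 0."""
    if isinstance(mu, LatentDistribution):
        mu, sigma = mu.mu, mu.sigma
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    log_var = 2.0 * np.log(sigma)
    return float(-0.5 * np.sum(1.0 + log_var - mu**2 - sigma**2))


def reparameterize(dist: LatentDistribution, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps (elementwise)."""
    eps = np.asarray(eps, float).ravel()
    if eps.shape != dist.mu.shape:
        raise ValueError("eps must match the latent dimension")
    return dist.mu + dist.sigma * eps


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad_from_out(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # d elu/dx = 1 for x > 0 else elu(x) + 1
    return np.where(x > 0, 1.0, y + 1.0)


class GCNBetaVAE:
    """Encoder/decoder pair bound to one precomputed mesh hierarchy."""

    def __init__(self, hierarchy: MeshHierarchy, config: ModelConfig | None = None,
                 seed: int = 0):
        if hierarchy.n_levels == 0:
            raise ValueError("model requires a non-trivial pooling hierarchy")
        self.hierarchy = hierarchy
        self.config = config or ModelConfig()
        if len(self.config.conv_channels) != hierarchy.n_levels:
            raise ValueError("conv_channels length must equal the number of "
                             "pooling levels")
        dt = np.dtype(self.config.dtype)
        self.np_dtype = dt
        # one rescaled Laplacian per resolution (lambda_max recomputed per level)
        self.lbars = [rescale_laplacian(build_graph(lv.mesh_fine)).astype(dt)
                      for lv in hierarchy.levels]
        self.q_ds = [lv.q_d.astype(dt) for lv in hierarchy.levels]
        self.q_us = [lv.q_u.astype(dt) for lv in hierarchy.levels]
        self.q_dts = [m.T.tocsr() for m in self.q_ds]
        self.q_uts = [m.T.tocsr() for m in self.q_us]
        self.counts = hierarchy.vertex_counts()
        self.n_coarse = self.counts[-1]
        self.params: dict[str, np.ndarray] = {}
        self._init_params(seed)

    # -- parameters ---------------------------------------------------------

    def _glorot(self, rng, shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(self.np_dtype)

    def _init_params(self, seed: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(seed)
        k = cfg.cheb_order
        chans = (3,) + tuple(cfg.conv_channels)
        p = self.params
        for i in range(len(cfg.conv_channels)):
            p[f"enc{i}_theta"] = self._glorot(
                rng, (k, chans[i], chans[i + 1]), k * chans[i], chans[i + 1])
            p[f"enc{i}_bias"] = np.zeros(chans[i + 1], dtype=self.np_dtype)
        flat = self.n_coarse * chans[-1]
        p["enc_lin_w"] = self._glorot(rng, (flat, cfg.hidden_width), flat,
                                      cfg.hidden_width)
        p["enc_lin_b"] = np.zeros(cfg.hidden_width, dtype=self.np_dtype)
        p["mu_w"] = self._glorot(rng, (cfg.hidden_width, cfg.latent_d),
                                 cfg.hidden_width, cfg.latent_d)
        p["mu_b"] = np.zeros(cfg.latent_d, dtype=self.np_dtype)
        p["logvar_w"] = 0.1 * self._glorot(rng, (cfg.hidden_width, cfg.latent_d),
                                           cfg.hidden_width, cfg.latent_d)
        p["logvar_b"] = np.zeros(cfg.latent_d, dtype=self.np_dtype)
        p["dec_lin1_w"] = self._glorot(rng, (cfg.latent_d, cfg.hidden_width),
                                       cfg.latent_d, cfg.hidden_width)
        p["dec_lin1_b"] = np.zeros(cfg.hidden_width, dtype=self.np_dtype)
        p["dec_lin2_w"] = self._glorot(rng, (cfg.hidden_width, flat),
                                       cfg.hidden_width, flat)
        p["dec_lin2_b"] = np.zeros(flat, dtype=self.np_dtype)
        # decoder convs run coarse -> fine: dec0 at the coarsest level
        dec_chans = list(reversed(chans[1:])) + [chans[1]]
        for i in range(len(cfg.conv_channels)):
            fin, fout = dec_chans[i], dec_chans[i + 1]
            p[f"dec{i}_theta"] = self._glorot(rng, (k, fin, fout), k * fin, fout)
            p[f"dec{i}_bias"] = np.zeros(fout, dtype=self.np_dtype)
        p["out_theta"] = self._glorot(rng, (k, chans[1], 3), k * chans[1], 3)
        p["out_bias"] = np.zeros(3, dtype=self.np_dtype)

    def _kernel(self, name: str) -> ChebKernel:
        return ChebKernel(self.params[f"{name}_theta"], self.params[f"{name}_bias"])

    # -- forward / backward -------------------------------------------------

    def encode_batch(self, x: np.ndarray, cache: dict | None = None) -> tuple:
        """x: (B, N, 3) -> (mu (B, d), log_var (B, d))."""
        x = np.asarray(x, float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.counts[0]:
            raise ValueError("input vertex count does not match the template")
        c = cache if cache is not None else {}
        h = x.astype(self.np_dtype, copy=False)
        for i in range(self.hierarchy.n_levels):
            y, basis = cheb_forward(self.lbars[i], self._kernel(f"enc{i}"), h)
            a = _elu(y)
            c[f"enc{i}_basis"], c[f"enc{i}_pre"], c[f"enc{i}_act"] = basis, y, a
            h = pool(a, self.q_ds[i])
        b = h.shape[0]
        flat = h.reshape(b, -1)
        c["enc_flat"] = flat
        hid_pre = flat @ self.params["enc_lin_w"] + self.params["enc_lin_b"]
        hid = _elu(hid_pre)
        c["enc_hid_pre"], c["enc_hid"] = hid_pre, hid
        mu = hid @ self.params["mu_w"] + self.params["mu_b"]
        log_var = hid @ self.params["logvar_w"] + self.params["logvar_b"]
        log_var = np.clip(log_var, -15.0, 15.0)
        return mu, log_var

    def decode_batch(self, z: np.ndarray, cache: dict | None = None) -> np.ndarray:
        z = np.asarray(z, dtype=self.np_dtype)
        if z.ndim == 1:
            z = z[None]
        c = cache if cache is not None else {}
        c["z"] = z
        h1_pre = z @ self.params["dec_lin1_w"] + self.params["dec_lin1_b"]
        h1 = _elu(h1_pre)
        h2_pre = h1 @ self.params["dec_lin2_w"] + self.params["dec_lin2_b"]
        h2 = _elu(h2_pre)
        c["dec_h1_pre"], c["dec_h1"] = h1_pre, h1
        c["dec_h2_pre"], c["dec_h2"] = h2_pre, h2
        b = z.shape[0]
        h = h2.reshape(b, self.n_coarse, -1)
        n_lev = self.hierarchy.n_levels
        for i in range(n_lev):
            lev_idx = n_lev - 1 - i
            up = unpool(h, self.q_us[lev_idx])
            y, basis = cheb_forward(self.lbars[lev_idx], self._kernel(f"dec{i}"), up)
            a = _elu(y)
            c[f"dec{i}_up"], c[f"dec{i}_basis"] = up, basis
            c[f"dec{i}_pre"], c[f"dec{i}_act"] = y, a
            h = a
        out, basis = cheb_forward(self.lbars[0], self._kernel("out"), h)
        c["out_basis"] = basis
        return out

    def decode_backward(self, d_out: np.ndarray, cache: dict,
                        grads: dict[str, np.ndarray]) -> np.ndarray:
        """Backprop through the decoder; returns dL/dz (B, d)."""
        def acc(name, val):
            grads[name] = grads.get(name, 0.0) + val

        dh, dth, dbi = cheb_backward(self.lbars[0], self._kernel("out"),
                                     cache["out_basis"], d_out)
        acc("out_theta", dth)
        acc("out_bias", dbi)
        n_lev = self.hierarchy.n_levels
        for i in reversed(range(n_lev)):
            lev_idx = n_lev - 1 - i
            dy = dh * _elu_grad_from_out(cache[f"dec{i}_act"], cache[f"dec{i}_pre"])
            dup, dth, dbi = cheb_backward(self.lbars[lev_idx],
                                          self._kernel(f"dec{i}"),
                                          cache[f"dec{i}_basis"], dy)
            acc(f"dec{i}_theta", dth)
            acc(f"dec{i}_bias", dbi)
            dh = pool(dup, self.q_uts[lev_idx])  # adjoint of unpool
        b = dh.shape[0]
        dh2 = dh.reshape(b, -1)
        dh2 = dh2 * _elu_grad_from_out(cache["dec_h2"], cache["dec_h2_pre"])
        acc("dec_lin2_w", cache["dec_h1"].T @ dh2)
        acc("dec_lin2_b", dh2.sum(axis=0))
        dh1 = dh2 @ self.params["dec_lin2_w"].T
        dh1 = dh1 * _elu_grad_from_out(cache["dec_h1"], cache["dec_h1_pre"])
        acc("dec_lin1_w", cache["z"].T @ dh1)
        acc("dec_lin1_b", dh1.sum(axis=0))
        return dh1 @ self.params["dec_lin1_w"].T

    def encode_backward(self, d_mu: np.ndarray, d_logvar: np.ndarray,
                        cache: dict, grads: dict[str, np.ndarray]) -> None:
        def acc(name, val):
            grads[name] = grads.get(name, 0.0) + val

        hid = cache["enc_hid"]
        acc("mu_w", hid.T @ d_mu)
        acc("mu_b", d_mu.sum(axis=0))
        acc("logvar_w", hid.T @ d_logvar)
        acc("logvar_b", d_logvar.sum(axis=0))
        dhid = d_mu @ self.params["mu_w"].T + d_logvar @ self.params["logvar_w"].T
        dhid = dhid * _elu_grad_from_out(cache["enc_hid"], cache["enc_hid_pre"])
        acc("enc_lin_w", cache["enc_flat"].T @ dhid)
        acc("enc_lin_b", dhid.sum(axis=0))
        dflat = dhid @ self.params["enc_lin_w"].T
        b = dflat.shape[0]
        dh = dflat.reshape(b, self.n_coarse, -1)
        for i in reversed(range(self.hierarchy.n_levels)):
            da = unpool(dh, self.q_dts[i])  # adjoint of pool
            dy = da * _elu_grad_from_out(cache[f"enc{i}_act"], cache[f"enc{i}_pre"])
            dh, dth, dbi = cheb_backward(self.lbars[i], self._kernel(f"enc{i}"),
                                         cache[f"enc{i}_basis"], dy)
            acc(f"enc{i}_theta", dth)
            acc(f"enc{i}_bias", dbi)

    # -- public single-mesh API --------------------------------------------

    def _prep(self, mesh) -> np.ndarray:
        v = mesh.vertices if isinstance(mesh, SurfaceMesh) else np.asarray(mesh, float)
        if self.config.center_inputs:
            v = v - v.mean(axis=0)
        return v

    def encode(self, mesh) -> LatentDistribution:
        """Encoder map M -> (mu, sigma) for one mesh on the template."""
        mu, log_var = self.encode_batch(self._prep(mesh)[None])
        return LatentDistribution(mu[0], np.exp(0.5 * log_var[0]))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode one latent vector into template vertex coordinates."""
        return self.decode_batch(np.asarray(z, float)[None])[0]

    def reconstruct(self, mesh) -> np.ndarray:
        """Deterministic round trip decode(encode(M).mu) — no sampling."""
        return self.decode(self.encode(mesh).mu)


def reconstruct(mesh, model: GCNBetaVAE) -> np.ndarray:
    return model.reconstruct(mesh)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _restrict_transform(t: Transform, arm: str) -> Transform:
    if arm == "procaug":
        return t
    allowed = {"scaling": "scale", "rotation": "rotation"}[arm]
    return t if t.kind == allowed else Transform("identity")


def train_model(meshes: list[SurfaceMesh], hierarchy: MeshHierarchy,
                model_config: ModelConfig | None = None,
                weights: LossWeights | None = None,
                train_config: TrainConfig | None = None,
                policy: AugmentPolicy | None = None,
                seed: int = 0,
                callback=None) -> tuple[GCNBetaVAE, list[dict]]:
    """Train a GCN-beta-VAE on a list of template meshes.

    Augmentation (when an arm other than ``none`` is selected) is applied
    online: transforms are re-sampled per mesh per epoch from ``policy``.
    Losses are summed per mesh and averaged over the batch.  Returns the
    trained model and a per-epoch history (mean loss and per-term means).

    All randomness (weight init, batch shuffling, reparameterization noise,
    augmentation draws) derives from named child streams of ``seed``.
    """
    model_config = model_config or ModelConfig()
    weights = weights or LossWeights()
    train_config = train_config or TrainConfig()
    if train_config.augmentation != "none" and policy is None:
        raise ValueError("augmentation requested but no AugmentPolicy given")

    ss = np.random.SeedSequence(seed)
    init_seed, shuffle_ss, eps_ss, aug_ss = ss.spawn(4)
    model = GCNBetaVAE(hierarchy, model_config,
                       seed=int(init_seed.generate_state(1)[0] % (2**31)))
    rng_shuffle = np.random.default_rng(shuffle_ss)
    rng_eps = np.random.default_rng(eps_ss)
    rng_aug = np.random.default_rng(aug_ss)
    opt = _Adam(model.params, train_config.learning_rate)

    faces = meshes[0].faces
    base = np.stack([model._prep(m) for m in meshes]).astype(
        model.np_dtype)  # (n, N, 3)
    n = len(base)
    bs = train_config.batch_size
    history: list[dict] = []

    for epoch in range(train_config.epochs):
        order = rng_shuffle.permutation(n)
        ep_terms = {"total": 0.0, "vertex": 0.0, "chamfer": 0.0, "edge": 0.0,
                    "normal": 0.0, "kl": 0.0}
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            batch = base[idx]
            if train_config.augmentation != "none":
                batch = batch.copy()
                for bi in range(len(batch)):
                    t = _restrict_transform(
                        sample_augmentation(policy, rng_aug),
                        train_config.augmentation)
                    batch[bi] = apply_augmentation(batch[bi], t)
            b = len(batch)
            cache: dict = {}
            mu, log_var = model.encode_batch(batch, cache)
            sigma = np.exp(0.5 * log_var)
            eps = rng_eps.standard_normal(mu.shape).astype(model.np_dtype)
            z = mu + sigma * eps
            dec_cache: dict = {}
            out = model.decode_batch(z, dec_cache)

            d_out = np.zeros_like(out)
            batch_terms = {k: 0.0 for k in ("vertex", "chamfer", "edge", "normal")}
            for bi in range(b):
                m_star = batch[bi]
                gt_n = _safe_normals(m_star, faces)
                lv_, gv = vertex_loss_grad(out[bi], m_star)
                lc_, gc = chamfer_loss_grad(out[bi], m_star)
                le_, ge = edge_loss_grad(out[bi], m_star, faces)
                ln_, gn = normal_loss_grad(out[bi], faces, gt_n)
                batch_terms["vertex"] += lv_
                batch_terms["chamfer"] += lc_
                batch_terms["edge"] += le_
                batch_terms["normal"] += ln_
                d_out[bi] = (weights.alpha_vertex * gv
                             + weights.alpha_chamfer * gc
                             + weights.alpha_edge * ge
                             + weights.alpha_normal * gn)
            d_out /= b

            kl = float(-0.5 * np.sum(1.0 + log_var - mu**2 - sigma**2)) / b
            grads: dict[str, np.ndarray] = {}
            dz = model.decode_backward(d_out, dec_cache, grads)
            d_mu = dz + (weights.beta / b) * mu
            d_logvar = dz * eps * sigma * 0.5 \
                + (weights.beta / b) * 0.5 * (sigma**2 - 1.0)
            model.encode_backward(d_mu, d_logvar, cache, grads)
            opt.step(model.params, grads)

            recon = {k: v / b for k, v in batch_terms.items()}
            total = (weights.beta * kl
                     + weights.alpha_vertex * recon["vertex"]
                     + weights.alpha_chamfer * recon["chamfer"]
                     + weights.alpha_edge * recon["edge"]
                     + weights.alpha_normal * recon["normal"])
            for k in recon:
                ep_terms[k] += recon[k]
            ep_terms["kl"] += kl
            ep_terms["total"] += total
            n_batches += 1
        row = {"epoch": epoch}
        row.update({k: v / n_batches for k, v in ep_terms.items()})
        history.append(row)
        if callback is not None:
            callback(epoch, row, model)
    return model, history


def _safe_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    n = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norms, 1e-14)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: GCNBetaVAE, path: str) -> None:
    """Weights + ModelConfig + hierarchy in a single .npz archive."""
    import io

    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    buf = io.BytesIO()
    save_hierarchy(model.hierarchy, buf)
    buf.seek(0)
    arrays["hierarchy_npz"] = np.frombuffer(buf.read(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> GCNBetaVAE:
    import io

    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
    config = ModelConfig(**cfg_dict)
    hier = load_hierarchy(io.BytesIO(bytes(data["hierarchy_npz"])))
    model = GCNBetaVAE(hier, config, seed=0)
    for k in model.params:
        model.params[k] = data[f"param_{k}"]
    return model
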