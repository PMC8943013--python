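"""Autoencoder variants for transform-invariant feature extraction.

Implements, in pure numpy with hand-written reverse-mode gradients:

* ``standard_vae``        — matched raw input/output pairs, ELBO loss
  (BCE reconstruction + KL to the unit Gaussian prior);
* ``output_corrected_vae``— randomly transformed input, canonical target;
* ``beta_vae``            — BCE + beta * KL;
* ``invariant_cvae``      — nuisance values injected into the decoder, with
  a marginal-posterior KL penalty (pairwise Gaussian KL within the batch);
* ``denoising_ae``        — reconstruction-only loss on transformed pairs;
* ``me_vae`` / ``me_dae`` — the multi-encoder architectures: one encoder per
  nuisance, each fed its own randomized transform of the canonical image;
  the per-encoder codes are fused by element-wise multiplication and a
  single decoder reconstructs the canonical target.  The ME-VAE KL term is
  the mean of the per-encoder KL divergences.

Encoder and decoder blocks are three fully-connected ReLU layers (plus the
Gaussian heads / the sigmoid output layer).  Losses follow the minimized
form BCE + (weight) * KL: BCE is summed over pixels and averaged over the
batch, KL summed over latent dimensions and averaged over the batch.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidInputError,
    ProvenanceError,
    TrainingDiverged,
)
from .synthetic import CellRecord
from .transforms import (
    PairedSample,
    canonicalize_record,
    nuisance_condition_matrix,
    random_transform,
)

VARIANTS = (
    "standard_vae",
    "output_corrected_vae",
    "beta_vae",
    "invariant_cvae",
    "denoising_ae",
    "me_vae",
    "me_dae",
)

_EPS = 1e-7
_LOGVAR_CLAMP = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Architecture configuration for one model variant."""

    variant: str = "me_vae"
    latent_dim: int = 64
    input_shape: tuple[int, int, int] = (32, 32, 1)
    corrections: tuple[str, ...] = ("rotation",)
    beta: float = 4.0
    lam: float = 1.0
    condition_dim: int = 0
    hidden: tuple[int, ...] = (256, 128, 64)
    kl_weight: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 64

    @property
    def n_encoders(self) -> int:
        return len(self.corrections) if self.variant in ("me_vae", "me_dae") else 1

    @property
    def input_dim(self) -> int:
        h, w, c = self.input_shape
        return h * w * c

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.latent_dim <= 0:
            raise ConfigurationError("latent_dim must be positive")
        if any(d <= 0 for d in self.input_shape):
            raise ConfigurationError("input_shape dims must be positive")
        if self.variant in ("me_vae", "me_dae") and self.n_encoders < 1:
            raise ConfigurationError("me_* variants need at least one correction/encoder")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if self.lam < 0:
            raise ConfigurationError("lambda must be non-negative")


# ---------------------------------------------------------------------------
# network components (dense blocks with manual gradients)
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))


class _MLP:
    """Fully-connected ReLU stack; final layer linear (activation applied by
    the owner).  Stores parameters and Adam state; forward caches for backward."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [_he_init(rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam = None

    def params(self):
        return self.W + self.b

    def forward(self, x: np.ndarray, relu_last: bool = False) -> np.ndarray:
        self._acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last or relu_last:
                h = np.maximum(h, 0.0)
            self._acts.append(h)
        self._relu_last = relu_last
        return h

    def backward(self, dout: np.ndarray):
        """Return (d_input, grads aligned with params())."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        last = len(self.W) - 1
        d = dout
        for i in range(last, -1, -1):
            if i < last or self._relu_last:
                d = d * (self._acts[i + 1] > 0)
            gW[i] = self._acts[i].T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return d, gW + gb

    def adam_step(self, grads, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self.params()
        if self._adam is None:
            self._adam = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
        for p, g, (m, v) in zip(params, grads, self._adam):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class Encoder:
    """Three dense ReLU layers followed by affine mu / logvar heads."""

    def __init__(self, input_dim: int, latent_dim: int, hidden: tuple[int, ...], rng: np.random.Generator):
        self.trunk = _MLP([input_dim, *hidden], rng)
        self.head_mu = _MLP([hidden[-1], latent_dim], rng)
        self.head_lv = _MLP([hidden[-1], latent_dim], rng)

    def forward(self, x: np.ndarray):
        h = self.trunk.forward(x, relu_last=True)
        mu = self.head_mu.forward(h)
        lv = self.head_lv.forward(h)
        self._lv_raw = lv
        lv = np.clip(lv, -_LOGVAR_CLAMP, _LOGVAR_CLAMP)
        return mu, lv

    def backward(self, dmu: np.ndarray, dlv: np.ndarray):
        dlv = dlv * (np.abs(self._lv_raw) < _LOGVAR_CLAMP)
        dh_mu, g_mu = self.head_mu.backward(dmu)
        dh_lv, g_lv = self.head_lv.backward(dlv)
        _, g_tr = self.trunk.backward(dh_mu + dh_lv)
        self._grads = (g_tr, g_mu, g_lv)

    def adam_step(self, lr: float, t: int):
        g_tr, g_mu, g_lv = self._grads
        self.trunk.adam_step(g_tr, lr, t)
        self.head_mu.adam_step(g_mu, lr, t)
        self.head_lv.adam_step(g_lv, lr, t)

    def state(self):
        return {"trunk_W": self.trunk.W, "trunk_b": self.trunk.b,
                "mu_W": self.head_mu.W, "mu_b": self.head_mu.b,
                "lv_W": self.head_lv.W, "lv_b": self.head_lv.b}


class Decoder:
    """Three dense ReLU layers plus a sigmoid output layer."""

    def __init__(self, latent_dim: int, output_dim: int, hidden: tuple[int, ...], rng: np.random.Generator):
        self.net = _MLP([latent_dim, *hidden[::-1], output_dim], rng)

    def forward(self, z: np.ndarray) -> np.ndarray:
        logits = self.net.forward(z)
        self._out = 1.0 / (1.0 + np.exp(-logits))
        return self._out

    def backward_from_logits(self, dlogits: np.ndarray):
        dz, grads = self.net.backward(dlogits)
        self._grads = grads
        return dz

    def adam_step(self, lr: float, t: int):
        self.net.adam_step(self._grads, lr, t)

    def state(self):
        return {"W": self.net.W, "b": self.net.b}


def build_encoder(input_shape: tuple[int, int, int], latent_dim: int,
                  hidden: tuple[int, ...] = (256, 128, 64), seed: int = 0) -> Encoder:
    """Construct a seeded encoder block for the given image shape."""
    if latent_dim <= 0 or any(d <= 0 for d in input_shape):
        raise ConfigurationError("invalid encoder shape")
    rng = np.random.default_rng(seed)
    return Encoder(int(np.prod(input_shape)), latent_dim, hidden, rng)


def build_decoder(latent_dim: int, output_shape: tuple[int, int, int],
                  hidden: tuple[int, ...] = (256, 128, 64), seed: int = 0) -> Decoder:
    """Construct a seeded decoder block producing sigmoid outputs."""
    if latent_dim <= 0 or any(d <= 0 for d in output_shape):
        raise ConfigurationError("invalid decoder shape")
    rng = np.random.default_rng(seed)
    return Decoder(latent_dim, int(np.prod(output_shape)), hidden, rng)


# ---------------------------------------------------------------------------
# loss functions (minimized form; usable on single samples or batches)
# ---------------------------------------------------------------------------

def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    return a.reshape(1, -1) if a.ndim == 1 else a.reshape(a.shape[0], -1) if a.ndim > 2 else a


def binary_cross_entropy(target: np.ndarray, reconstruction: np.ndarray) -> float:
    """BCE summed over pixels, averaged over the batch."""
    t, r = _as_batch(target), _as_batch(reconstruction)
    if t.shape != r.shape:
        raise InvalidInputError("target and reconstruction shapes differ")
    if np.any(r < 0.0) or np.any(r > 1.0):
        raise InvalidInputError("reconstruction outside [0, 1]")
    r = np.clip(r, _EPS, 1.0 - _EPS)
    per_sample = -(t * np.log(r) + (1.0 - t) * np.log(1.0 - r)).sum(axis=1)
    return float(per_sample.mean())


def kl_closed_form(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(mu, diag(sigma^2)) || N(0, I)) summed over dimensions.

    Batched inputs are averaged over the batch.
    """
    mu, lv = _as_batch(mu), _as_batch(logvar)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise InvalidInputError("non-finite KL inputs")
    # expm1 avoids cancellation in exp(lv) - 1 - lv near lv = 0, keeping the
    # divergence exactly non-negative
    per_sample = 0.5 * (mu**2 + (np.expm1(lv) - lv)).sum(axis=1)
    return float(per_sample.mean())


def fuse_latents(z_list: list[np.ndarray]) -> np.ndarray:
    """Element-wise product across encoders' latent codes."""
    if not z_list:
        raise InvalidInputError("empty latent list")
    out = np.asarray(z_list[0], float).copy()
    for z in z_list[1:]:
        z = np.asarray(z, float)
        if z.shape != out.shape:
            raise InvalidInputError("latent length mismatch")
        out = out * z
    return out


def loss_standard_vae(target, reconstruction, mu, logvar, kl_weight: float = 1.0) -> float:
    return binary_cross_entropy(target, reconstruction) + kl_weight * kl_closed_form(mu, logvar)


def loss_output_corrected(target_canonical, reconstruction, mu, logvar,
                          kl_weight: float = 1.0, provenance: dict | None = None) -> float:
    """Same arithmetic as the standard loss; the difference is the pairing
    (transformed input, canonical target), asserted via sample provenance."""
    if provenance is not None and not provenance.get("target_is_canonical", False):
        raise ProvenanceError("output-corrected loss requires a canonical target")
    return loss_standard_vae(target_canonical, reconstruction, mu, logvar, kl_weight)


def loss_me_vae(target_canonical, reconstruction, mu_list, logvar_list, kl_weight: float = 1.0) -> float:
    """BCE to the canonical target + mean of the per-encoder KL divergences."""
    n = len(mu_list)
    if n == 0 or len(logvar_list) != n:
        raise InvalidInputError("need matching, nonempty mu/logvar lists")
    kl = sum(kl_closed_form(m, lv) for m, lv in zip(mu_list, logvar_list)) / n
    return binary_cross_entropy(target_canonical, reconstruction) + kl_weight * kl


def loss_beta_vae(target, reconstruction, mu, logvar, beta: float) -> float:
    if beta <= 0:
        raise ConfigurationError("beta must be positive")
    return binary_cross_entropy(target, reconstruction) + beta * kl_closed_form(mu, logvar)


def gaussian_pairwise_kl(mu_i: np.ndarray, logvar_i: np.ndarray,
                         mus: np.ndarray, logvars: np.ndarray) -> np.ndarray:
    """Closed-form KL(N_i || N_j) against each row j of (mus, logvars)."""
    mu_i, lv_i = np.asarray(mu_i, float), np.asarray(logvar_i, float)
    d_mu = mu_i[None, :] - mus
    return 0.5 * (logvars - lv_i[None, :] + (np.exp(lv_i)[None, :] + d_mu**2) * np.exp(-logvars) - 1.0).sum(axis=1)


def loss_invariant_cvae(target, reconstruction, mu, logvar,
                        batch_mus, batch_logvars, lam: float = 1.0) -> float:
    """(1+lambda) * BCE + KL(q||prior) + lambda * marginal-KL approximation.

    The marginal term approximates KL(q(z|x) || q(z)) by the mean pairwise
    Gaussian KL between this sample's posterior and every other posterior
    in the batch.
    """
    batch_mus = np.atleast_2d(np.asarray(batch_mus, float))
    batch_lvs = np.atleast_2d(np.asarray(batch_logvars, float))
    if lam > 0 and batch_mus.shape[0] < 2:
        raise InvalidInputError("marginal term needs a batch of at least 2")
    bce = binary_cross_entropy(target, reconstruction)
    kl = kl_closed_form(mu, logvar)
    marginal = 0.0
    if lam > 0:
        pair = gaussian_pairwise_kl(np.asarray(mu).ravel(), np.asarray(logvar).ravel(), batch_mus, batch_lvs)
        is_self = np.all(np.isclose(batch_mus, np.asarray(mu).ravel()[None, :]), axis=1) & np.all(
            np.isclose(batch_lvs, np.asarray(logvar).ravel()[None, :]), axis=1
        )
        others = pair[~is_self]
        marginal = float(others.mean()) if others.size else 0.0
    return (1.0 + lam) * bce + kl + lam * marginal


def loss_denoising_ae(target_canonical, reconstruction) -> float:
    """Reconstruction-only loss (no latent regularization)."""
    return binary_cross_entropy(target_canonical, reconstruction)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    spec: ModelSpec
    encoders: list[Encoder]
    decoder: Decoder
    history: list[dict]
    seed: int
    radius: int | None = None


def _prepare_arrays(spec: ModelSpec, dataset: list[PairedSample]):
    D = spec.input_dim
    n_enc = spec.n_encoders
    for s in dataset:
        if len(s.inputs) < n_enc:
            raise ConfigurationError("dataset inputs-per-sample does not match encoder count")
    X = [np.stack([s.inputs[i].reshape(-1) for s in dataset]) for i in range(n_enc)]
    Y = np.stack([s.target.reshape(-1) for s in dataset])
    if Y.shape[1] != D:
        raise ConfigurationError(f"images of dim {Y.shape[1]} do not match input_shape {spec.input_shape}")
    C = None
    if spec.variant == "invariant_cvae":
        C = np.stack([s.condition for s in dataset])
        if C.shape[1] != spec.condition_dim:
            raise ConfigurationError("condition vectors do not match condition_dim")
    return X, Y, C


def _marginal_kl_and_grads(mu: np.ndarray, lv: np.ndarray):
    """Batch marginal term: mean_i mean_{j!=i} KL(N_i || N_j), with gradients
    with respect to mu and logvar (both roles accumulated)."""
    B, d = mu.shape
    var = np.exp(lv)
    inv_var = np.exp(-lv)
    dmu = mu[:, None, :] - mu[None, :, :]  # (i, j, d)
    ratio = var[:, None, :] * inv_var[None, :, :]
    kl_ij = 0.5 * (lv[None, :, :] - lv[:, None, :] + ratio + dmu**2 * inv_var[None, :, :] - 1.0).sum(-1)
    off = ~np.eye(B, dtype=bool)
    scale = 1.0 / (B * (B - 1))
    value = float(kl_ij[off].sum() * scale)
    w = off.astype(float) * scale
    # d KL(i||j)/d mu_i = (mu_i-mu_j)/var_j ; d/d mu_j is its negation
    weighted = w[:, :, None] * dmu * inv_var[None, :, :]
    g_mu = weighted.sum(axis=1) - weighted.sum(axis=0)
    # d KL(i||j)/d lv_i = (ratio-1)/2 ; d/d lv_j = (1 - ratio - dmu^2/var_j)/2
    g_lv = 0.5 * (w[:, :, None] * (ratio - 1.0)).sum(axis=1)
    g_lv += 0.5 * (w[:, :, None] * (1.0 - ratio - dmu**2 * inv_var[None, :, :])).sum(axis=0)
    return value, g_mu, g_lv


def train(spec: ModelSpec, dataset: list[PairedSample], epochs: int = 10, seed: int = 0) -> TrainedModel:
    """Train a variant on self-supervision pairs with Adam.

    Per-epoch mean reconstruction / KL / total losses are recorded in the
    history; a non-finite loss aborts with the offending term named.
    epochs=0 returns the freshly initialized model with empty history.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_enc = spec.n_encoders
    enc_in = spec.input_dim
    dec_in = spec.latent_dim + (spec.condition_dim if spec.variant == "invariant_cvae" else 0)
    encoders = [Encoder(enc_in, spec.latent_dim, spec.hidden, rng) for _ in range(n_enc)]
    decoder = Decoder(dec_in, enc_in, spec.hidden, rng)
    X, Y, C = _prepare_arrays(spec, dataset)
    N = Y.shape[0]
    variational = spec.variant not in ("denoising_ae", "me_dae")
    kl_scale = {"beta_vae": spec.beta}.get(spec.variant, spec.kl_weight)
    history: list[dict] = []
    t_step = 0
    for _epoch in range(epochs):
        order = rng.permutation(N)
        ep_recon, ep_kl, n_batches = 0.0, 0.0, 0
        for start in range(0, N, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            B = len(idx)
            target = Y[idx]
            mus, lvs, zs, eps_list = [], [], [], []
            for enc, Xi in zip(encoders, X):
                mu, lv = enc.forward(Xi[idx])
                if variational:
                    eps = rng.standard_normal(mu.shape)
                    z = mu + np.exp(0.5 * lv) * eps
                else:
                    eps, z = None, mu
                mus.append(mu)
                lvs.append(lv)
                zs.append(z)
                eps_list.append(eps)
            z_all = zs[0].copy()
            for z in zs[1:]:
                z_all *= z
            dec_in_vec = np.concatenate([z_all, C[idx]], axis=1) if C is not None else z_all
            recon = decoder.forward(dec_in_vec)
            recon_c = np.clip(recon, _EPS, 1.0 - _EPS)
            recon_loss = float(-(target * np.log(recon_c) + (1 - target) * np.log(1 - recon_c)).sum(1).mean())
            kl_terms = [0.5 * (m**2 + np.exp(l) - 1 - l).sum(1).mean() for m, l in zip(mus, lvs)]
            kl_loss = float(np.mean(kl_terms)) if variational else 0.0
            bce_w = (1.0 + spec.lam) if spec.variant == "invariant_cvae" else 1.0
            if not np.isfinite(recon_loss):
                raise TrainingDiverged("reconstruction loss became non-finite")
            if not np.isfinite(kl_loss):
                raise TrainingDiverged("KL loss became non-finite")
            # ---- backward ----
            dlogits = bce_w * (recon - target) / B
            dz_all = decoder.backward_from_logits(dlogits)
            if C is not None:
                dz_all = dz_all[:, : spec.latent_dim]
            marg_val, marg_gmu, marg_glv = (0.0, None, None)
            if spec.variant == "invariant_cvae" and spec.lam > 0:
                if B < 2:
                    raise InvalidInputError("invariant_cvae needs batch size >= 2")
                marg_val, marg_gmu, marg_glv = _marginal_kl_and_grads(mus[0], lvs[0])
            for i, enc in enumerate(encoders):
                prod_others = np.ones_like(dz_all)
                for j, z in enumerate(zs):
                    if j != i:
                        prod_others *= z
                dz_i = dz_all * prod_others
                if variational:
                    dmu = dz_i + kl_scale / (len(encoders) * B) * mus[i]
                    dlv = dz_i * 0.5 * np.exp(0.5 * lvs[i]) * eps_list[i] + kl_scale / (len(encoders) * B) * 0.5 * (
                        np.exp(lvs[i]) - 1.0
                    )
                    if marg_gmu is not None:
                        dmu = dmu + spec.lam * marg_gmu
                        dlv = dlv + spec.lam * marg_glv
                else:
                    dmu, dlv = dz_i, np.zeros_like(lvs[i])
                enc.backward(dmu, dlv)
            t_step += 1
            for enc in encoders:
                enc.adam_step(spec.learning_rate, t_step)
            decoder.adam_step(spec.learning_rate, t_step)
            ep_recon += recon_loss
            ep_kl += kl_loss
            n_batches += 1
        history.append(
            {
                "reconstruction": ep_recon / n_batches,
                "kl": ep_kl / n_batches,
                "total": ep_recon / n_batches + kl_scale * ep_kl / n_batches,
            }
        )
    return TrainedModel(spec=spec, encoders=encoders, decoder=decoder, history=history, seed=seed)


# ---------------------------------------------------------------------------
# deterministic encoding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """Cells x latent-dimensions matrix with identities and labels attached."""

    values: np.ndarray
    cell_ids: list[str]
    labels: list[str] | None = None
    nuisance: dict | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("embedding contains non-finite values")
        if len(self.cell_ids) != self.values.shape[0]:
            raise InvalidInputError("cell_ids do not align with rows")


def _cell_seed(cell_id: str, k: int) -> int:
    return (zlib.crc32(cell_id.encode()) + 7919 * k) % (2**31)


def encode(model: TrainedModel, records: list[CellRecord], radius: int | None = None) -> EmbeddingMatrix:
    """Deterministic embeddings: posterior means; for the multi-encoder
    variants, the element-wise product of per-encoder means, each encoder
    fed a cell-id-seeded random transform of the canonical image."""
    spec = model.spec
    corrected = spec.variant in ("output_corrected_vae", "denoising_ae", "me_vae", "me_dae")
    rows = []
    for rec in records:
        if corrected:
            canon = canonicalize_record(rec, spec.corrections, radius=radius)
            xs = []
            for k, kind in enumerate(spec.corrections[: spec.n_encoders]):
                img, _, _ = random_transform(canon.image, canon.mask, kind, _cell_seed(rec.cell_id, k))
                xs.append(img.reshape(-1))
            if spec.variant in ("output_corrected_vae", "denoising_ae"):
                xs = xs[:1]
        else:
            xs = [rec.image.reshape(-1)]
        mus = [enc.forward(x[None, :])[0][0] for enc, x in zip(model.encoders, xs)]
        rows.append(fuse_latents(mus) if len(mus) > 1 else mus[0])
    nuisance = None
    if all(r.truth is not None for r in records):
        nuisance = {
            "rotation_deg": np.array([r.truth.rotation_deg for r in records]),
            "polarity_deg": np.array([r.truth.polarity_deg for r in records]),
            "area_px": np.array([r.truth.area_px for r in records], float),
        }
    return EmbeddingMatrix(
        values=np.stack(rows),
        cell_ids=[r.cell_id for r in records],
        labels=[r.label for r in records],
        nuisance=nuisance,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str) -> None:
    """Weights as .npz plus a JSON sidecar with the spec and history."""
    arrays = {}
    for i, enc in enumerate(model.encoders):
        for key, mats in enc.state().items():
            for j, m in enumerate(mats):
                arrays[f"enc{i}_{key}_{j}"] = m
    for key, mats in model.decoder.state().items():
        for j, m in enumerate(mats):
            arrays[f"dec_{key}_{j}"] = m
    np.savez(path, **arrays)
    sidecar = {
        "spec": {**model.spec.__dict__, "input_shape": list(model.spec.input_shape),
                 "corrections": list(model.spec.corrections), "hidden": list(model.spec.hidden)},
        "history": model.history,
        "seed": model.seed,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path: str) -> TrainedModel:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    sd = sidecar["spec"]
    spec = ModelSpec(**{**sd, "input_shape": tuple(sd["input_shape"]),
                        "corrections": tuple(sd["corrections"]), "hidden": tuple(sd["hidden"])})
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    rng = np.random.default_rng(0)
    encoders = [Encoder(spec.input_dim, spec.latent_dim, spec.hidden, rng) for _ in range(spec.n_encoders)]
    dec_in = spec.latent_dim + (spec.condition_dim if spec.variant == "invariant_cvae" else 0)
    decoder = Decoder(dec_in, spec.input_dim, spec.hidden, rng)
    for i, enc in enumerate(encoders):
        for key, mats in enc.state().items():
            for j in range(len(mats)):
                mats[j][...] = data[f"enc{i}_{key}_{j}"]
    for key, mats in decoder.state().items():
        for j in range(len(mats)):
            mats[j][...] = data[f"dec_{key}_{j}"]
    return TrainedModel(spec=spec, encoders=encoders, decoder=decoder,
                        history=sidecar["history"], seed=sidecar["seed"])
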