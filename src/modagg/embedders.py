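"""Per-modality embedding generation into a shared dimensionality.

Each modality gets its own, independently trained encoder — a variational
autoencoder for RNA, mutation and image-tile data, and a fixed
deterministic nonlinear map standing in for a pretrained sentence encoder
for clinical annotations.  The only coordination between modalities is the
shared output dimensionality (default 768); the latent geometries are
otherwise unaligned by construction.

The VAE loss is reconstruction (summed squared error per sample) plus a
KL term whose weight beta ramps linearly from ``kl_beta_init`` to 1 over
``kl_kappa`` epochs (KL warm-up); with kappa = 1 and beta starting at 0
the warm-up lasts exactly one epoch.  Training uses Adam, mini-batches,
and early stopping on a held-out validation split with best-weight
restoration.  Encoding always returns the latent *mean*, so the encoder
is a pure function after training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from . import _nn
from ._nn import Adam, Dense, EarlyStopper, ReLU, Sequential, TrainingError
from .cohort import Cohort, MODALITIES

__all__ = [
    "VaeConfig",
    "Vae",
    "beta_schedule",
    "train_vae",
    "train_vae_two_phase",
    "encode",
    "tile_image",
    "filter_background",
    "truncate_embedding",
    "AnnotationEmbedder",
    "EmbeddingPool",
    "build_pool",
]

_F = np.float32


def beta_schedule(epoch: int, kappa: float, beta_init: float = 0.0) -> float:
    """KL weight at integer epoch t: linear ramp from beta_init to 1 over kappa epochs."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return float(min(1.0, beta_init + (1.0 - beta_init) * epoch / kappa))


@dataclass(frozen=True)
class VaeConfig:
    input_dim: int = 0  # inferred from data when 0
    latent_dim: int = 768
    hidden_sizes: tuple[int, ...] = (1024, 1024)
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 10
    kl_kappa: float = 1.0
    kl_beta_init: float = 0.0
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    # "gaussian" (squared error) for continuous data; "bernoulli" (logit
    # decoder + cross-entropy) for binary matrices such as one-hot mutations
    likelihood: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.kl_beta_init < 0:
            raise ValueError("kl_beta_init must be >= 0")
        if self.kl_kappa <= 0:
            raise ValueError("kl_kappa must be > 0")
        if self.likelihood not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


class Vae:
    """Gaussian-latent VAE with diagonal posterior and linear decoder output."""

    def __init__(self, config: VaeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (config.input_dim, *config.hidden_sizes)
        enc = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            enc += [Dense(a, b, rng), ReLU()]
        self.enc_body = Sequential(*enc)
        self.mu_head = Dense(sizes[-1], config.latent_dim, rng)
        self.logvar_head = Dense(sizes[-1], config.latent_dim, rng)
        dec_sizes = (config.latent_dim, *reversed(config.hidden_sizes))
        dec = []
        for a, b in zip(dec_sizes[:-1], dec_sizes[1:]):
            dec += [Dense(a, b, rng), ReLU()]
        dec.append(Dense(dec_sizes[-1], config.input_dim, rng))
        self.decoder = Sequential(*dec)
        self.history: list[dict] = []

    def _params(self):
        return (
            self.enc_body.params()
            + self.mu_head.params()
            + self.logvar_head.params()
            + self.decoder.params()
        )

    def _grads(self):
        return (
            self.enc_body.grads()
            + self.mu_head.grads()
            + self.logvar_head.grads()
            + self.decoder.grads()
        )

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent means (deterministic inference)."""
        X = np.asarray(X, dtype=_F)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (n, {self.config.input_dim}) input, got {X.shape}"
            )
        h = self.enc_body.forward(X, train=False)
        return self.mu_head.forward(h, train=False)

    def _loss_terms(self, X, rng, train, beta, opt=None):
        h = self.enc_body.forward(X, train)
        mu = self.mu_head.forward(h, train)
        logvar = np.clip(self.logvar_head.forward(h, train), -10.0, 10.0)
        n = X.shape[0]
        if train:
            eps = rng.standard_normal(mu.shape).astype(_F)
        else:
            eps = np.zeros_like(mu)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        xhat = self.decoder.forward(z, train)
        if self.config.likelihood == "bernoulli":
            p = 1.0 / (1.0 + np.exp(-np.clip(xhat, -30, 30)))
            recon = float(
                -(X * np.log(np.clip(p, 1e-12, None))
                  + (1 - X) * np.log(np.clip(1 - p, 1e-12, None))).sum() / n
            )
            d_xhat = (p - X) / n
        else:
            recon = float(((xhat - X) ** 2).sum() / n)
            d_xhat = (2.0 / n) * (xhat - X)
        kl = float(0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum() / n)
        loss = recon + beta * kl
        if opt is not None:
            dz = self.decoder.backward(d_xhat.astype(_F))
            dmu = dz + beta * mu / n
            dlogvar = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0) / n
            dh = self.mu_head.backward(dmu.astype(_F)) + self.logvar_head.backward(
                dlogvar.astype(_F)
            )
            self.enc_body.backward(dh)
            opt.step()
        return loss, recon, kl


def train_vae(
    X: np.ndarray, config: VaeConfig, model: Vae | None = None
) -> Vae:
    """Fit a VAE; returns the trained model with per-epoch history attached."""
    X = np.asarray(X, dtype=_F)
    if not np.isfinite(X).all():
        raise ValueError("training data must be finite")
    if config.input_dim == 0:
        config = replace(config, input_dim=X.shape[1])
    if X.shape[0] < config.batch_size:
        warnings.warn(
            "fewer rows than batch_size; training full-batch", stacklevel=2
        )
    vae = model if model is not None else Vae(config)
    rng = np.random.default_rng(config.seed + 1)
    n_val = max(1, int(round(config.val_fraction * X.shape[0])))
    order = rng.permutation(X.shape[0])
    X_val, X_train = X[order[:n_val]], X[order[n_val:]]

    opt = Adam(vae._params(), vae._grads(), lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    best = _nn.snapshot(vae._params())
    for epoch in range(config.max_epochs):
        beta = beta_schedule(epoch, config.kl_kappa, config.kl_beta_init)
        losses = []
        for idx in _nn.iterate_minibatches(X_train.shape[0], config.batch_size, rng):
            loss, _, _ = vae._loss_terms(X_train[idx], rng, True, beta, opt)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch
                )
            losses.append(loss)
        val_loss, val_recon, val_kl = vae._loss_terms(X_val, rng, False, beta)
        vae.history.append(
            {
                "epoch": epoch,
                "beta": beta,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_recon": val_recon,
                "val_kl": val_kl,
            }
        )
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best = _nn.snapshot(vae._params())
        if stop:
            break
    _nn.restore(vae._params(), best)
    return vae


def train_vae_two_phase(
    X: np.ndarray, config: VaeConfig, finetune_lr_scale: float = 0.1
) -> Vae:
    """Pretraining pass followed by a fine-tuning pass at a reduced learning
    rate, as used for the RNA modality."""
    vae = train_vae(X, config)
    ft = replace(
        vae.config,
        learning_rate=config.learning_rate * finetune_lr_scale,
        kl_beta_init=1.0,  # warm-up already done in phase one
        seed=config.seed + 1,
    )
    return train_vae(X, ft, model=_rewrap(vae, ft))


def _rewrap(vae: Vae, config: VaeConfig) -> Vae:
    vae.config = config
    return vae


def encode(vae: Vae, records: np.ndarray) -> np.ndarray:
    """One latent-mean embedding per record."""
    return vae.encode(records)


def tile_image(image: np.ndarray, tile_size: int = 256) -> list[np.ndarray]:
    """Partition an H x W (x C) image into non-overlapping square tiles.

    Border remainders smaller than a tile are dropped.  Tiles are returned
    row-major (top-left first).
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2-D or 3-D (H, W[, C])")
    H, W = img.shape[:2]
    if H < tile_size or W < tile_size:
        warnings.warn("image smaller than one tile; returning no tiles", stacklevel=2)
        return []
    return [
        img[r * tile_size : (r + 1) * tile_size, c * tile_size : (c + 1) * tile_size]
        for r in range(H // tile_size)
        for c in range(W // tile_size)
    ]


def filter_background(
    tiles: list[np.ndarray],
    rgb_threshold: float = 220.0,
    background_fraction: float = 0.8,
) -> list[np.ndarray]:
    """Drop tiles that are predominantly background.

    A pixel counts as background when *all* its channels exceed
    rgb_threshold; a tile is removed when the background-pixel fraction
    exceeds background_fraction.  Input order is preserved.
    """
    kept = []
    for tile in tiles:
        t = np.asarray(tile)
        if t.ndim != 3:
            raise ValueError("tiles must be RGB (H, W, C)")
        frac = (t > rgb_threshold).all(axis=-1).mean()
        if frac <= background_fraction:
            kept.append(tile)
    return kept


def truncate_embedding(vector: np.ndarray) -> np.ndarray:
    """Keep the latter half of an embedding (e.g. 1536 -> final 768 dims)."""
    v = np.asarray(vector)
    if v.ndim == 1:
        v = v[None, :]
        squeeze = True
    else:
        squeeze = False
    if v.shape[-1] % 2 != 0:
        raise ValueError("embedding length must be even to truncate by half")
    out = v[..., v.shape[-1] // 2 :]
    return out[0] if squeeze else out


class AnnotationEmbedder:
    """Deterministic fixed nonlinear map emulating a pretrained sentence
    encoder: each input latent maps to a fixed point in a 768-d semantic
    space, with no probabilistic structure and no relation to any VAE map."""

    def __init__(self, latent_dim: int, embed_dim: int = 768, seed: int = 7_654_321):
        rng = np.random.default_rng(seed)
        hidden = 256
        self.W1 = rng.standard_normal((latent_dim, hidden)) / np.sqrt(latent_dim)
        self.b1 = rng.standard_normal(hidden) * 0.1
        self.W2 = rng.standard_normal((hidden, embed_dim)) / np.sqrt(hidden)
        self.b2 = rng.standard_normal(embed_dim) * 0.1

    def embed(self, latents: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        h = np.tanh(z @ self.W1 + self.b1)
        return (h @ self.W2 + self.b2).astype(_F)


@dataclass
class EmbeddingPool:
    """All modality embeddings of a cohort in one table."""

    vectors: np.ndarray  # (N, embed_dim) float32
    modality: np.ndarray  # (N,) str
    patient_id: np.ndarray  # (N,) str
    cancer_type: np.ndarray  # (N,) str

    def __post_init__(self):
        n = self.vectors.shape[0]
        if not (len(self.modality) == len(self.patient_id) == len(self.cancer_type) == n):
            raise ValueError("pool column lengths disagree")

    @property
    def embed_dim(self) -> int:
        return self.vectors.shape[1]

    def subset(self, mask: np.ndarray) -> "EmbeddingPool":
        return EmbeddingPool(
            self.vectors[mask],
            self.modality[mask],
            self.patient_id[mask],
            self.cancer_type[mask],
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=self.vectors)
            s = h5py.string_dtype()
            f.create_dataset("modality", data=self.modality.astype(object), dtype=s)
            f.create_dataset("patient_id", data=self.patient_id.astype(object), dtype=s)
            f.create_dataset("cancer_type", data=self.cancer_type.astype(object), dtype=s)

    @classmethod
    def from_hdf5(cls, path) -> "EmbeddingPool":
        with h5py.File(path, "r") as f:
            return cls(
                f["vectors"][...],
                f["modality"].asstr()[...],
                f["patient_id"].asstr()[...],
                f["cancer_type"].asstr()[...],
            )

    def labels_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "modality": self.modality,
                "patient_id": self.patient_id,
                "cancer_type": self.cancer_type,
            }
        ).to_csv(path, index=False)


def build_pool(
    cohort: Cohort,
    rna_config: VaeConfig | None = None,
    mutation_config: VaeConfig | None = None,
    image_config: VaeConfig | None = None,
    annotation_seed: int = 7_654_321,
    max_image_train_rows: int = 3000,
    seed: int = 0,
) -> EmbeddingPool:
    """Train all modality embedders on a cohort and emit the joint pool.

    RNA uses the two-phase (pretrain + fine-tune) VAE schedule; mutation a
    single-phase VAE; image tiles a VAE with a double-width latent whose
    output is truncated to its latter half (the tile-embedder path); and
    annotations the deterministic semantic-map stub.  The image VAE is
    fitted on a seeded subsample of at most max_image_train_rows tiles and
    then encodes every tile.
    """
    D = cohort.config.embed_dim
    rng = np.random.default_rng(seed)
    pid = cohort.patients["patient_id"].to_numpy()
    ctype = cohort.patients["cancer_type"].to_numpy()

    if rna_config is None:
        rna_config = VaeConfig(latent_dim=D, seed=seed + 11)
    # binary one-hot input: Bernoulli likelihood; the higher learning rate
    # compensates for the few gradient updates per epoch at cohort-scale n
    if mutation_config is None:
        mutation_config = VaeConfig(
            latent_dim=D, likelihood="bernoulli", learning_rate=1e-2, seed=seed + 12
        )
    if image_config is None:
        image_config = VaeConfig(latent_dim=2 * D, hidden_sizes=(512, 512), seed=seed + 13)
    if rna_config.latent_dim != D or mutation_config.latent_dim != D:
        raise ValueError(f"RNA/mutation VAE latent_dim must equal embed_dim {D}")
    if image_config.latent_dim != 2 * D:
        raise ValueError(
            f"image VAE latent_dim must be 2 x embed_dim (= {2 * D}) for truncation"
        )

    vecs, mods, pids, cts = [], [], [], []

    rna_vae = train_vae_two_phase(cohort.rna_matrix, rna_config)
    vecs.append(encode(rna_vae, cohort.rna_matrix))
    mods += ["rna"] * cohort.n_patients
    pids.append(pid)
    cts.append(ctype)

    mut_vae = train_vae(cohort.mutation_matrix.astype(_F), mutation_config)
    vecs.append(encode(mut_vae, cohort.mutation_matrix.astype(_F)))
    mods += ["mutation"] * cohort.n_patients
    pids.append(pid)
    cts.append(ctype)

    tile_feats = np.concatenate(cohort.image_features, axis=0)
    tile_owner = np.repeat(
        np.arange(cohort.n_patients), [f.shape[0] for f in cohort.image_features]
    )
    if tile_feats.shape[0] > max_image_train_rows:
        train_rows = rng.choice(tile_feats.shape[0], max_image_train_rows, replace=False)
    else:
        train_rows = np.arange(tile_feats.shape[0])
    img_vae = train_vae(tile_feats[train_rows], image_config)
    img_emb = truncate_embedding(encode(img_vae, tile_feats))
    vecs.append(img_emb)
    mods += ["image"] * tile_feats.shape[0]
    pids.append(pid[tile_owner])
    cts.append(ctype[tile_owner])

    ann = AnnotationEmbedder(cohort.config.latent_dim, D, seed=annotation_seed)
    ann_latents = np.concatenate(cohort.annotation_latents, axis=0)
    ann_owner = np.repeat(
        np.arange(cohort.n_patients), [a.shape[0] for a in cohort.annotation_latents]
    )
    vecs.append(ann.embed(ann_latents))
    mods += ["annotation"] * ann_latents.shape[0]
    pids.append(pid[ann_owner])
    cts.append(ctype[ann_owner])

    return EmbeddingPool(
        vectors=np.concatenate(vecs, axis=0).astype(_F),
        modality=np.array(mods, dtype=object),
        patient_id=np.concatenate(pids).astype(object),
        cancer_type=np.concatenate(cts).astype(object),
    )
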