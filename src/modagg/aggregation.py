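"""Sampling strategies that build summed aggregate embeddings.

Three strategies:

* modality-level — constituents drawn across the whole pool regardless of
  patient or cancer type (composition-recognition task);
* cancer-specific — all constituents of one aggregate share a cancer type;
* patient-level — constituents drawn from a single patient's embeddings,
  with R independent summed rounds concatenated into one patient vector.

Constituents are drawn *with replacement* (a modality may contribute more
than once); composition targets record presence/absence only.  The noise
perturbation replaces whole constituents with Gaussian noise vectors while
preserving the total constituent count of each aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .cohort import MODALITIES
from .embedders import EmbeddingPool

__all__ = [
    "AggregateSample",
    "PatientAggregate",
    "RecognitionDataset",
    "sample_modality_level",
    "sample_specific_cancer",
    "sample_patient_level",
    "build_dataset",
    "build_composite",
    "build_patient_dataset",
    "perturb_with_noise",
    "perturb_dataset",
]

_F = np.float32


@dataclass
class AggregateSample:
    """One summed embedding plus its tracked composition."""

    vector: np.ndarray  # (embed_dim,)
    composition: tuple[str, ...]  # surviving constituent modalities (multiset)
    constituent_vectors: np.ndarray  # (sample_count, embed_dim), incl. noise rows
    cancer_type: str | None = None
    noise_count: int = 0

    @property
    def sample_count(self) -> int:
        return len(self.composition) + self.noise_count


@dataclass
class PatientAggregate:
    """R concatenated summed rounds for one patient (length R x embed_dim)."""

    vector: np.ndarray
    patient_id: str
    cancer_type: str
    subtype: str | None = None
    tmb_class: int | None = None


@dataclass
class RecognitionDataset:
    """Aggregate vectors with multi-label composition targets.

    constituent_modalities / constituent_indices hold, per row, the drawn
    modality ids and the global pool row of each constituent — retained so
    noise perturbation can be applied after the fact.  A composite dataset
    (mixed sample counts) stores them as ragged blocks.
    """

    X: np.ndarray  # (N, embed_dim) float32
    Y: np.ndarray  # (N, n_modalities) int8 presence matrix
    modalities: tuple[str, ...]
    sample_count: int | str  # fixed count, or "mixed" for composites
    cancer_labels: np.ndarray | None = None  # (N,) under cancer-specific sampling
    constituent_modalities: np.ndarray | None = None  # (N, sc) int8
    constituent_indices: np.ndarray | None = None  # (N, sc) int64
    noise_counts: np.ndarray | None = None  # (N,) after perturbation

    def __post_init__(self):
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts disagree")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("Y", data=self.Y)
            f.attrs["modalities"] = list(self.modalities)
            f.attrs["sample_count"] = str(self.sample_count)
            if self.cancer_labels is not None:
                f.create_dataset(
                    "cancer_labels",
                    data=self.cancer_labels.astype(object),
                    dtype=h5py.string_dtype(),
                )

    def labels_to_csv(self, path) -> None:
        df = pd.DataFrame(self.Y, columns=list(self.modalities))
        if self.cancer_labels is not None:
            df["cancer_type"] = self.cancer_labels
        df.to_csv(path, index=False)


def _modality_indices(pool: EmbeddingPool, modalities) -> list[np.ndarray]:
    return [np.flatnonzero(pool.modality == m) for m in modalities]


def _check_probs(modality_probs, n_mod: int) -> np.ndarray:
    if modality_probs is None:
        return np.full(n_mod, 1.0 / n_mod)
    p = np.asarray(modality_probs, dtype=float)
    if p.shape != (n_mod,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("modality_probs must be a distribution over modalities")
    return p


def _draw(
    pool: EmbeddingPool,
    sample_count: int,
    modality_probs,
    rng: np.random.Generator,
    modalities: tuple[str, ...],
    restrict: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (modality ids, global pool indices) for one aggregate."""
    if sample_count < 1:
        raise ValueError("sample_count must be >= 1")
    probs = _check_probs(modality_probs, len(modalities))
    groups = []
    for m in modalities:
        idx = np.flatnonzero(pool.modality == m)
        if restrict is not None:
            idx = idx[np.isin(idx, restrict)]
        groups.append(idx)
    for m, g, p in zip(modalities, groups, probs):
        if p > 0 and len(g) == 0:
            raise ValueError(f"no embeddings available for modality {m!r}")
    mod_ids = rng.choice(len(modalities), size=sample_count, p=probs)
    gidx = np.array([rng.choice(groups[m]) for m in mod_ids])
    return mod_ids, gidx


def sample_modality_level(
    pool: EmbeddingPool,
    sample_count: int,
    modality_probs=None,
    rng: np.random.Generator | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> AggregateSample:
    """One aggregate drawn across the whole pool, patient/type agnostic."""
    rng = rng if rng is not None else np.random.default_rng()
    mod_ids, gidx = _draw(pool, sample_count, modality_probs, rng, modalities)
    constituents = pool.vectors[gidx]
    return AggregateSample(
        vector=constituents.sum(axis=0),
        composition=tuple(modalities[m] for m in mod_ids),
        constituent_vectors=constituents,
    )


def sample_specific_cancer(
    pool: EmbeddingPool,
    sample_count: int,
    cancer_type: str,
    modality_probs=None,
    rng: np.random.Generator | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> AggregateSample:
    """One aggregate whose constituents all carry the given cancer type."""
    rng = rng if rng is not None else np.random.default_rng()
    restrict = np.flatnonzero(pool.cancer_type == cancer_type)
    if restrict.size == 0:
        raise ValueError(f"no embeddings of cancer type {cancer_type!r} in pool")
    mod_ids, gidx = _draw(pool, sample_count, modality_probs, rng, modalities, restrict)
    constituents = pool.vectors[gidx]
    return AggregateSample(
        vector=constituents.sum(axis=0),
        composition=tuple(modalities[m] for m in mod_ids),
        constituent_vectors=constituents,
        cancer_type=cancer_type,
    )


def sample_patient_level(
    patient_pool: EmbeddingPool,
    sample_count: int,
    repeats: int,
    rng: np.random.Generator | None = None,
) -> PatientAggregate:
    """R rounds of (draw sample_count embeddings from one patient, sum),
    concatenated in round order -> vector of length repeats x embed_dim."""
    rng = rng if rng is not None else np.random.default_rng()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    n = patient_pool.vectors.shape[0]
    if n == 0:
        raise ValueError("patient pool is empty")
    pids = np.unique(patient_pool.patient_id)
    if len(pids) != 1:
        raise ValueError("patient_pool must contain exactly one patient")
    rounds = []
    for _ in range(repeats):
        idx = rng.integers(0, n, size=sample_count)
        rounds.append(patient_pool.vectors[idx].sum(axis=0))
    return PatientAggregate(
        vector=np.concatenate(rounds).astype(_F),
        patient_id=str(pids[0]),
        cancer_type=str(patient_pool.cancer_type[0]),
    )


def build_dataset(
    pool: EmbeddingPool,
    sample_count: int,
    n: int = 15000,
    strategy: str = "modality_level",
    modality_probs=None,
    rng: np.random.Generator | int | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> RecognitionDataset:
    """Build n aggregates at a fixed sample count (vectorised).

    Each constituent is drawn by first picking a modality (uniformly by
    default) and then a uniform embedding of that modality — under the
    cancer-specific strategy, a uniform embedding of that modality *and*
    the row's cancer type (itself drawn uniformly per row).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sample_count < 1:
        raise ValueError("sample_count must be >= 1")
    if strategy not in ("modality_level", "specific_cancer"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = _check_probs(modality_probs, len(modalities))

    mod_ids = rng.choice(len(modalities), size=(n, sample_count), p=probs).astype(np.int8)
    gidx = np.empty((n, sample_count), dtype=np.int64)
    cancer_labels = None

    if strategy == "modality_level":
        groups = _modality_indices(pool, modalities)
        for m, g in enumerate(groups):
            if probs[m] > 0 and len(g) == 0:
                raise ValueError(f"no embeddings available for modality {modalities[m]!r}")
        for m, g in enumerate(groups):
            mask = mod_ids == m
            if mask.any():
                gidx[mask] = g[rng.integers(0, len(g), size=int(mask.sum()))]
    else:
        types = np.unique(pool.cancer_type)
        cancer_labels = types[rng.integers(0, len(types), size=n)]
        for ct in types:
            row_mask = cancer_labels == ct
            in_type = pool.cancer_type == ct
            for m, modality in enumerate(modalities):
                g = np.flatnonzero(in_type & (pool.modality == modality))
                if probs[m] > 0 and len(g) == 0:
                    raise ValueError(
                        f"no {modality!r} embeddings for cancer type {ct!r}"
                    )
                mask = row_mask[:, None] & (mod_ids == m)
                if mask.any():
                    gidx[mask] = g[rng.integers(0, len(g), size=int(mask.sum()))]

    # sum column-by-column to avoid materialising an (n, sc, D) block
    X = np.zeros((n, pool.vectors.shape[1]), dtype=_F)
    for j in range(sample_count):
        X += pool.vectors[gidx[:, j]]
    Y = np.zeros((n, len(modalities)), dtype=np.int8)
    for m in range(len(modalities)):
        Y[:, m] = (mod_ids == m).any(axis=1)
    return RecognitionDataset(
        X=X,
        Y=Y,
        modalities=modalities,
        sample_count=sample_count,
        cancer_labels=cancer_labels,
        constituent_modalities=mod_ids,
        constituent_indices=gidx,
    )


def build_composite(datasets: list[RecognitionDataset]) -> RecognitionDataset:
    """Row-wise concatenation of isolation datasets into a mixed-count one."""
    if not datasets:
        raise ValueError("need at least one dataset")
    D = datasets[0].X.shape[1]
    mods = datasets[0].modalities
    for d in datasets[1:]:
        if d.X.shape[1] != D:
            raise ValueError("embed_dim mismatch between datasets")
        if d.modalities != mods:
            raise ValueError("modality schema mismatch between datasets")
    cancer = None
    if all(d.cancer_labels is not None for d in datasets):
        cancer = np.concatenate([d.cancer_labels for d in datasets])
    return RecognitionDataset(
        X=np.concatenate([d.X for d in datasets], axis=0),
        Y=np.concatenate([d.Y for d in datasets], axis=0),
        modalities=mods,
        sample_count="mixed",
        cancer_labels=cancer,
    )


def build_patient_dataset(
    pool: EmbeddingPool,
    patients: pd.DataFrame,
    sample_count: int,
    repeats: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One PatientAggregate row per patient; returns (X, aligned label table)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, kept = [], []
    for _, rec in patients.iterrows():
        mask = pool.patient_id == rec["patient_id"]
        if not mask.any():
            continue
        agg = sample_patient_level(pool.subset(mask), sample_count, repeats, rng)
        rows.append(agg.vector)
        kept.append(rec)
    if not rows:
        raise ValueError("no patients with embeddings in pool")
    return np.stack(rows).astype(_F), pd.DataFrame(kept).reset_index(drop=True)


def _noise_replacement_count(fraction: float, sample_count: int) -> int:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("noise fraction must be in [0, 1]")
    if fraction == 0.0:
        return 0
    # round() alone would deactivate small fractions at low sample counts
    return max(1, int(round(fraction * sample_count)))


def perturb_with_noise(
    sample: AggregateSample,
    fraction: float,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> AggregateSample:
    """Replace a fraction of constituents by Gaussian noise vectors.

    The total constituent count is preserved; replaced constituents are
    removed from the composition targets and counted in noise_count.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sc = sample.sample_count
    k = _noise_replacement_count(fraction, sc)
    if k == 0:
        return sample
    D = sample.vector.shape[0]
    replace_at = rng.choice(sc, size=k, replace=False)
    constituents = sample.constituent_vectors.copy()
    constituents[replace_at] = (rng.standard_normal((k, D)) * noise_sd).astype(_F)
    keep = np.setdiff1d(np.arange(sc), replace_at)
    composition = tuple(np.array(sample.composition, dtype=object)[keep])
    return AggregateSample(
        vector=constituents.sum(axis=0),
        composition=composition,
        constituent_vectors=constituents,
        cancer_type=sample.cancer_type,
        noise_count=k,
    )


def perturb_dataset(
    dataset: RecognitionDataset,
    pool: EmbeddingPool,
    fraction: float,
    noise_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> RecognitionDataset:
    """Vectorised whole-constituent noise replacement over a dataset.

    Requires an isolation dataset that retained its constituent indices.
    """
    if dataset.constituent_indices is None or dataset.constituent_modalities is None:
        raise ValueError("dataset does not carry constituent information")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, sc = dataset.constituent_indices.shape
    k = _noise_replacement_count(fraction, sc)
    if k == 0:
        return dataset
    D = dataset.X.shape[1]
    # per-row noise positions: argsort of uniforms = seeded random subsets
    order = rng.random((n, sc)).argsort(axis=1)
    noise_pos = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    removed = pool.vectors[dataset.constituent_indices[rows, noise_pos.ravel()]]
    noise = (rng.standard_normal((n * k, D)) * noise_sd).astype(_F)
    X = dataset.X.copy()
    np.subtract.at(X, rows, removed)
    np.add.at(X, rows, noise)
    surviving = dataset.constituent_modalities.astype(np.int16).copy()
    surviving[rows, noise_pos.ravel()] = -1
    Y = np.zeros_like(dataset.Y)
    for m in range(len(dataset.modalities)):
        Y[:, m] = (surviving == m).any(axis=1)
    return RecognitionDataset(
        X=X.astype(_F),
        Y=Y,
        modalities=dataset.modalities,
        sample_count=dataset.sample_count,
        cancer_labels=dataset.cancer_labels,
        noise_counts=np.full(n, k),
    )
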