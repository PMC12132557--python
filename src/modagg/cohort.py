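"""Synthetic multimodal cancer cohort generator.

Emulates the statistical structure the aggregation study relies on: each
patient carries a low-dimensional latent factor (cancer-type centroid +
subtype offset + patient noise), and every data modality observes that
factor through its *own* fixed random map with its own noise — so the raw
modality spaces, and the embedding spaces later trained on them, are built
with no coordination beyond dimensionality.

Modalities and their per-patient multiplicities mirror a real multi-omic
cohort: exactly one RNA expression profile and one one-hot somatic mutation
profile per patient, and variable numbers of histology tiles and clinical
annotation segments per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "CANCER_TYPES",
    "CohortConfig",
    "Cohort",
    "TmbLabel",
    "generate_cohort",
    "compute_tmb",
    "assign_subtypes",
    "subtype_tasks",
    "draw_multiplicities",
]

MODALITIES = ("rna", "image", "mutation", "annotation")

#: the six tumor types of the study cohort
CANCER_TYPES = ("BRCA", "BLCA", "LUAD", "STAD", "THCA", "COAD")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    class_separation is the approximate Euclidean distance between
    cancer-type centroids in latent space; patient-level latent noise has
    unit sd, so class_separation is directly an effect size.  noise_sd
    scales the additive noise each modality map adds in its raw feature
    space (and the latent jitter of per-record modalities).
    """

    n_patients_per_type: int = 50
    cancer_types: tuple[str, ...] = CANCER_TYPES
    latent_dim: int = 16
    embed_dim: int = 768
    n_genes_rna: int = 600
    n_genes_mutation: int = 500
    # multiplicity specs: ("fixed", k) or ("poisson_plus_one", lam)
    image_multiplicity: tuple[str, float] = ("poisson_plus_one", 40.0)
    annotation_multiplicity: tuple[str, float] = ("poisson_plus_one", 10.0)
    class_separation: float = 10.0
    subtype_separation: float = 3.0
    n_subtypes_per_type: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients_per_type < 1:
            raise ValueError("n_patients_per_type must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.class_separation < 0 or self.noise_sd < 0:
            raise ValueError("class_separation and noise_sd must be >= 0")
        if self.n_subtypes_per_type < 1:
            raise ValueError("n_subtypes_per_type must be >= 1")
        for spec in (self.image_multiplicity, self.annotation_multiplicity):
            _validate_multiplicity(spec)


def _validate_multiplicity(spec: tuple[str, float]) -> None:
    kind, value = spec
    if kind not in ("fixed", "poisson_plus_one"):
        raise ValueError(f"unknown multiplicity kind {kind!r}")
    if value < 0 or (kind == "fixed" and value < 1):
        raise ValueError(f"invalid multiplicity parameter {value!r}")


def draw_multiplicities(
    spec: tuple[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-patient record counts; always >= 1 (every patient has data)."""
    _validate_multiplicity(spec)
    kind, value = spec
    if kind == "fixed":
        return np.full(n, int(value), dtype=np.int64)
    return rng.poisson(value, size=n) + 1


@dataclass(frozen=True)
class TmbLabel:
    """Tumor mutational burden in mutations/Mb plus its class label.

    Classes: 0 = low burden, 1 = high burden (>= threshold), 2 = no
    mutations at all (kept separate because a zero count is qualitatively
    different from a low one).
    """

    tmb_value: float
    tmb_class: int


def compute_tmb(
    mutation_row: np.ndarray,
    exonic_coverage_mb: float = 30.0,
    threshold: float = 0.5,
) -> TmbLabel:
    """Mutations-per-megabase from a one-hot mutation row.

    TMB = (number of mutated genes) / exonic_coverage_mb, with the exonic
    footprint fixed at 30 Mb by default.
    """
    row = np.asarray(mutation_row)
    if exonic_coverage_mb <= 0:
        raise ValueError("exonic_coverage_mb must be > 0")
    if row.size and not np.isin(row, (0, 1)).all():
        raise ValueError("mutation_row must be binary (0/1)")
    count = int(row.sum())
    if count == 0:
        return TmbLabel(0.0, 2)
    value = count / exonic_coverage_mb
    return TmbLabel(value, 1 if value >= threshold else 0)


@dataclass
class Cohort:
    """Generated cohort: label table, latent factors and raw modality data."""

    config: CohortConfig
    patients: pd.DataFrame  # patient_id, cancer_type, subtype, tmb_value, tmb_class
    latents: np.ndarray  # (n_patients, latent_dim)
    rna_matrix: np.ndarray  # (n_patients, n_genes_rna) float32
    mutation_matrix: np.ndarray  # (n_patients, n_genes_mutation) int8, one-hot
    image_features: list[np.ndarray]  # per patient (k_i, embed_dim) in [0, 1]
    annotation_latents: list[np.ndarray]  # per patient (m_i, latent_dim)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def tile_images(self, patient_index: int, side: int | None = None) -> np.ndarray:
        """Materialise a patient's tiles as (k, side, side, 3) uint8 RGB.

        The side defaults to sqrt(embed_dim / 3), e.g. 16 for 768 features.
        """
        feats = self.image_features[patient_index]
        if side is None:
            side = int(round(np.sqrt(feats.shape[1] / 3)))
        if feats.shape[1] != 3 * side * side:
            raise ValueError(
                f"embed_dim {feats.shape[1]} does not factor as {side}x{side}x3"
            )
        return (feats.reshape(-1, side, side, 3) * 255).astype(np.uint8)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("latents", data=self.latents)
            f.create_dataset("rna_matrix", data=self.rna_matrix)
            f.create_dataset("mutation_matrix", data=self.mutation_matrix)
            img = f.create_group("image_features")
            ann = f.create_group("annotation_latents")
            for i in range(self.n_patients):
                img.create_dataset(str(i), data=self.image_features[i])
                ann.create_dataset(str(i), data=self.annotation_latents[i])
            f.attrs["cancer_types"] = list(self.config.cancer_types)
            f.attrs["seed"] = self.config.seed

    def labels_to_csv(self, path) -> None:
        self.patients.to_csv(path, index=False)


def _spread_points(
    n: int, dim: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """n points whose pairwise distances are ~separation on average."""
    raw = rng.standard_normal((n, dim))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    # independent random unit vectors are near-orthogonal in high dim, so
    # scaling by separation/sqrt(2) puts pairs ~separation apart
    return raw * (separation / np.sqrt(2.0))


def assign_subtypes(
    cancer_types: np.ndarray,
    type_list: tuple[str, ...],
    n_subtypes_per_type: int,
    subtype_separation: float,
    latent_dim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each patient a subtype and the corresponding latent offset.

    Subtypes are sub-centroids within each cancer-type cluster; a
    separation of 0 yields labelled but indistinguishable subtypes.
    Returns (subtype label array, (n, latent_dim) offsets).
    """
    n = len(cancer_types)
    labels = np.empty(n, dtype=object)
    offsets = np.zeros((n, latent_dim))
    for ct in type_list:
        mask = cancer_types == ct
        sub_centroids = _spread_points(
            n_subtypes_per_type, latent_dim, subtype_separation, rng
        )
        idx = rng.integers(0, n_subtypes_per_type, size=mask.sum())
        labels[mask] = [f"{ct}_s{j}" for j in idx]
        offsets[mask] = sub_centroids[idx]
    return labels, offsets


def subtype_tasks(cohort: Cohort, min_samples: int = 100) -> list[tuple[str, pd.DataFrame]]:
    """Subtype prediction tasks for types with more than min_samples patients."""
    tasks = []
    for ct, group in cohort.patients.groupby("cancer_type", sort=False):
        if len(group) > min_samples and group["subtype"].nunique() > 1:
            tasks.append((ct, group[["patient_id", "subtype"]].copy()))
    return tasks


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministically for a given seed."""
    rng = np.random.default_rng(config.seed)
    types = config.cancer_types
    n = config.n_patients_per_type * len(types)
    ld = config.latent_dim

    cancer_type = np.repeat(np.array(types, dtype=object), config.n_patients_per_type)
    patient_id = np.array([f"P{i:05d}" for i in range(n)], dtype=object)

    centroids = _spread_points(len(types), ld, config.class_separation, rng)
    subtype, sub_offset = assign_subtypes(
        cancer_type, types, config.n_subtypes_per_type,
        config.subtype_separation, ld, rng,
    )
    type_index = np.array([types.index(c) for c in cancer_type])
    latents = centroids[type_index] + sub_offset + rng.standard_normal((n, ld))

    # --- RNA: one continuous profile per patient via a fixed affine map
    A_rna = rng.standard_normal((ld, config.n_genes_rna)) / np.sqrt(ld)
    b_rna = rng.standard_normal(config.n_genes_rna)
    rna = latents @ A_rna + b_rna
    rna += rng.standard_normal(rna.shape) * config.noise_sd
    rna = rna.astype(np.float32)

    # --- mutations: one one-hot row per patient.  Per-patient expected
    # count is log-normal and tied to the latent, spanning zero-mutation
    # patients through high-burden ones so all three TMB classes occur.
    G = config.n_genes_mutation
    w_burden = rng.standard_normal(ld) / np.sqrt(ld)
    burden_score = latents @ w_burden + rng.standard_normal(n) * 0.8
    lam = np.exp(1.8 + 0.8 * (burden_score - burden_score.mean()) / burden_score.std())
    B_gene = rng.standard_normal((ld, G)) * 0.5 / np.sqrt(ld)
    base_gene = rng.standard_normal(G) * 0.5
    gene_logits = latents @ B_gene + base_gene
    gene_w = np.exp(gene_logits - gene_logits.max(axis=1, keepdims=True))
    gene_w /= gene_w.sum(axis=1, keepdims=True)
    p_mut = np.clip(lam[:, None] * gene_w, 0.0, 1.0)
    mutation = (rng.random((n, G)) < p_mut).astype(np.int8)

    tmb = [compute_tmb(row) for row in mutation]

    # --- image tiles: per-record latent jitter -> fixed sigmoid map into
    # [0, 1] pixel features (one row per tile, reshapeable to an RGB tile)
    A_img = rng.standard_normal((ld, config.embed_dim)) / np.sqrt(ld)
    b_img = rng.standard_normal(config.embed_dim) * 0.5
    img_counts = draw_multiplicities(config.image_multiplicity, n, rng)
    image_features = []
    for i in range(n):
        z = latents[i] + rng.standard_normal((img_counts[i], ld)) * 0.5 * config.noise_sd
        feats = z @ A_img + b_img
        feats += rng.standard_normal(feats.shape) * 0.3 * config.noise_sd
        image_features.append(
            (1.0 / (1.0 + np.exp(-feats))).astype(np.float32)
        )

    # --- annotations: per-segment latent jitter only; the deterministic
    # semantic-space map lives in the embedders module, uncoordinated with
    # any of the above maps.
    ann_counts = draw_multiplicities(config.annotation_multiplicity, n, rng)
    annotation_latents = [
        latents[i] + rng.standard_normal((ann_counts[i], ld)) * 0.5 * config.noise_sd
        for i in range(n)
    ]

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "cancer_type": cancer_type,
            "subtype": subtype,
            "tmb_value": [t.tmb_value for t in tmb],
            "tmb_class": [t.tmb_class for t in tmb],
        }
    )
    return Cohort(
        config=config,
        patients=patients,
        latents=latents,
        rna_matrix=rna,
        mutation_matrix=mutation,
        image_features=image_features,
        annotation_latents=annotation_latents,
    )
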