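"""Config-driven orchestration of the full study at desk scale.

``run_experiment`` wires cohort generation -> embedding training ->
aggregation -> model training -> stratified evaluation, writes per-run
metric CSVs plus a JSON manifest (config hash, seed ladder, artifact
list), and skips stages whose outputs already exist under a matching
manifest.  Seeds are derived from the master seed with a fixed counter
scheme so every stage and run is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import (
    build_composite,
    build_dataset,
    build_patient_dataset,
    perturb_dataset,
)
from .cohort import CohortConfig, generate_cohort
from .embedders import EmbeddingPool, build_pool
from .models import (
    ClassifierConfig,
    RecognizerConfig,
    TrainedRecognizer,
    build_recognizer,
    train_classifier,
    train_recognizer,
)

__all__ = ["ExperimentConfig", "run_experiment", "run_noise_sweep", "stage_seed"]

log = logging.getLogger("modagg")


def stage_seed(master_seed: int, stage: str, run: int = 0) -> int:
    """Deterministic per-stage/per-run seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{run}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    strategy: str = "modality_level"
    sample_counts: tuple[int, ...] = tuple(range(3, 11))
    dataset_size: int = 15000
    repeats: int = 5
    noise_fractions: tuple[float, ...] = (0.0, 0.1, 0.5)
    n_runs: int = 30
    master_seed: int = 42
    recognizer: RecognizerConfig = field(default_factory=RecognizerConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self):
        if any(not 1 <= sc <= 50 for sc in self.sample_counts):
            raise ValueError("sample_counts must lie in [1, 50]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if any(not 0 <= f <= 1 for f in self.noise_fractions):
            raise ValueError("noise fractions must be in [0, 1]")

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.json"


def _load_manifest(outdir: Path, cfg_hash: str) -> dict:
    path = _manifest_path(outdir)
    if path.exists():
        manifest = json.loads(path.read_text())
        if manifest.get("config_hash") == cfg_hash:
            return manifest
    return {"config_hash": cfg_hash, "stages": {}, "artifacts": []}


def _save_manifest(outdir: Path, manifest: dict) -> None:
    _manifest_path(outdir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_done(manifest: dict, name: str, outdir: Path) -> bool:
    stage = manifest["stages"].get(name)
    if not stage:
        return False
    return all((outdir / f).exists() for f in stage.get("files", []))


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run the recogniser experiment grid; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest = _load_manifest(outdir, cfg_hash)

    def finish_stage(name: str, files: list[str], seed: int) -> None:
        manifest["stages"][name] = {"files": files, "seed": seed}
        for f in files:
            if f not in manifest["artifacts"]:
                manifest["artifacts"].append(f)
        _save_manifest(outdir, manifest)

    # --- stage: cohort + embedding pool
    pool_file = "pool.h5"
    seed_pool = stage_seed(config.master_seed, "pool")
    if _stage_done(manifest, "pool", outdir):
        log.info("pool stage cached; skipping")
        pool = EmbeddingPool.from_hdf5(outdir / pool_file)
        cohort = generate_cohort(
            dataclasses.replace(config.cohort, seed=stage_seed(config.master_seed, "cohort"))
        )
    else:
        log.info("generating cohort and training embedders (seed=%d)", seed_pool)
        cohort = generate_cohort(
            dataclasses.replace(config.cohort, seed=stage_seed(config.master_seed, "cohort"))
        )
        pool = build_pool(cohort, seed=seed_pool)
        pool.to_hdf5(outdir / pool_file)
        cohort.labels_to_csv(outdir / "patients.csv")
        finish_stage("pool", [pool_file, "patients.csv"], seed_pool)

    # --- stage: isolation datasets + recognisers + stratified reports
    summary_rows = []
    for sc in config.sample_counts:
        name = f"recognizer_sc{sc}"
        report_file = f"stratified_sc{sc}.csv"
        seed_ds = stage_seed(config.master_seed, f"dataset_sc{sc}")
        if _stage_done(manifest, name, outdir):
            log.info("%s cached; skipping", name)
            continue
        dataset = build_dataset(
            pool, sc, n=config.dataset_size, strategy=config.strategy, rng=seed_ds
        )
        rec_cfg = dataclasses.replace(
            config.recognizer,
            embed_dim=pool.embed_dim,
            seed=stage_seed(config.master_seed, f"recognizer_sc{sc}"),
            cancer_head=config.strategy == "specific_cancer",
            cancer_types=tuple(np.unique(pool.cancer_type))
            if config.strategy == "specific_cancer"
            else (),
        )
        trained = train_recognizer(build_recognizer(rec_cfg), dataset, rec_cfg)
        report = trained.evaluate(dataset)
        report.to_csv(outdir / report_file)
        for _, row in report.table.iterrows():
            summary_rows.append({"sample_count": sc, **row.to_dict()})
        # noise sweep on the clean-trained model
        sweep = run_noise_sweep(
            trained, dataset, pool, config.noise_fractions,
            seed=stage_seed(config.master_seed, f"noise_sc{sc}"),
        )
        sweep_file = f"noise_sweep_sc{sc}.csv"
        sweep.to_csv(outdir / sweep_file, index=False)
        finish_stage(name, [report_file, sweep_file], seed_ds)
    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(outdir / "recognizer_summary.csv", index=False)
        finish_stage("summary", ["recognizer_summary.csv"], config.master_seed)

    # --- stage: patient-level classifier
    clf_name = "classifier"
    if not _stage_done(manifest, clf_name, outdir):
        seed_clf = stage_seed(config.master_seed, "classifier")
        X, labels = build_patient_dataset(
            pool, cohort.patients, sample_count=5, repeats=config.repeats, rng=seed_clf
        )
        result = train_classifier(
            X, labels["cancer_type"].to_numpy(), "cancer_type",
            dataclasses.replace(config.classifier, seed=seed_clf),
            n_runs=config.n_runs,
        )
        result.runs.to_csv(outdir / "classifier_runs.csv", index=False)
        result.per_class_f1.to_csv(outdir / "classifier_per_class_f1.csv", index=False)
        finish_stage(clf_name, ["classifier_runs.csv", "classifier_per_class_f1.csv"], seed_clf)

    return manifest


def run_noise_sweep(
    trained: TrainedRecognizer,
    dataset,
    pool: EmbeddingPool,
    fractions=(0.0, 0.1, 0.5),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluation-only pass over noise-perturbed test sets.

    The recogniser must have been trained on clean data; no retraining
    happens here.  Fraction 0 reproduces the clean test report.
    """
    rows = []
    for frac in fractions:
        if frac == 0.0:
            perturbed = dataset
        else:
            perturbed = perturb_dataset(dataset, pool, frac, noise_sd, rng=seed)
        report = trained.evaluate(perturbed)
        for _, row in report.table.iterrows():
            rows.append({"noise_fraction": frac, **row.to_dict()})
    return pd.DataFrame(rows)
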