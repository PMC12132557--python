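"""Shared fixtures.

Small fixtures (tiny cohort/pool) back the unit tests; the session-scoped
``default_pool`` / ``trained_recognizer_sc3`` fixtures reproduce the
package's default study conditions once and are shared by the acceptance
tests, which are the expensive part of the suite.
"""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from modagg import (
    CohortConfig,
    EmbeddingPool,
    RecognizerConfig,
    VaeConfig,
    build_dataset,
    build_pool,
    build_recognizer,
    generate_cohort,
    train_recognizer,
)
from modagg.cohort import MODALITIES

SMALL_EMBED_DIM = 48


def small_cohort_config(**overrides):
    defaults = dict(
        n_patients_per_type=10,
        embed_dim=SMALL_EMBED_DIM,
        image_multiplicity=("poisson_plus_one", 5.0),
        annotation_multiplicity=("poisson_plus_one", 3.0),
        seed=1,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def small_vae_config(embed_dim=SMALL_EMBED_DIM, **overrides):
    defaults = dict(
        latent_dim=embed_dim, hidden_sizes=(128,), max_epochs=10, patience=5, seed=3
    )
    defaults.update(overrides)
    defaults["patience"] = min(defaults["patience"], defaults["max_epochs"])
    return VaeConfig(**defaults)


def build_small_pool(cohort, seed=5):
    D = cohort.config.embed_dim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_pool(
            cohort,
            rna_config=small_vae_config(D, seed=11),
            mutation_config=small_vae_config(D, seed=12),
            image_config=small_vae_config(D, latent_dim=2 * D, seed=13),
            seed=seed,
        )


def random_pool(rng, embed_dim=16, per_modality=20, cancer_types=("A", "B")):
    """A pool of raw random vectors (no training) for structural tests."""
    n = per_modality * len(MODALITIES)
    vectors = rng.standard_normal((n, embed_dim)).astype(np.float32)
    modality = np.repeat(np.array(MODALITIES, dtype=object), per_modality)
    patient = np.array([f"P{i}" for i in range(n)], dtype=object)
    ctype = np.array(
        [cancer_types[i % len(cancer_types)] for i in range(n)], dtype=object
    )
    return EmbeddingPool(vectors, modality, patient, ctype)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def small_pool(small_cohort):
    return build_small_pool(small_cohort)


# --- default study conditions (shared by the acceptance tests) ---------------


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_pool(default_cohort):
    return build_pool(default_cohort, seed=42)


@pytest.fixture(scope="session")
def isolation_sc3(default_pool):
    """Isolation dataset at sample count 3, 5000 aggregates."""
    return build_dataset(default_pool, sample_count=3, n=5000, rng=1)


@pytest.fixture(scope="session")
def trained_recognizer_sc3(isolation_sc3):
    config = RecognizerConfig(seed=1)
    return train_recognizer(build_recognizer(config), isolation_sc3, config)
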