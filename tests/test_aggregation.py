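"""Aggregation: sampling strategies, composition tracking, noise replacement."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from modagg import (
    EmbeddingPool,
    build_composite,
    build_dataset,
    build_patient_dataset,
    perturb_dataset,
    perturb_with_noise,
    sample_modality_level,
    sample_patient_level,
    sample_specific_cancer,
)
from modagg.cohort import MODALITIES

from conftest import random_pool


@pytest.fixture
def pool():
    return random_pool(np.random.default_rng(0))


def ones_pool(value=1.0, per_modality=3):
    n = per_modality * len(MODALITIES)
    return EmbeddingPool(
        np.full((n, 8), value, dtype=np.float32),
        np.repeat(np.array(MODALITIES, dtype=object), per_modality),
        np.array([f"P{i}" for i in range(n)], dtype=object),
        np.array(["A"] * n, dtype=object),
    )


class TestModalityLevelSampling:
    def test_sum_of_one_is_a_pool_vector(self, pool):
        s = sample_modality_level(pool, 1, rng=np.random.default_rng(1))
        assert any(np.array_equal(s.vector, v) for v in pool.vectors)
        assert len(s.composition) == 1

    def test_all_ones_pool_sums_to_count(self):
        s = sample_modality_level(ones_pool(), 5, rng=np.random.default_rng(0))
        assert np.allclose(s.vector, 5.0)

    def test_order_invariance_of_summation(self, pool):
        rng = np.random.default_rng(3)
        s = sample_modality_level(pool, 7, rng=rng)
        perm = np.random.default_rng(4).permutation(7)
        assert np.allclose(
            s.constituent_vectors[perm].sum(axis=0), s.vector, atol=1e-4
        )

    def test_empty_modality_with_positive_prob_errors(self, pool):
        sub = pool.subset(pool.modality != "rna")
        with pytest.raises(ValueError, match="rna"):
            sample_modality_level(sub, 3, rng=np.random.default_rng(0))

    def test_invalid_probs_rejected(self, pool):
        with pytest.raises(ValueError):
            sample_modality_level(pool, 2, modality_probs=[0.5, 0.5, 0.5, 0.5],
                                  rng=np.random.default_rng(0))


class TestCancerSpecificSampling:
    def test_constituents_share_cancer_type(self, pool):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = sample_specific_cancer(pool, 4, "A", rng=rng)
            assert s.cancer_type == "A"
            for v in s.constituent_vectors:
                row = np.flatnonzero((pool.vectors == v).all(axis=1))[0]
                assert pool.cancer_type[row] == "A"

    def test_absent_type_errors(self, pool):
        with pytest.raises(ValueError):
            sample_specific_cancer(pool, 3, "NOPE", rng=np.random.default_rng(0))

    def test_sampling_with_replacement_on_tiny_pool(self):
        # one embedding per modality of type A: a draw of 4 may repeat them
        rng = np.random.default_rng(0)
        pool = random_pool(rng, per_modality=2, cancer_types=("A", "B"))
        seen_repeat = False
        for seed in range(30):
            s = sample_specific_cancer(pool, 4, "A", rng=np.random.default_rng(seed))
            if len(set(s.composition)) < len(s.composition):
                seen_repeat = True
        assert seen_repeat


class TestPatientLevelSampling:
    def test_concatenated_length_is_repeats_times_dim(self, pool):
        sub = pool.subset(pool.patient_id == "P0")
        agg = sample_patient_level(sub, 4, repeats=3, rng=np.random.default_rng(0))
        assert agg.vector.shape == (3 * pool.embed_dim,)

    def test_single_draw_returns_pool_embedding(self, pool):
        sub = pool.subset(pool.patient_id == "P0")
        agg = sample_patient_level(sub, 1, 1, rng=np.random.default_rng(0))
        assert np.array_equal(agg.vector, sub.vectors[0])

    def test_single_embedding_patient_forced_sum(self, pool):
        sub = pool.subset(pool.patient_id == "P0")
        agg = sample_patient_level(sub, 5, 2, rng=np.random.default_rng(0))
        assert np.allclose(agg.vector[: pool.embed_dim], 5 * sub.vectors[0], atol=1e-4)

    def test_empty_pool_errors(self, pool):
        empty = pool.subset(np.zeros(len(pool.vectors), dtype=bool))
        with pytest.raises(ValueError):
            sample_patient_level(empty, 2, 2, rng=np.random.default_rng(0))


class TestBuildDataset:
    def test_row_count_and_presence_targets(self, pool):
        ds = build_dataset(pool, 3, n=500, rng=0)
        assert len(ds) == 500
        assert ds.X.shape == (500, pool.embed_dim)
        assert np.isin(ds.Y, (0, 1)).all()
        # presence target is 1 exactly for modalities with >= 1 constituent
        for i in range(50):
            present = {MODALITIES[m] for m in ds.constituent_modalities[i]}
            assert set(np.array(MODALITIES)[ds.Y[i] == 1]) == present

    def test_sums_match_constituents(self, pool):
        ds = build_dataset(pool, 4, n=50, rng=1)
        for i in range(10):
            manual = pool.vectors[ds.constituent_indices[i]].sum(axis=0)
            assert np.allclose(ds.X[i], manual, atol=1e-4)

    def test_deterministic_given_seed(self, pool):
        a = build_dataset(pool, 3, n=200, rng=5)
        b = build_dataset(pool, 3, n=200, rng=5)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)

    def test_n_zero_rejected(self, pool):
        with pytest.raises(ValueError):
            build_dataset(pool, 3, n=0, rng=0)

    def test_cancer_specific_rows_single_type(self, pool):
        ds = build_dataset(pool, 3, n=100, strategy="specific_cancer", rng=2)
        assert ds.cancer_labels is not None
        for i in range(20):
            types = {pool.cancer_type[g] for g in ds.constituent_indices[i]}
            assert types == {ds.cancer_labels[i]}

    def test_uniform_modality_probability_default(self, pool):
        ds = build_dataset(pool, 1, n=8000, rng=3)
        freq = np.bincount(ds.constituent_modalities.ravel(), minlength=4) / 8000
        assert np.allclose(freq, 0.25, atol=0.02)


class TestComposite:
    def test_eight_isolation_datasets_concatenate(self, pool):
        parts = [build_dataset(pool, sc, n=100, rng=sc) for sc in range(3, 11)]
        comp = build_composite(parts)
        assert len(comp) == 800
        assert comp.sample_count == "mixed"

    def test_identity_on_single_dataset(self, pool):
        ds = build_dataset(pool, 3, n=50, rng=0)
        comp = build_composite([ds])
        assert np.array_equal(comp.X, ds.X) and np.array_equal(comp.Y, ds.Y)

    def test_size_conservation(self, pool):
        sizes = [10, 25, 40]
        parts = [build_dataset(pool, 3, n=s, rng=s) for s in sizes]
        assert len(build_composite(parts)) == sum(sizes)

    def test_dim_mismatch_rejected(self, pool):
        other = random_pool(np.random.default_rng(1), embed_dim=8)
        with pytest.raises(ValueError):
            build_composite(
                [build_dataset(pool, 3, n=10, rng=0),
                 build_dataset(other, 3, n=10, rng=0)]
            )


class TestNoisePerturbation:
    def test_fraction_zero_is_identity(self, pool):
        s = sample_modality_level(pool, 5, rng=np.random.default_rng(0))
        out = perturb_with_noise(s, 0.0, rng=np.random.default_rng(1))
        assert out is s

    def test_half_replacement_preserves_total(self, pool):
        s = sample_modality_level(pool, 10, rng=np.random.default_rng(0))
        out = perturb_with_noise(s, 0.5, rng=np.random.default_rng(1))
        assert out.noise_count == 5
        assert len(out.composition) == 5
        assert out.sample_count == 10

    def test_full_replacement_empties_composition(self, pool):
        s = sample_modality_level(pool, 4, rng=np.random.default_rng(0))
        out = perturb_with_noise(s, 1.0, rng=np.random.default_rng(1))
        assert out.composition == ()
        assert np.allclose(out.vector, out.constituent_vectors.sum(axis=0), atol=1e-4)

    def test_minimum_one_replacement_for_small_fractions(self, pool):
        s = sample_modality_level(pool, 3, rng=np.random.default_rng(0))
        out = perturb_with_noise(s, 0.1, rng=np.random.default_rng(1))
        assert out.noise_count == 1

    def test_fraction_out_of_range_rejected(self, pool):
        s = sample_modality_level(pool, 3, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            perturb_with_noise(s, 1.5)

    def test_dataset_perturbation_conserves_labels(self, pool):
        ds = build_dataset(pool, 10, n=200, rng=0)
        out = perturb_dataset(ds, pool, 0.5, rng=1)
        assert (out.noise_counts == 5).all()
        # surviving presence targets are a subset of the clean ones
        assert ((out.Y == 1) <= (ds.Y == 1)).all()
        assert len(out) == len(ds)

    def test_dataset_fraction_zero_identity(self, pool):
        ds = build_dataset(pool, 5, n=50, rng=0)
        assert perturb_dataset(ds, pool, 0.0, rng=1) is ds


class TestDecompositionOracle:
    def test_labels_match_exhaustive_multiset_search(self):
        """With a tiny pool of distinct vectors, the true composition of an
        aggregate is recoverable by exhaustive multiset search; the tracked
        labels must agree with that independent reconstruction."""
        rng = np.random.default_rng(42)
        pool = random_pool(rng, embed_dim=12, per_modality=5)
        items = list(range(len(pool.vectors)))
        sc = 3
        for trial in range(200):
            s = sample_modality_level(
                pool, sc, rng=np.random.default_rng(1000 + trial)
            )
            matches = []
            for combo in combinations_with_replacement(items, sc):
                total = pool.vectors[list(combo)].sum(axis=0)
                if np.allclose(total, s.vector, atol=1e-4):
                    matches.append(combo)
            assert len(matches) == 1
            recovered = tuple(sorted(pool.modality[list(matches[0])]))
            assert recovered == tuple(sorted(s.composition))


class TestPatientDataset:
    def test_one_row_per_patient(self, small_pool, small_cohort):
        X, labels = build_patient_dataset(small_pool, small_cohort.patients, 3, 2, rng=0)
        assert X.shape == (small_cohort.n_patients, 2 * small_pool.embed_dim)
        assert list(labels["patient_id"]) == list(small_cohort.patients["patient_id"])
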