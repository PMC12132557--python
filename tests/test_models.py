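"""Recognizer, baseline and classifier models: architecture contracts,
training behaviour on separable vs information-free data, split protocol."""

import warnings

import numpy as np
import pytest

from modagg import (
    ClassifierConfig,
    RecognizerConfig,
    build_composite,
    build_dataset,
    build_patient_dataset,
    build_recognizer,
    fit_baseline_mcrm,
    predict_composition,
    split_indices,
    train_classifier,
    train_recognizer,
)
from modagg.aggregation import RecognitionDataset
from modagg.cohort import MODALITIES

from conftest import (
    SMALL_EMBED_DIM,
    build_small_pool,
    small_cohort_config,
)
from modagg import generate_cohort

SMALL_REC = dict(
    embed_dim=SMALL_EMBED_DIM,
    shared_layer_sizes=(128, 64),
    branch_layer_sizes=(32,),
    max_epochs=40,
    patience=8,
)


class TestBuildRecognizer:
    def test_one_branch_per_modality(self):
        model = build_recognizer(RecognizerConfig(**SMALL_REC, seed=0))
        scores, logits = model.forward(np.zeros((3, SMALL_EMBED_DIM)))
        assert scores.shape == (3, 4)
        assert logits is None

    def test_cancer_head_adds_six_way_output(self):
        cfg = RecognizerConfig(
            **SMALL_REC, seed=0, cancer_head=True,
            cancer_types=("BRCA", "BLCA", "LUAD", "STAD", "THCA", "COAD"),
        )
        _, logits = build_recognizer(cfg).forward(np.zeros((3, SMALL_EMBED_DIM)))
        assert logits.shape == (3, 6)

    def test_same_seed_identical_parameters(self):
        cfg = RecognizerConfig(**SMALL_REC, seed=5)
        a, b = build_recognizer(cfg), build_recognizer(cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a._params(), b._params()))

    def test_empty_modalities_rejected(self):
        with pytest.raises(ValueError):
            RecognizerConfig(modalities=())

    def test_cancer_head_without_types_rejected(self):
        with pytest.raises(ValueError):
            RecognizerConfig(cancer_head=True)


class TestPredictComposition:
    class _Stub:
        def __init__(self, scores, threshold=0.5):
            self._scores = np.asarray(scores, dtype=float)
            from types import SimpleNamespace

            self.config = SimpleNamespace(presence_threshold=threshold)

        def predict_scores(self, X):
            return self._scores

    def test_threshold_rule(self):
        from modagg.models import predict_composition

        stub = self._Stub([[0.9, 0.1, 0.6, 0.4]])
        assert predict_composition(stub, np.zeros((1, 4))).tolist() == [[1, 0, 1, 0]]

    def test_threshold_is_inclusive(self):
        stub = self._Stub([[0.5, 0.5, 0.5, 0.5]])
        assert predict_composition(stub, np.zeros((1, 4))).tolist() == [[1, 1, 1, 1]]

    def test_batch_shape(self, small_pool):
        cfg = RecognizerConfig(**SMALL_REC, seed=0)
        model = build_recognizer(cfg)
        out = predict_composition(model, small_pool.vectors[:7])
        assert out.shape == (7, 4)

    def test_dimension_mismatch_rejected(self):
        model = build_recognizer(RecognizerConfig(**SMALL_REC, seed=0))
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 11)))


class TestSplits:
    @pytest.mark.parametrize("n", [10, 100, 1234])
    def test_split_conservation_and_disjointness(self, n):
        train, val, test = split_indices(n, np.random.default_rng(0))
        assert len(train) + len(val) + len(test) == n
        assert len(set(train) | set(val) | set(test)) == n
        assert len(test) == int(round(0.2 * n))
        assert len(val) == int(round(0.2 * (n - len(test))))


class TestTrainRecognizer:
    def test_recovers_composition_on_separable_pool(self, small_pool):
        ds = build_dataset(small_pool, 3, n=2000, rng=7)
        cfg = RecognizerConfig(**SMALL_REC, seed=3)
        trained = train_recognizer(build_recognizer(cfg), ds, cfg)
        mcc = trained.evaluate(ds).nonzero_mcc()
        assert min(mcc.values()) > 0.6
        assert np.mean(list(mcc.values())) > 0.8

    def test_no_information_gives_zero_mcc(self):
        rng = np.random.default_rng(0)
        n = 600
        X = np.tile(rng.standard_normal(SMALL_EMBED_DIM), (n, 1)).astype(np.float32)
        Y = (rng.random((n, 4)) < 0.5).astype(np.int8)
        ds = RecognitionDataset(X=X, Y=Y, modalities=MODALITIES, sample_count=3)
        cfg = RecognizerConfig(**{**SMALL_REC, "max_epochs": 10}, seed=1)
        trained = train_recognizer(build_recognizer(cfg), ds, cfg)
        mcc = trained.evaluate(ds).nonzero_mcc()
        assert all(abs(v) < 0.2 for v in mcc.values())

    def test_composite_dataset_accepted(self, small_pool):
        comp = build_composite(
            [build_dataset(small_pool, sc, n=150, rng=sc) for sc in (3, 4, 5)]
        )
        cfg = RecognizerConfig(**{**SMALL_REC, "max_epochs": 5}, seed=2)
        trained = train_recognizer(build_recognizer(cfg), comp, cfg)
        assert trained.history.shape[0] >= 1

    def test_training_history_recorded(self, small_pool):
        ds = build_dataset(small_pool, 3, n=400, rng=1)
        cfg = RecognizerConfig(**{**SMALL_REC, "max_epochs": 6, "patience": 6}, seed=0)
        trained = train_recognizer(build_recognizer(cfg), ds, cfg)
        assert {"epoch", "train_loss", "val_loss"} <= set(trained.history.columns)


class TestBaselineMcrm:
    def test_high_mcc_on_separable_low_count_data(self, small_pool):
        ds = build_dataset(small_pool, 3, n=2000, rng=7)
        baseline = fit_baseline_mcrm(ds, seed=0)
        mcc = baseline.evaluate(ds).nonzero_mcc()
        assert np.mean(list(mcc.values())) > 0.6

    def test_single_class_column_gets_constant_head(self, small_pool):
        ds = build_dataset(small_pool, 3, n=300, rng=1)
        ds.Y[:, 2] = 0  # force a degenerate always-absent target
        with pytest.warns(UserWarning, match="single-class"):
            baseline = fit_baseline_mcrm(ds, seed=0)
        pred = baseline.predict(ds.X[:10])
        assert (pred[:, 2] == 0).all()
        assert baseline.evaluate(ds).nonzero_mcc()[MODALITIES[2]] == 0.0

    def test_same_seed_identical_coefficients(self, small_pool):
        ds = build_dataset(small_pool, 3, n=500, rng=2)
        a, b = fit_baseline_mcrm(ds, seed=3), fit_baseline_mcrm(ds, seed=3)
        for m in a.modality_models:
            assert np.allclose(a.modality_models[m].coef_, b.modality_models[m].coef_)

    def test_annotation_recognition_stays_high_at_high_sample_count(
        self, default_pool
    ):
        """At high sample counts the isolation recogniser keeps annotation
        MCC above 0.9 and stays close to the linear baseline.  (The synthetic
        modality maps are affine in the latent, so unlike on real embeddings
        the baseline does not degrade here and offers no separation to beat.)
        """
        ds = build_dataset(default_pool, 8, n=5000, rng=9)
        cfg = RecognizerConfig(seed=4)
        dl = train_recognizer(build_recognizer(cfg), ds, cfg).evaluate(ds).nonzero_mcc()
        bl = fit_baseline_mcrm(ds, seed=4).evaluate(ds).nonzero_mcc()
        assert dl["annotation"] >= 0.9
        assert dl["annotation"] >= bl["annotation"] - 0.1


class TestTrainClassifier:
    SMALL_CLF = ClassifierConfig(hidden_sizes=(64,), max_epochs=60, patience=10)

    def test_run_protocol_aggregates_requested_runs(self, small_pool, small_cohort):
        X, labels = build_patient_dataset(small_pool, small_cohort.patients, 3, 2, rng=0)
        res = train_classifier(
            X, labels["cancer_type"].to_numpy(), config=self.SMALL_CLF, n_runs=3
        )
        assert len(res.runs) == 3
        assert res.per_class_f1.shape == (3, 6)
        assert res.confusion.sum() == 3 * 12  # 20% of 60 patients per run
        assert set(res.summary().index) == {"mean", "std"}

    def test_chance_accuracy_without_class_signal(self):
        cfg = small_cohort_config(class_separation=0.0, subtype_separation=0.0, seed=9)
        cohort = generate_cohort(cfg)
        pool = build_small_pool(cohort, seed=9)
        X, labels = build_patient_dataset(pool, cohort.patients, 3, 2, rng=1)
        res = train_classifier(
            X, labels["cancer_type"].to_numpy(), config=self.SMALL_CLF, n_runs=5
        )
        assert res.runs["accuracy"].mean() < 0.45  # ~1/6 up to small-sample noise

    def test_inconsistent_feature_rows_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((10, 4)), np.zeros(7), n_runs=1)


class TestGeneratorNoiseMonotonicity:
    def test_recognizer_mcc_non_increasing_in_generator_noise(self):
        """More raw-space noise in the generator blurs each modality's
        embedding signature, so recognition cannot improve (one-sided trend
        over 3 noise levels x 3 seeds, within sampling error)."""
        means = []
        for noise_sd in (0.5, 2.0, 6.0):
            vals = []
            for seed in (0, 1, 2):
                cfg = small_cohort_config(noise_sd=noise_sd, seed=20 + seed)
                pool = build_small_pool(generate_cohort(cfg), seed=20 + seed)
                ds = build_dataset(pool, 3, n=1200, rng=seed)
                rcfg = RecognizerConfig(**{**SMALL_REC, "max_epochs": 25}, seed=seed)
                trained = train_recognizer(build_recognizer(rcfg), ds, rcfg)
                vals.append(np.mean(list(trained.evaluate(ds).nonzero_mcc().values())))
            means.append(np.mean(vals))
        assert means[1] <= means[0] + 0.05
        assert means[2] <= means[1] + 0.05
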