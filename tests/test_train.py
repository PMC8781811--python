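"""Loss functions and the training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msapnea import (FocalParams, SegmentDataset, TrainConfig, build_model,
                     desk_config, fit, focal_loss, imbalance_experiment,
                     weighted_ce)


def _random_probs_labels(seed, n=50):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01, 1.0, n), rng.integers(0, 2, n)


class TestLosses:
    def test_worked_focal_value(self):
        # single sample, p_t = 0.9, alpha = 0.25, gamma = 2
        loss = focal_loss([0.9], [0], FocalParams(alpha=(0.25, 0.75),
                                                  gamma=2.0))
        assert math.isclose(loss, 0.25 * 0.1 ** 2 * (-math.log(0.9)),
                            rel_tol=1e-12)
        assert math.isclose(loss, 2.634e-4, rel_tol=1e-3)

    def test_perfect_predictions_give_zero_loss(self):
        assert focal_loss(np.ones(5), np.zeros(5, int),
                          FocalParams(gamma=2.0)) == 0.0
        assert weighted_ce(np.ones(5), np.zeros(5, int)) == 0.0

    def test_unit_alpha_inverse_exp(self):
        assert math.isclose(weighted_ce([math.exp(-1)], [1], (1.0, 1.0)),
                            1.0, rel_tol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_focal_gamma_zero_equals_weighted_ce(self, seed):
        p, y = _random_probs_labels(seed)
        params = FocalParams(alpha=(0.3, 0.7), gamma=0.0)
        assert focal_loss(p, y, params) == weighted_ce(p, y, params.alpha)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_all_one_alpha_is_plain_ce(self, seed):
        p, y = _random_probs_labels(seed)
        plain = float(np.mean(-np.log(np.clip(p, 1e-7, 1.0))))
        assert math.isclose(weighted_ce(p, y, (1.0, 1.0)), plain,
                            rel_tol=1e-12)

    def test_focal_strictly_decreasing_in_p(self):
        p = np.linspace(0.01, 0.999, 200)
        params = FocalParams(alpha=(0.5, 0.5), gamma=2.0)
        vals = [focal_loss([pi], [0], params) for pi in p]
        assert np.all(np.diff(vals) < 0)

    def test_modulation_downweights_easy_samples(self):
        # for p_t > 0.5 the focal/CE ratio is (1-p)^2 < 0.25
        for p in np.linspace(0.51, 0.99, 20):
            fl = focal_loss([p], [0], FocalParams(alpha=(0.5, 0.5), gamma=2.0))
            ce = weighted_ce([p], [0], (0.5, 0.5))
            assert fl / ce < 0.25

    def test_invalid_probabilities_raise(self):
        with pytest.raises(ValueError):
            focal_loss([1.2], [0], FocalParams())
        with pytest.raises(ValueError):
            weighted_ce([-0.1], [0])
        with pytest.raises(ValueError):
            FocalParams(gamma=-1.0)
        with pytest.raises(ValueError):
            FocalParams(alpha=(0.0, 1.0))


def _separable_dataset(n_per_class=20, seed=0, n_records=2,
                       minority_fraction=0.5):
    """Synthetic segments with a trivially separable class structure."""
    rng = np.random.default_rng(seed)
    t = np.arange(300) / 5.0
    segs, labels = [], []
    n_pos = int(round(2 * n_per_class * minority_fraction))
    n_neg = 2 * n_per_class - n_pos
    for label, count in ((0, n_neg), (1, n_pos)):
        for _ in range(count):
            base = rng.normal(0, 1.0, (2, 300))
            if label == 1:
                base += 3.0 * np.sin(2 * np.pi * t / 45.0)[None, :]
            segs.append(base)
            labels.append(label)
    order = rng.permutation(len(labels))
    segs = np.asarray(segs, dtype=np.float32)[order]
    labels = np.asarray(labels)[order]
    n = len(labels)
    rec = np.array([f"r{i % n_records}" for i in range(n)])
    return SegmentDataset(segments=segs, labels=labels, record_ids=rec,
                          minute_indices=np.arange(n),
                          norm_mean=np.zeros((n, 2)),
                          norm_std=np.ones((n, 2)))


class TestFit:
    def test_overfits_separable_segments(self):
        ds = _separable_dataset(n_per_class=20, seed=1)
        model = build_model(desk_config(), seed=0)
        model, history = fit(model, ds, TrainConfig(epochs=30, seed=0,
                                                    batch_size=16))
        train_pred = model.predict(ds.segments)
        assert np.mean(train_pred == ds.labels) == 1.0

    def test_same_seed_reproduces_final_loss(self):
        ds = _separable_dataset(n_per_class=10, seed=2)
        runs = []
        for _ in range(2):
            model = build_model(desk_config(), seed=3)
            _, history = fit(model, ds, TrainConfig(epochs=2, seed=3,
                                                    batch_size=16))
            runs.append(history["loss"].iloc[-1])
        assert runs[0] == runs[1]

    def test_empty_dataset_errors(self):
        ds = _separable_dataset(n_per_class=2)
        empty = SegmentDataset(segments=ds.segments[:0], labels=ds.labels[:0],
                               record_ids=ds.record_ids[:0],
                               minute_indices=ds.minute_indices[:0],
                               norm_mean=ds.norm_mean[:0],
                               norm_std=ds.norm_std[:0])
        with pytest.raises(ValueError, match="empty"):
            fit(build_model(desk_config(), seed=0), empty, TrainConfig())

    def test_single_class_with_class_weights_errors(self):
        ds = _separable_dataset(n_per_class=6, minority_fraction=0.0)
        with pytest.raises(ValueError, match="class"):
            fit(build_model(desk_config(), seed=0), ds,
                TrainConfig(loss_mode="class_weight", epochs=1))

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_mode="hinge")
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestImbalanceExperiment:
    def test_table_shape_and_consistency(self, tmp_path):
        ds = _separable_dataset(n_per_class=15, seed=4, n_records=4,
                                minority_fraction=0.2)
        seeds = (0, 1)
        table = imbalance_experiment(
            ds, TrainConfig(epochs=4, batch_size=16), seeds=seeds,
            out_dir=tmp_path)
        assert len(table) == 3 * len(seeds)
        assert set(table["mode"]) == {"focal", "class_weight", "plain"}
        from msapnea.train import record_split
        _, val_idx = record_split(ds)
        totals = table[["tn", "fp", "fn", "tp"]].sum(axis=1)
        assert np.all(totals == len(val_idx))
        assert (tmp_path / "imbalance_comparison.csv").exists()
        assert (tmp_path / "imbalance_comparison.png").exists()
        med = table.groupby("mode")["recall_minority"].median()
        assert med["focal"] >= med["plain"] - 1e-9

    def test_single_class_dataset_rejected(self):
        ds = _separable_dataset(n_per_class=4, minority_fraction=0.0)
        with pytest.raises(ValueError):
            imbalance_experiment(ds, TrainConfig(epochs=1), seeds=(0,))
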