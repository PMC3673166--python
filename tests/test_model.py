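"""Windowing, balanced sampling, training protocol and daily aggregation."""

import numpy as np
import pandas as pd
import pytest

from shearwater.model import (
    ClassifierModel,
    FeatureWindows,
    ModelConfig,
    balance_and_split,
    daily_proportions,
    evaluate_classifier,
    make_windows,
    predict_series,
    train_classifier,
)


def _logger(n, start="2008-01-01T00:05Z", salt=100):
    times = pd.date_range(start, periods=n, freq="10min", tz="UTC")
    return pd.DataFrame({"time": times, "salt": salt, "light": 0})


def _separable_windows(n_per_class, d=35, seed=0):
    """Linearly separable 3-class windows: distinct salt plateaus."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for lab, level in (("rest", 0.95), ("flight", 0.02), ("forage", 0.5)):
        X.append(rng.normal(level, 0.03, size=(n_per_class, d)))
        labels += [lab] * n_per_class
    times = pd.date_range("2008-01-01", periods=3 * n_per_class, freq="10min", tz="UTC")
    return FeatureWindows(
        X=np.vstack(X), center_time=times, labels=np.asarray(labels, dtype=object)
    )


class TestMakeWindows:
    def test_exact_length_series_one_window(self):
        cfg = ModelConfig()
        w = make_windows(_logger(cfg.window_samples), None, cfg)
        assert len(w.labels) == 1

    def test_sliding_count(self):
        cfg = ModelConfig()
        w = make_windows(_logger(cfg.window_samples + 2), None, cfg)
        assert len(w.labels) == 3

    def test_label_outside_tolerance_unknown(self):
        cfg = ModelConfig()
        log = _logger(cfg.window_samples)
        center = log["time"].iloc[cfg.window_samples // 2]
        lab = pd.DataFrame(
            {
                "time": [center + pd.Timedelta(minutes=12)],
                "lat": [0.0],
                "lon": [0.0],
                "label": ["flight"],
            }
        )
        w = make_windows(log, lab, cfg)
        assert w.labels[0] == "unknown"

    def test_label_within_tolerance_attached(self):
        cfg = ModelConfig()
        log = _logger(cfg.window_samples)
        center = log["time"].iloc[cfg.window_samples // 2]
        lab = pd.DataFrame(
            {
                "time": [center + pd.Timedelta(minutes=4)],
                "lat": [0.0],
                "lon": [0.0],
                "label": ["flight"],
            }
        )
        w = make_windows(log, lab, cfg)
        assert w.labels[0] == "flight"

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            make_windows(_logger(10), None, ModelConfig())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(window_samples=36)

    def test_short_gap_interpolated_long_gap_dropped(self):
        cfg = ModelConfig()
        log = _logger(cfg.window_samples + 10)
        log.loc[17, "salt"] = np.nan  # 1-sample gap: interpolated
        log.loc[40:44, "salt"] = np.nan  # 5-sample gap: windows dropped
        w = make_windows(log, None, cfg)
        assert not np.isnan(w.X).any()
        assert len(w.labels) < cfg.window_samples + 10 - cfg.window_samples + 1


class TestBalanceAndSplit:
    def test_default_pool_and_split_sizes(self):
        fw = _separable_windows(700)
        cfg = ModelConfig()
        train, test, val = balance_and_split(fw, cfg, seed=1)
        assert [len(y) for _, y in (train, test, val)] == [1000, 500, 500]
        pooled = np.concatenate([train[1], test[1], val[1]])
        counts = np.bincount(pooled)
        assert counts.sum() == 2000
        assert counts.max() - counts.min() <= 1
        for _, y in (train, test, val):
            c = np.bincount(y)
            assert c.max() - c.min() <= 2, "subsets must stay class-balanced"

    def test_insufficient_class_named_in_error(self):
        fw = _separable_windows(700)
        fw.labels[fw.labels == "flight"] = "unknown"
        with pytest.raises(ValueError, match="flight"):
            balance_and_split(fw, ModelConfig(), seed=1)

    def test_tiny_total_two_per_class(self):
        fw = _separable_windows(10)
        cfg = ModelConfig(total_examples=6)
        train, test, val = balance_and_split(fw, cfg, seed=1)
        pooled = np.concatenate([train[1], test[1], val[1]])
        assert len(pooled) == 6
        assert (np.bincount(pooled) == 2).all()


class TestTraining:
    def test_separable_problem_high_accuracy(self):
        fw = _separable_windows(700)
        cfg = ModelConfig(max_epochs=60)
        train, test, val = balance_and_split(fw, cfg, seed=1)
        model = train_classifier(train, test, cfg, seed=2)
        res = evaluate_classifier(model, val, seed=3)
        assert res.accuracy > 0.95

    def test_same_seed_identical_weights(self):
        fw = _separable_windows(100)
        cfg = ModelConfig(total_examples=150, max_epochs=10)
        train, test, _ = balance_and_split(fw, cfg, seed=1)
        m1 = train_classifier(train, test, cfg, seed=5)
        m2 = train_classifier(train, test, cfg, seed=5)
        for w1, w2 in zip(m1.net.coefs_, m2.net.coefs_):
            np.testing.assert_array_equal(w1, w2)

    def test_model_json_round_trip(self):
        fw = _separable_windows(100)
        cfg = ModelConfig(total_examples=150, max_epochs=10)
        train, test, val = balance_and_split(fw, cfg, seed=1)
        model = train_classifier(train, test, cfg, seed=5)
        clone = ClassifierModel.from_json(model.to_json())
        np.testing.assert_allclose(
            model.predict_proba(val[0]), clone.predict_proba(val[0]), atol=1e-12
        )


class TestEvaluation:
    def test_perfect_predictor_diagonal(self):
        fw = _separable_windows(700)
        cfg = ModelConfig(max_epochs=80)
        train, test, val = balance_and_split(fw, cfg, seed=1)
        model = train_classifier(train, test, cfg, seed=2)
        res = evaluate_classifier(model, val, seed=3)
        assert res.matrix.sum() == len(val[1])
        for i in range(3):
            assert res.matrix[i].sum() == (val[1] == i).sum()

    def test_probabilities_sum_to_one(self):
        fw = _separable_windows(100)
        cfg = ModelConfig(total_examples=150, max_epochs=10)
        train, test, val = balance_and_split(fw, cfg, seed=1)
        model = train_classifier(train, test, cfg, seed=5)
        p = model.predict_proba(val[0])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_validation_rejected(self):
        fw = _separable_windows(100)
        cfg = ModelConfig(total_examples=150, max_epochs=5)
        train, test, _ = balance_and_split(fw, cfg, seed=1)
        model = train_classifier(train, test, cfg, seed=5)
        with pytest.raises(ValueError):
            evaluate_classifier(model, (np.empty((0, 35)), np.empty(0, dtype=int)))


@pytest.fixture(scope="module")
def trained():
    fw = _separable_windows(700)
    cfg = ModelConfig(max_epochs=60)
    train, test, _ = balance_and_split(fw, cfg, seed=1)
    return train_classifier(train, test, cfg, seed=2)


class TestPredictSeries:
    def test_window_margins_unknown(self, trained):
        n = 500
        preds = predict_series(trained, _logger(n, salt=190))
        half = trained.config.window_samples // 2
        assert (preds["label"].iloc[:half] == "unknown").all()
        assert (preds["label"].iloc[-half:] == "unknown").all()
        assert (preds["label"].iloc[half : n - half] != "unknown").all()

    def test_constant_wet_series_is_rest(self, trained):
        preds = predict_series(trained, _logger(400, salt=190))
        known = preds[preds["label"] != "unknown"]
        assert (known["label"] == "rest").mean() >= 0.95

    def test_empty_series_empty_output(self, trained):
        out = predict_series(trained, _logger(0))
        assert len(out) == 0

    def test_wrong_cadence_rejected(self, trained):
        log = _logger(100)
        log["time"] = pd.date_range("2008-01-01", periods=100, freq="5min", tz="UTC")
        with pytest.raises(ValueError):
            predict_series(trained, log)


class TestDailyProportions:
    @staticmethod
    def _preds(labels, start="2008-01-01T00:05Z"):
        times = pd.date_range(start, periods=len(labels), freq="10min", tz="UTC")
        return pd.DataFrame({"time": times, "label": labels})

    def test_all_flight_day(self):
        out = daily_proportions(self._preds(["flight"] * 144))
        assert out[["p_rest", "p_flight", "p_forage"]].iloc[0].tolist() == [0.0, 1.0, 0.0]

    def test_half_rest_half_forage(self):
        out = daily_proportions(self._preds(["rest"] * 72 + ["forage"] * 72))
        assert out["p_rest"].iloc[0] == 0.5
        assert out["p_forage"].iloc[0] == 0.5

    def test_mixed_day_counts(self):
        labels = ["rest"] * 36 + ["flight"] * 72 + ["forage"] * 36
        out = daily_proportions(self._preds(labels))
        assert out[["p_rest", "p_flight", "p_forage"]].iloc[0].tolist() == [0.25, 0.5, 0.25]

    def test_sparse_day_flagged_and_sums_to_one(self):
        labels = ["unknown"] * 100 + ["rest"] * 44
        out = daily_proportions(self._preds(labels))
        assert bool(out["flagged"].iloc[0])
        assert out[["p_rest", "p_flight", "p_forage"]].iloc[0].sum() == pytest.approx(1.0)
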