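"""Encoder-decoder forecaster: training, cross-validation, ensembling, persistence."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pytest

from graftcast.preprocess import DailySeries, ForecastConfig, make_windows
from graftcast.seq2seq import (
    EnsembleForecaster,
    ModelConfig,
    assign_folds,
    cross_validate,
    evaluate_ensemble,
    load_ensemble,
    save_ensemble,
    train_fold,
)

TINY = ModelConfig(hidden_size=8, max_epochs=20, early_stop_patience=5, seed=0)


def constant_windows(value=40.0, n_series=12, L=20, cfg=ForecastConfig(5, 5)):
    out = []
    for i in range(n_series):
        s = DailySeries(f"p{i}", 0, np.full(L, value), np.ones(L, dtype=bool))
        out.extend(make_windows(s, cfg))
    return out


@dataclass
class StubFold:
    """A fold stand-in emitting a fixed constant sequence (test double)."""

    constant: float
    forecast_config: ForecastConfig

    def predict(self, x):
        return np.full(self.forecast_config.output_len, self.constant)

    def predict_batch(self, X):
        return np.full((len(X), self.forecast_config.output_len), self.constant)


class TestTrainFold:
    def test_constant_cohort_learned(self):
        cfg = ForecastConfig(5, 5)
        windows = constant_windows(40.0, cfg=cfg)
        fm = train_fold(windows, TINY, cfg)
        pred = fm.predict(np.full(5, 40.0))
        assert np.all(np.abs(pred - 40.0) < 0.5)

    def test_same_seed_same_weights_digest(self, small_noisy_series):
        cfg = ForecastConfig(5, 5)
        windows = [w for s in small_noisy_series.values() for w in make_windows(s, cfg, stride=5)]
        f1 = train_fold(windows, replace(TINY, max_epochs=5), cfg)
        f2 = train_fold(windows, replace(TINY, max_epochs=5), cfg)
        assert f1.model.weights_digest() == f2.model.weights_digest()
        f3 = train_fold(windows, replace(TINY, max_epochs=5, seed=1), cfg)
        assert f3.model.weights_digest() != f1.model.weights_digest()

    def test_too_few_windows_rejected(self):
        cfg = ForecastConfig(5, 5)
        with pytest.raises(ValueError, match=">= 10 training windows"):
            train_fold(constant_windows(n_series=1, L=12, cfg=cfg)[:3], TINY, cfg)

    def test_scale_equivariance(self, small_noisy_series):
        """Affine rescaling of the eGFR unit applied to training data and the
        query input rescales predictions identically (z-scoring absorbs it)."""
        cfg = ForecastConfig(5, 5)
        windows = [w for s in small_noisy_series.values() for w in make_windows(s, cfg, stride=9)]
        a, b = 1.8, 7.0
        scaled = [
            type(w)(
                w.patient_id,
                w.input_start_day,
                a * w.input_values + b,
                a * w.target_values + b,
                w.target_observed_mask,
            )
            for w in windows
        ]
        f1 = train_fold(windows, replace(TINY, max_epochs=8), cfg)
        f2 = train_fold(scaled, replace(TINY, max_epochs=8), cfg)
        x = windows[0].input_values
        assert np.allclose(a * f1.predict(x) + b, f2.predict(a * x + b), atol=1e-3)


class TestFolds:
    def test_partition_law(self):
        pids = [f"p{i}" for i in range(23)]
        folds = assign_folds(pids, 5, seed=3)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(pids)          # union = cohort
        assert len(set(flat)) == len(flat)           # pairwise disjoint

    def test_seeded_determinism_and_order_invariance(self):
        pids = [f"p{i}" for i in range(17)]
        f1 = assign_folds(pids, 5, seed=9)
        f2 = assign_folds(list(reversed(pids)), 5, seed=9)
        assert f1 == f2
        assert assign_folds(pids, 5, seed=10) != f1

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], 5, seed=0)


class TestEnsemble:
    def _stub_ensemble(self, constants, cfg=ForecastConfig(3, 4)):
        return EnsembleForecaster([StubFold(c, cfg) for c in constants], cfg)

    def test_needs_exactly_five_folds(self):
        cfg = ForecastConfig(3, 4)
        with pytest.raises(ValueError, match="exactly 5"):
            EnsembleForecaster([StubFold(40, cfg)] * 4, cfg)

    def test_collapsed_ensemble_degenerate_quartiles(self):
        ens = self._stub_ensemble([40.0] * 5)
        c = ens.predict_candidates(np.full(3, 40.0))
        assert np.allclose(c.q1, 40) and np.allclose(c.median, 40) and np.allclose(c.q3, 40)

    def test_order_statistic_quartiles_and_mean(self):
        ens = self._stub_ensemble([30.0, 35.0, 40.0, 45.0, 50.0])
        c = ens.predict_candidates(np.full(3, 40.0))
        assert np.allclose(c.q1, 35) and np.allclose(c.median, 40) and np.allclose(c.q3, 45)
        assert np.allclose(c.mean_candidate, c.candidates.mean(axis=0))

    def test_perfect_oracle_zero_rmse(self, small_noisy_series):
        """An oracle that reproduces every target exactly scores RMSE 0."""
        cfg = ForecastConfig(5, 5)
        windows = [w for s in small_noisy_series.values() for w in make_windows(s, cfg, stride=11)]

        @dataclass
        class Oracle:
            forecast_config: ForecastConfig
            table: dict

            def predict_batch(self, X):
                return np.stack([self.table[x.tobytes()] for x in np.asarray(X)])

        table = {w.input_values.tobytes(): w.target_values for w in windows}
        ens = EnsembleForecaster([Oracle(cfg, table)] * 5, cfg)
        assert evaluate_ensemble(ens, windows)["ensemble_rmse"] == pytest.approx(0.0, abs=1e-12)


class TestCrossValidate:
    def test_cv_structure_and_determinism(self, small_noisy_series):
        cfg = ForecastConfig(5, 5)
        mc = replace(TINY, max_epochs=4)
        r1 = cross_validate(small_noisy_series, mc, cfg, train_stride=6, eval_stride=10)
        r2 = cross_validate(small_noisy_series, mc, cfg, train_stride=6, eval_stride=10)
        assert r1["folds"] == r2["folds"]
        assert r1["fold_rmse"] == r2["fold_rmse"]
        assert len(r1["ensemble"].folds) == 5
        assert r1["cv_rmse"] == pytest.approx(np.mean(r1["fold_rmse"]))

    def test_k_exceeding_patients_rejected(self, small_noisy_series):
        few = dict(list(small_noisy_series.items())[:3])
        with pytest.raises(ValueError):
            cross_validate(few, TINY, ForecastConfig(5, 5), k=5)


class TestPersistence:
    def _tiny_ensemble(self, small_noisy_series):
        return cross_validate(
            small_noisy_series, replace(TINY, max_epochs=3), ForecastConfig(5, 5),
            train_stride=8, eval_stride=20,
        )["ensemble"]

    def test_round_trip_probe_equality(self, small_noisy_series, tmp_path):
        ens = self._tiny_ensemble(small_noisy_series)
        save_ensemble(ens, tmp_path / "m")
        loaded = load_ensemble(tmp_path / "m")
        probe = np.array([42.0, 41.0, 39.5, 44.0, 43.0])
        a, b = ens.predict_candidates(probe), loaded.predict_candidates(probe)
        assert np.array_equal(a.candidates, b.candidates)
        for orig, back in zip(ens.folds, loaded.folds):
            assert orig.model.weights_digest() == back.model.weights_digest()

    def test_config_mismatch_rejected(self, small_noisy_series, tmp_path):
        ens = self._tiny_ensemble(small_noisy_series)
        save_ensemble(ens, tmp_path / "m")
        with pytest.raises(ValueError, match="requested config"):
            load_ensemble(tmp_path / "m", expected_config=ForecastConfig(30, 30))

    def test_missing_fold_file_named(self, small_noisy_series, tmp_path):
        ens = self._tiny_ensemble(small_noisy_series)
        save_ensemble(ens, tmp_path / "m")
        (tmp_path / "m" / "fold_2.npz").unlink()
        with pytest.raises(FileNotFoundError, match="fold 2"):
            load_ensemble(tmp_path / "m")
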