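"""Masked RMSE, quartile convention, config selection and the biopsy alarm."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pytest

from graftcast.alarm import (
    assess_biopsy,
    cohort_sensitivity,
    masked_rmse,
    quartiles5,
    select_config_by_input_length,
)
from graftcast.data_io import BiopsyEvent
from graftcast.preprocess import DailySeries, ForecastConfig


class TestMaskedRmse:
    def test_hand_example(self):
        got = masked_rmse([40, 50], [44, 47], [True, True])
        assert got == pytest.approx(np.sqrt((16 + 9) / 2))

    def test_mask_semantics(self, rng):
        actual = rng.uniform(20, 60, 8)
        predicted = actual.copy()
        mask = rng.random(8) < 0.5
        mask[0] = True
        predicted[~mask] = 999.0  # arbitrary on imputed days
        assert masked_rmse(predicted, actual, mask) == 0.0

    def test_single_observed_day(self):
        assert masked_rmse([40, 999], [44, 1], [True, False]) == pytest.approx(4.0)

    def test_no_observed_day_rejected(self):
        with pytest.raises(ValueError, match="no observed day"):
            masked_rmse([40.0], [44.0], [False])


class TestQuartiles5:
    def test_order_statistics(self):
        assert quartiles5([30, 35, 40, 45, 50]) == (35.0, 40.0, 45.0)

    def test_degenerate(self):
        assert quartiles5([40] * 5) == (40.0, 40.0, 40.0)

    def test_permutation_invariance_exhaustive(self):
        base = (12.0, 3.5, 99.0, 40.0, 41.0)
        expected = quartiles5(sorted(base))
        for perm in permutations(base):
            assert quartiles5(perm) == expected

    def test_matches_linear_interpolation_convention(self, rng):
        vals = rng.uniform(0, 100, 5)
        q1, med, q3 = quartiles5(vals)
        assert (q1, med, q3) == tuple(np.percentile(vals, [25, 50, 75], method="linear"))

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            quartiles5([1, 2, 3])


class TestSelectConfig:
    CONFIGS = [ForecastConfig(n, n) for n in (5, 15, 30, 45, 90)]

    @pytest.mark.parametrize("available,expected", [(20, 15), (37, 30), (90, 90), (2, 5)])
    def test_closest_input_length(self, available, expected):
        assert select_config_by_input_length(available, self.CONFIGS).input_len == expected

    def test_tie_breaks_to_smaller(self):
        configs = [ForecastConfig(5, 5), ForecastConfig(15, 15)]
        assert select_config_by_input_length(10, configs).input_len == 5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_config_by_input_length(10, [])


@dataclass
class StubEnsemble:
    """Emits fixed per-candidate constants at every forecast day."""

    constants: tuple
    config: ForecastConfig

    @property
    def forecast_config(self):
        return self.config

    def predict_candidates(self, x):
        out_len = self.config.output_len

        @dataclass
        class C:
            candidates: np.ndarray

        return C(np.tile(np.asarray(self.constants, dtype=float)[:, None], (1, out_len)))


def observed_series(values, observed_days=None):
    L = len(values)
    mask = np.ones(L, dtype=bool)
    if observed_days is not None:
        mask[:] = False
        mask[list(observed_days)] = True
    return DailySeries("p", 0, np.asarray(values, dtype=float), mask)


class TestAssessBiopsy:
    CFG = ForecastConfig(5, 15)

    def _ensembles(self, constants=(30, 35, 40, 45, 50)):
        return {self.CFG: StubEnsemble(tuple(constants), self.CFG)}

    def test_worsening_below_q1(self):
        series = observed_series(np.linspace(50, 34, 20))
        a = assess_biopsy(series, BiopsyEvent("p", 19), self._ensembles())
        assert a.assessable and a.config_used == self.CFG
        assert (a.predicted_q1, a.predicted_median, a.predicted_q3) == (35, 40, 45)
        assert a.actual_egfr == pytest.approx(34.0)
        assert a.deviation == pytest.approx(-1.0)
        assert a.worsening is True

    def test_boundary_not_worsening(self):
        vals = np.linspace(50, 40, 20)
        vals[-1] = 35.0  # exactly Q1
        a = assess_biopsy(observed_series(vals), BiopsyEvent("p", 19), self._ensembles())
        assert a.assessable and a.worsening is False and a.deviation == 0.0

    def test_first_five_days_not_assessable(self):
        a = assess_biopsy(observed_series(np.full(20, 40.0)), BiopsyEvent("p", 3), self._ensembles())
        assert not a.assessable and a.reason == "first 5 days"

    def test_unmeasured_biopsy_day_not_assessable(self):
        s = observed_series(np.full(20, 40.0), observed_days=range(0, 19))
        a = assess_biopsy(s, BiopsyEvent("p", 19), self._ensembles())
        assert not a.assessable and a.reason == "no measurement on biopsy day"

    def test_horizon_not_reachable(self):
        # sparse observations push the forecast offset beyond every output_len
        cfg = ForecastConfig(5, 5)
        s = observed_series(np.full(40, 40.0), observed_days=[0, 2, 4, 6, 8, 10, 39])
        a = assess_biopsy(s, BiopsyEvent("p", 39), {cfg: StubEnsemble((1, 2, 3, 4, 5), cfg)})
        assert not a.assessable and a.reason == "horizon"

    def test_excludes_last_four_measured_values(self):
        """The 4 withheld values are measured values, not grid days: with
        observations every 3 days the input must end 13 grid days before
        the biopsy (4 observations back), not 4 days before."""
        days = list(range(0, 19, 3))  # 0,3,...,18
        s = observed_series(np.full(20, 40.0), observed_days=days + [19])
        a = assess_biopsy(s, BiopsyEvent("p", 19), self._ensembles())
        # last retained observation: day 6 (dropping days 9,12,15,18)
        assert a.assessable
        # offset 13 still within output_len=15 of the stub config
        assert a.config_used == self.CFG

    def test_vacuous_exclusion_without_history(self):
        s = observed_series(np.full(20, 40.0), observed_days=[19])
        a = assess_biopsy(s, BiopsyEvent("p", 19), self._ensembles())
        assert not a.assessable and a.reason == "no history before biopsy"


class TestCohortSensitivity:
    def _assessment(self, deviation, assessable=True):
        from graftcast.alarm import AlarmAssessment

        return AlarmAssessment(
            "p", 10, assessable,
            deviation=deviation if assessable else None,
            worsening=(deviation < 0) if assessable else None,
        )

    def test_reported_fraction_arithmetic(self):
        # 478 worsening of 555 assessable -> 86.1%
        a = [self._assessment(-1.0)] * 478 + [self._assessment(2.0)] * 77
        s = cohort_sensitivity(a)
        assert s["sensitivity"] == pytest.approx(478 / 555)
        assert round(100 * s["sensitivity"], 1) == 86.1

    def test_all_worsening(self):
        s = cohort_sensitivity([self._assessment(-3.0)] * 4)
        assert s["sensitivity"] == 1.0

    def test_histogram_hand_count(self):
        s = cohort_sensitivity(
            [self._assessment(d) for d in (-5.0, -1.0, 2.0)], bin_width=5.0
        )
        assert s["sensitivity"] == pytest.approx(2 / 3)
        assert s["histogram"] == [(-5.0, 0.0, 2), (0.0, 5.0, 1)]

    def test_unassessable_counted_not_scored(self):
        s = cohort_sensitivity([self._assessment(-1.0), self._assessment(0.0, assessable=False)])
        assert s["assessable_count"] == 1 and s["unassessable_count"] == 1

    def test_zero_assessable_rejected(self):
        with pytest.raises(ValueError):
            cohort_sensitivity([self._assessment(0.0, assessable=False)])


class TestOracleNoFalseAlarm:
    def test_truth_predicting_ensemble_never_alarms_on_clean_trajectory(self):
        """When observations equal the latent truth and the forecaster
        predicts that truth exactly, 'below Q1' can never fire (strict)."""
        from graftcast.simulate import SyntheticConfig, generate_cohort
        from graftcast.preprocess import to_daily_series

        cfg = SyntheticConfig(
            n_patients=10, ar_sd=0.0, meas_cv=0.0, dgf_fraction=0.0,
            injury_rate_per_90d=0.0, seed=77,
        )
        cohort, truth = generate_cohort(cfg)
        series, _ = to_daily_series(cohort, 90)

        fc = ForecastConfig(5, 30)

        @dataclass
        class TruthEnsemble:
            latent: np.ndarray
            config: ForecastConfig

            def predict_candidates(self, x):
                # align on the last input value, then replay the truth
                start = int(np.argmin(np.abs(self.latent - x[-1]))) + 1

                @dataclass
                class C:
                    candidates: np.ndarray

                horizon = self.config.output_len
                path = self.latent[start : start + horizon]
                if path.size < horizon:
                    path = np.concatenate([path, np.full(horizon - path.size, self.latent[-1])])
                return C(np.tile(path, (5, 1)))

        n_assessed = 0
        for pid, s in series.items():
            ens = {fc: TruthEnsemble(truth.latent_series(pid), fc)}
            for day in (20, 40, 60):  # synthetic protocol-style biopsy days
                a = assess_biopsy(s, BiopsyEvent(pid, day), ens)
                if a.assessable:
                    n_assessed += 1
                    assert a.worsening is False
        assert n_assessed > 0
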