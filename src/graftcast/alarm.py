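"""Masked RMSE scoring and the biopsy-day worsening-graft-function alarm.

The forecasting ensemble emits five candidate eGFR sequences per query.
Their per-day median and quartiles form a patient-specific expected range;
a measured eGFR on the day of an indication biopsy that falls strictly
below the lower quartile (Q1) of the candidates is flagged as worsening
graft function. Cohort sensitivity is the fraction of assessable biopsies
flagged this way.

To mimic prospective use, the four most recent *measured* values before a
biopsy are withheld from the forecaster's input (they already carry the
deterioration that prompted the biopsy), the daily grid is rebuilt by LOCF
from the remaining observations, and the trained configuration whose input
length is closest to the available history is queried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BiopsyEvent
from .preprocess import DailySeries, ForecastConfig, locf_grid

__all__ = [
    "AlarmAssessment",
    "masked_rmse",
    "quartiles5",
    "select_config_by_input_length",
    "assess_biopsy",
    "cohort_sensitivity",
]


def masked_rmse(
    predicted: np.ndarray, actual: np.ndarray, observed_mask: np.ndarray
) -> float:
    """RMSE in mL/min/1.73 m², scored only on truly measured days.

    Imputed grid days carry no information about model accuracy, so the
    error pools squared deviations over mask-true days only. Raises if no
    day in the segment was observed (such segments are excluded and counted
    upstream).
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if predicted.shape != actual.shape or predicted.shape != observed_mask.shape:
        raise ValueError("predicted, actual and mask must have equal length")
    if not observed_mask.any():
        raise ValueError("no observed day in segment; masked RMSE undefined")
    diff = predicted[observed_mask] - actual[observed_mask]
    return float(np.sqrt(np.mean(diff**2)))


def quartiles5(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) of exactly five values.

    Uses the linear-interpolation quartile convention, which for five
    points is exactly the 2nd, 3rd and 4th order statistics — so the
    predicted range of a 5-model ensemble is fully auditable.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (5,):
        raise ValueError(f"quartiles5 needs exactly 5 values, got shape {values.shape}")
    s = np.sort(values)
    return float(s[1]), float(s[2]), float(s[3])


def select_config_by_input_length(
    available_input_days: int, configs
) -> ForecastConfig:
    """Pick the trained configuration whose input length best matches the history.

    Minimizes ``|input_len - available_input_days|``; ties break toward the
    smaller input length.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no trained configurations available")
    return min(
        configs,
        key=lambda c: (abs(c.input_len - available_input_days), c.input_len),
    )


@dataclass
class AlarmAssessment:
    """Outcome of comparing the biopsy-day measurement with the predicted range."""

    patient_id: str
    biopsy_day: int
    assessable: bool
    reason: str = ""
    actual_egfr: float | None = None
    predicted_median: float | None = None
    predicted_q1: float | None = None
    predicted_q3: float | None = None
    deviation: float | None = None  # actual - Q1, mL/min/1.73 m²
    worsening: bool | None = None
    config_used: ForecastConfig | None = None


#: Number of trailing measured values withheld before a biopsy.
N_EXCLUDED_PRE_BIOPSY = 4
#: Biopsies earlier than this day cannot be assessed (no usable history).
MIN_ASSESSABLE_DAY = 5


def assess_biopsy(
    series: DailySeries,
    biopsy: BiopsyEvent,
    ensembles: dict[ForecastConfig, object],
) -> AlarmAssessment:
    """Assess one indication biopsy against the ensemble's predicted range.

    Procedure: require a measured eGFR on the biopsy day and a biopsy day
    of at least 5; drop the last four measured values strictly before the
    biopsy and rebuild the grid by LOCF; measure the available history up
    to the last retained observation; among trained configurations whose
    output horizon reaches the biopsy-day offset, query the one with the
    closest input length; take (Q1, median, Q3) of the five candidate
    values at the biopsy-day offset; flag worsening when the measured
    value lies strictly below Q1.
    """
    pid, day = biopsy.patient_id, biopsy.day
    if day < MIN_ASSESSABLE_DAY:
        return AlarmAssessment(pid, day, False, reason="first 5 days")
    rel = day - series.start_day
    if rel < 0 or rel >= len(series):
        return AlarmAssessment(pid, day, False, reason="outside series horizon")
    if not series.observed_mask[rel]:
        return AlarmAssessment(pid, day, False, reason="no measurement on biopsy day")
    actual = float(series.values[rel])

    obs_idx = np.flatnonzero(series.observed_mask)
    before = obs_idx[obs_idx < rel]
    kept = before[:-N_EXCLUDED_PRE_BIOPSY] if N_EXCLUDED_PRE_BIOPSY else before
    if kept.size == 0:
        return AlarmAssessment(pid, day, False, reason="no history before biopsy")

    last_kept = int(kept[-1])
    truncated_len = last_kept + 1
    grid, _ = locf_grid(kept, series.values[kept], truncated_len)
    offset = rel - last_kept  # forecast day 1 = grid day last_kept + 1

    reachable = [c for c in ensembles if c.output_len >= offset]
    if not reachable:
        return AlarmAssessment(pid, day, False, reason="horizon")
    config = select_config_by_input_length(truncated_len, reachable)
    ens = ensembles[config]

    x = grid[-config.input_len :]
    if x.size < config.input_len:  # history shorter than input: back-fill with first value
        x = np.concatenate([np.full(config.input_len - x.size, grid[0]), x])
    cand = ens.predict_candidates(x)
    day_values = np.asarray(cand.candidates, dtype=float)[:, offset - 1]
    q1, med, q3 = quartiles5(day_values)
    deviation = actual - q1
    return AlarmAssessment(
        pid,
        day,
        True,
        actual_egfr=actual,
        predicted_median=med,
        predicted_q1=q1,
        predicted_q3=q3,
        deviation=deviation,
        worsening=bool(actual < q1),
        config_used=config,
    )


def cohort_sensitivity(
    assessments, bin_width: float = 5.0
) -> dict:
    """Fraction of assessable biopsies flagged as worsening, plus a deviation histogram.

    Returns a dict with ``sensitivity``, ``worsening_count``,
    ``assessable_count``, ``unassessable_count``, and ``histogram`` — a
    list of ``(bin_left, bin_right, count)`` rows over the deviations
    (actual minus Q1), mirroring how such alarm analyses are reported.
    """
    assessments = list(assessments)
    assessable = [a for a in assessments if a.assessable]
    if not assessable:
        raise ValueError("no assessable biopsy; sensitivity undefined")
    worsening = sum(1 for a in assessable if a.worsening)
    deviations = np.array([a.deviation for a in assessable], dtype=float)

    lo = np.floor(deviations.min() / bin_width) * bin_width
    hi = np.ceil(deviations.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(deviations, bins=edges)
    histogram = [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(len(counts))
    ]
    return {
        "sensitivity": worsening / len(assessable),
        "worsening_count": worsening,
        "assessable_count": len(assessable),
        "unassessable_count": len(assessments) - len(assessable),
        "histogram": histogram,
    }
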