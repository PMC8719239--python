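"""Daily eGFR grids via last-observation-carried-forward, and window cutting.

Laboratory visits are irregular: daily while the recipient is hospitalized,
then thinning out. The forecasting models consume one value per day, so
each patient's measurements are placed on a day grid and unmeasured days
are imputed by carrying the last observation forward (LOCF). Days before
the first observation are back-filled from that first observation — the
inclusion rule guarantees a measurement within the first 5 days, so the
back-filled stretch is at most 4 days. An ``observed_mask`` records which
grid days carry a real measurement; evaluation metrics only ever score
observed days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Cohort

__all__ = [
    "DailySeries",
    "ForecastConfig",
    "WindowPair",
    "Normalizer",
    "to_daily_series",
    "locf_grid",
    "make_windows",
    "fit_normalizer",
    "TABLE_PRESETS",
]


@dataclass(frozen=True)
class ForecastConfig:
    """Input/output lengths (days) of a forecasting configuration."""

    input_len: int
    output_len: int

    def __post_init__(self) -> None:
        if self.input_len < 1 or self.output_len < 1:
            raise ValueError("input_len and output_len must be >= 1")

    def __str__(self) -> str:  # e.g. "5x15"
        return f"{self.input_len}x{self.output_len}"


#: The configuration lattice evaluated in the first 3 months post transplant.
TABLE_PRESETS: tuple[ForecastConfig, ...] = (
    ForecastConfig(5, 5),
    ForecastConfig(5, 15),
    ForecastConfig(30, 30),
    ForecastConfig(45, 45),
    ForecastConfig(90, 90),
)


@dataclass
class DailySeries:
    """Complete daily eGFR series for one patient with an observed/imputed mask."""

    patient_id: str
    start_day: int
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask must have equal length")
        if self.values.size and not np.all(self.values > 0):
            raise ValueError(f"{self.patient_id}: eGFR values must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def observed_days(self) -> np.ndarray:
        """Absolute day indices carrying a real measurement."""
        return self.start_day + np.flatnonzero(self.observed_mask)


@dataclass(frozen=True)
class WindowPair:
    """A contiguous (input, target) pair cut from a daily series.

    ``target_values`` immediately follow ``input_values`` in time; the
    target mask flags which target days were actually measured.
    """

    patient_id: str
    input_start_day: int
    input_values: np.ndarray
    target_values: np.ndarray
    target_observed_mask: np.ndarray


def locf_grid(
    days: np.ndarray, values: np.ndarray, horizon_days: int
) -> tuple[np.ndarray, np.ndarray]:
    """Place (day, value) observations on a 0..horizon-1 grid with LOCF.

    Unobserved days take the nearest preceding observed value; days before
    the first observation take the first observed value (back-fill).
    Returns ``(grid_values, observed_mask)``.
    """
    days = np.asarray(days, dtype=int)
    values = np.asarray(values, dtype=float)
    if days.size == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(days, kind="stable")
    days, values = days[order], values[order]

    grid = np.empty(horizon_days, dtype=float)
    mask = np.zeros(horizon_days, dtype=bool)
    in_range = days < horizon_days
    for d, v in zip(days[in_range], values[in_range]):
        grid[d] = v
        mask[d] = True

    obs_idx = np.flatnonzero(mask)
    if obs_idx.size == 0:
        raise ValueError("no observation within the horizon")
    # back-fill before the first observation, then carry forward
    grid[: obs_idx[0]] = grid[obs_idx[0]]
    last = grid[obs_idx[0]]
    for d in range(obs_idx[0], horizon_days):
        if mask[d]:
            last = grid[d]
        else:
            grid[d] = last
    return grid, mask


def to_daily_series(
    cohort: Cohort, horizon_days: int = 90
) -> tuple[dict[str, DailySeries], list[tuple[str, str]]]:
    """Build one complete daily series per included patient.

    Patients with no measurement within the first 5 days post transplant
    are excluded (they lack the anchoring early observations), as are
    patients with no measurement inside the horizon at all. Multiple
    measurements on one day are averaged before gridding.

    Returns ``(series_by_patient, exclusions)`` where each exclusion is a
    ``(patient_id, reason)`` pair.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    series: dict[str, DailySeries] = {}
    exclusions: list[tuple[str, str]] = []
    meas_by_patient: dict[str, list] = {p.patient_id: [] for p in cohort.patients}
    for m in cohort.measurements:
        meas_by_patient[m.patient_id].append(m)

    for pid in cohort.patient_ids:
        ms = [m for m in meas_by_patient[pid] if m.egfr is not None]
        if not ms:
            exclusions.append((pid, "no eGFR measurements"))
            continue
        if min(m.day for m in ms) > 4:
            exclusions.append((pid, "no eGFR within first 5 days"))
            continue
        by_day: dict[int, list[float]] = {}
        for m in ms:
            if m.day < horizon_days:
                by_day.setdefault(m.day, []).append(m.egfr)
        if not by_day:
            exclusions.append((pid, "no eGFR within horizon"))
            continue
        days = np.array(sorted(by_day), dtype=int)
        vals = np.array([float(np.mean(by_day[d])) for d in days])
        grid, mask = locf_grid(days, vals, horizon_days)
        series[pid] = DailySeries(pid, 0, grid, mask)
    return series, exclusions


def write_exclusion_report(exclusions: list[tuple[str, str]], path) -> None:
    import pandas as pd

    pd.DataFrame(exclusions, columns=["patient_id", "reason"]).to_csv(path, index=False)


def make_windows(
    series: DailySeries, config: ForecastConfig, stride: int = 1
) -> list[WindowPair]:
    """Cut sliding (input, target) pairs from a daily series.

    Windows advance by ``stride`` days; a series shorter than
    ``input_len + output_len`` yields an empty list. The count equals
    ``floor((L - input_len - output_len)/stride) + 1`` when non-negative.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    L = len(series)
    total = config.input_len + config.output_len
    out: list[WindowPair] = []
    for start in range(0, L - total + 1, stride):
        mid = start + config.input_len
        end = mid + config.output_len
        out.append(
            WindowPair(
                patient_id=series.patient_id,
                input_start_day=series.start_day + start,
                input_values=series.values[start:mid].copy(),
                target_values=series.values[mid:end].copy(),
                target_observed_mask=series.observed_mask[mid:end].copy(),
            )
        )
    return out


@dataclass
class Normalizer:
    """Z-scaling fitted on training-fold input values only."""

    mean: float
    std: float
    shift_only: bool = False

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shift_only:
            return x - self.mean
        return (x - self.mean) / self.std

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.shift_only:
            return z + self.mean
        return z * self.std + self.mean

    def to_dict(self) -> dict:
        return {"mean": float(self.mean), "std": float(self.std), "shift_only": bool(self.shift_only)}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(mean=float(d["mean"]), std=float(d["std"]), shift_only=bool(d["shift_only"]))


def fit_normalizer(windows: list[WindowPair]) -> Normalizer:
    """Fit z-scaling statistics from the input values of training windows.

    A zero-variance training set (e.g. a constant cohort) falls back to a
    shift-only transform with a warning.
    """
    if not windows:
        raise ValueError("need at least one training window")
    vals = np.concatenate([w.input_values for w in windows])
    mean = float(vals.mean())
    std = float(vals.std())
    if std < 1e-12:
        import warnings

        warnings.warn("zero variance in training inputs; falling back to shift-only scaling")
        return Normalizer(mean=mean, std=1.0, shift_only=True)
    return Normalizer(mean=mean, std=std)
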