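"""ARIMA multistep out-of-sample forecasting benchmark.

For every evaluation window an ARIMA model is fitted on the input segment
alone and asked for an h-step-ahead forecast covering the output segment
(model-based multistep prediction, not refit-per-step). Orders are either
fixed or chosen by AIC over a small grid. Series too short or fits that
fail to converge fall back to the random-walk forecast ARIMA(0,1,0) —
the last observed value carried forward — with a logged warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .alarm import masked_rmse
from .preprocess import DailySeries, ForecastConfig, WindowPair, make_windows

logger = logging.getLogger(__name__)

__all__ = ["ArimaSpec", "arima_forecast", "evaluate_arima"]

#: AIC-search grid (p, d, q ranges) used in auto mode.
AIC_GRID = [(p, d, q) for p in range(4) for d in range(2) for q in range(3)]


@dataclass(frozen=True)
class ArimaSpec:
    """ARIMA order specification; ``aic_grid`` searches p 0-3, d 0-1, q 0-2."""

    p: int = 1
    d: int = 1
    q: int = 0
    selection_mode: str = "aic_grid"  # or "fixed"

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if self.p > 5 or self.q > 5 or self.d > 2:
            raise ValueError("order out of supported range (p,q <= 5, d <= 2)")
        if self.selection_mode not in {"fixed", "aic_grid"}:
            raise ValueError("selection_mode must be 'fixed' or 'aic_grid'")


def _fit_forecast(y: np.ndarray, order: tuple[int, int, int], h: int) -> tuple[np.ndarray, float]:
    """Fit one ARIMA order and forecast h steps; returns (forecast, aic)."""
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(
            y,
            order=order,
            enforce_stationarity=True,
            enforce_invertibility=True,
            concentrate_scale=True,
        )
        res = model.fit(method_kwargs={"maxiter": 50})
        fc = np.asarray(res.forecast(steps=h), dtype=float)
    if not np.all(np.isfinite(fc)):
        raise ValueError("non-finite forecast")
    return fc, float(res.aic)


def _random_walk_forecast(y: np.ndarray, h: int) -> np.ndarray:
    return np.full(h, float(y[-1]))


def _feasible(order: tuple[int, int, int], n: int) -> bool:
    p, d, q = order
    return n >= max(p + d, q + d) + 2


def arima_forecast(
    input_values: np.ndarray, h: int, spec: ArimaSpec = ArimaSpec()
) -> np.ndarray:
    """Multistep out-of-sample forecast of ``h`` days from the input segment.

    Deterministic given inputs and spec. In ``aic_grid`` mode the forecast
    of the minimum-AIC fit over the feasible grid is returned; a degenerate
    (constant) input or an all-orders failure falls back to the
    random-walk forecast.
    """
    y = np.asarray(input_values, dtype=float)
    if h < 1:
        raise ValueError("h must be >= 1")
    if y.ndim != 1 or y.size < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    if np.ptp(y) < 1e-12:  # constant input: every ARIMA reduces to the constant
        return np.full(h, float(y[-1]))

    if spec.selection_mode == "fixed":
        order = (spec.p, spec.d, spec.q)
        if order == (0, 1, 0):
            return _random_walk_forecast(y, h)
        if not _feasible(order, y.size):
            raise ValueError(f"input length {y.size} too short for order {order}")
        try:
            fc, _ = _fit_forecast(y, order, h)
            return fc
        except Exception as exc:  # noqa: BLE001 - statsmodels raises many types
            logger.warning("ARIMA%s failed (%s); falling back to random walk", order, exc)
            return _random_walk_forecast(y, h)

    result = aic_grid_search(y, h)
    if result is None:
        logger.warning("all ARIMA grid fits failed; falling back to random walk")
        return _random_walk_forecast(y, h)
    return result["forecast"]


def aic_grid_search(y: np.ndarray, h: int) -> dict | None:
    """Minimum-AIC fit over the feasible grid; None when every fit fails.

    Returns ``{"order", "aic", "forecast"}`` of the winning fit.
    """
    y = np.asarray(y, dtype=float)
    best: dict | None = None
    for order in AIC_GRID:
        if not _feasible(order, y.size):
            continue
        try:
            fc, aic = _fit_forecast(y, order, h)
        except Exception:  # noqa: BLE001
            continue
        if best is None or aic < best["aic"]:
            best = {"order": order, "aic": aic, "forecast": fc}
    return best


def evaluate_arima(
    series_by_patient: dict[str, DailySeries],
    config: ForecastConfig,
    spec: ArimaSpec = ArimaSpec(),
    *,
    stride: int = 1,
    max_windows: int | None = None,
    rng_seed: int = 0,
    windows: list[WindowPair] | None = None,
) -> dict:
    """Pooled masked RMSE of per-window ARIMA forecasts over a cohort.

    Each window's model is fitted on its input segment only and scored on
    the measured days of its output segment. A precomputed ``windows``
    list (shared with the sequence model for a like-for-like benchmark)
    may be passed; otherwise windows are cut at ``stride``, optionally
    subsampled to ``max_windows`` with a seeded choice.
    """
    if windows is None:
        windows = []
        for s in series_by_patient.values():
            windows.extend(make_windows(s, config, stride=stride))
    windows = [w for w in windows if w.target_observed_mask.any()]
    if not windows:
        raise ValueError("no evaluable window (no observed target days)")
    if max_windows is not None and len(windows) > max_windows:
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(windows), size=max_windows, replace=False)
        windows = [windows[i] for i in sorted(idx)]

    sq_sum = 0.0
    n_obs = 0
    per_window: list[float] = []
    for w in windows:
        fc = arima_forecast(w.input_values, config.output_len, spec)
        mask = w.target_observed_mask
        diff = fc[mask] - w.target_values[mask]
        sq_sum += float(np.sum(diff**2))
        n_obs += int(mask.sum())
        per_window.append(masked_rmse(fc, w.target_values, mask))
    return {
        "rmse": float(np.sqrt(sq_sum / n_obs)),
        "n_windows": len(windows),
        "n_observed_days": n_obs,
        "per_window_rmse": per_window,
    }
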