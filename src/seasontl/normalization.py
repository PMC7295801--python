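"""Outcome and predictor normalization.

Raw T/S ratios carry a plate batch effect (different plates measure on
different scales), so the analysis outcome is a per-plate z-score of T/S.
This module provides the batch-effect ANOVA check, the per-plate z-score
transform, a Box-Cox power transform with profile-likelihood lambda
selection (used when the z-score distribution is skewed), and the natural
log transform applied to skewed predictors such as maternal BMI and
maternal folate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizationError",
    "per_plate_zscore",
    "plate_batch_anova",
    "boxcox",
    "log_transform_predictors",
    "normalize_ltl",
]

BOXCOX_GRID = np.arange(-2.0, 2.0 + 1e-9, 1e-3)
#: Shifted minimum used when Box-Cox is applied to values that are not
#: strictly positive (z-scores): min(x) + shift = BOXCOX_MIN_POSITIVE.
BOXCOX_MIN_POSITIVE = 0.01


class NormalizationError(ValueError):
    pass


def per_plate_zscore(ts: pd.DataFrame, min_plate_size: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize T/S ratios within each plate.

    Parameters
    ----------
    ts
        Table with columns ``sample_id``, ``plate_id``, ``ts_ratio``
        (QC-passed samples only).
    min_plate_size
        Plates with fewer samples than this, or with zero T/S standard
        deviation, cannot support a z-score; their samples are excluded.

    Returns
    -------
    (normalized, excluded)
        ``normalized`` has columns sample_id, plate_id, ltl_z with, per
        plate, mean 0 and sample sd 1; ``excluded`` lists dropped samples
        with a ``reason`` column.
    """
    required = {"sample_id", "plate_id", "ts_ratio"}
    if not required.issubset(ts.columns):
        raise NormalizationError(f"input must have columns {sorted(required)}")

    out_rows, excl_rows = [], []
    for plate_id, grp in ts.groupby("plate_id", sort=True):
        vals = grp["ts_ratio"].to_numpy(dtype=float)
        if len(vals) < min_plate_size:
            reason = f"plate has {len(vals)} samples (< {min_plate_size})"
        elif np.std(vals, ddof=1) == 0:
            reason = "zero T/S standard deviation on plate"
        else:
            z = (vals - vals.mean()) / np.std(vals, ddof=1)
            out_rows.append(
                pd.DataFrame(
                    {"sample_id": grp["sample_id"].values, "plate_id": plate_id, "ltl_z": z}
                )
            )
            continue
        excl_rows.append(
            pd.DataFrame(
                {"sample_id": grp["sample_id"].values, "plate_id": plate_id, "reason": reason}
            )
        )
    normalized = (
        pd.concat(out_rows, ignore_index=True)
        if out_rows
        else pd.DataFrame(columns=["sample_id", "plate_id", "ltl_z"])
    )
    excluded = (
        pd.concat(excl_rows, ignore_index=True)
        if excl_rows
        else pd.DataFrame(columns=["sample_id", "plate_id", "reason"])
    )
    return normalized, excluded


def plate_batch_anova(ts: pd.DataFrame, value_col: str = "ts_ratio") -> tuple[float, float]:
    """One-way ANOVA of a value across plates (the batch-effect check).

    Returns (F, p). Requires at least two plates with >= 2 samples each.
    """
    groups = [
        g[value_col].to_numpy(dtype=float)
        for _, g in ts.groupby("plate_id")
        if len(g) >= 2
    ]
    if len(groups) < 2:
        raise NormalizationError("ANOVA requires >= 2 plates with >= 2 samples each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _boxcox_profile_loglik(x: np.ndarray, lmbda: float) -> float:
    if lmbda == 0:
        y = np.log(x)
    else:
        y = (x**lmbda - 1.0) / lmbda
    var = np.var(y)  # MLE variance
    if var <= 0:
        return -np.inf
    n = len(x)
    return float(-n / 2.0 * np.log(var) + (lmbda - 1.0) * np.sum(np.log(x)))


def boxcox(
    values, lmbda: float | None = None, grid: np.ndarray = BOXCOX_GRID
) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform with optional profile-likelihood lambda.

    ``y = ((x + shift)**lambda - 1)/lambda`` (log for lambda = 0). When any
    value is <= 0 a shift is chosen so the minimum maps to
    ``BOXCOX_MIN_POSITIVE``; the shift is returned so the transform is
    reproducible. When ``lmbda`` is None it is chosen by maximizing the
    profile log-likelihood over a fixed grid (default -2..2, step 1e-3),
    which makes the estimate deterministic.

    Returns (transformed, lambda_hat, shift).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise NormalizationError("Box-Cox input must be finite")
    shift = 0.0
    if x.min() <= 0:
        shift = BOXCOX_MIN_POSITIVE - x.min()
    xs = x + shift

    if lmbda is None:
        logliks = np.array([_boxcox_profile_loglik(xs, l) for l in grid])
        lmbda = float(grid[int(np.argmax(logliks))])
    if lmbda == 0:
        y = np.log(xs)
    else:
        # expm1 form stays accurate as lambda -> 0
        y = np.expm1(lmbda * np.log(xs)) / lmbda
    return y, float(lmbda), float(shift)


def log_transform_predictors(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Natural-log transform skewed predictor columns.

    Adds ``log_<name>`` columns; missing values pass through. A
    non-positive value is an error naming the row and column.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise NormalizationError(f"unknown predictor column {col!r}")
        vals = out[col]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            idx = out.index[bad][0]
            raise NormalizationError(
                f"non-positive value in column {col!r} at row {idx}: {vals.loc[idx]}"
            )
        out[f"log_{col}"] = np.log(vals.astype(float))
    return out


def normalize_ltl(
    ts: pd.DataFrame,
    apply_boxcox: bool = False,
    boxcox_order: str = "z_then_boxcox",
    min_plate_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full outcome normalization: per-plate z-score, optional Box-Cox.

    ``boxcox_order`` selects the dialect:

    * ``"z_then_boxcox"`` (default): per-plate z-scores, then a shifted
      Box-Cox of the z-scores, then an overall re-standardization so the
      outcome stays in z-score units.
    * ``"boxcox_then_z"``: Box-Cox of the raw (positive) T/S ratios, then
      per-plate z-scores.

    Returns (normalized, excluded, params) where ``params`` records the
    transform applied (lambda, shift) for the reproducibility sidecar.
    """
    params: dict = {"transform": "none", "boxcox_lambda": None, "boxcox_shift": None}
    if not apply_boxcox:
        normalized, excluded = per_plate_zscore(ts, min_plate_size)
        return normalized, excluded, params

    if boxcox_order == "z_then_boxcox":
        normalized, excluded = per_plate_zscore(ts, min_plate_size)
        y, lam, shift = boxcox(normalized["ltl_z"].to_numpy())
        y = (y - y.mean()) / np.std(y, ddof=1)  # keep z-score units
        normalized = normalized.assign(ltl_z=y)
    elif boxcox_order == "boxcox_then_z":
        y, lam, shift = boxcox(ts["ts_ratio"].to_numpy())
        ts2 = ts.assign(ts_ratio=y)
        normalized, excluded = per_plate_zscore(ts2, min_plate_size)
    else:
        raise NormalizationError(f"unknown boxcox_order {boxcox_order!r}")
    params.update(transform="boxcox", boxcox_lambda=lam, boxcox_shift=shift,
                  boxcox_order=boxcox_order)
    return normalized, excluded, params
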