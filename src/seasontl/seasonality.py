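"""Fourier (cosinor) seasonal regression of telomere length on date of conception.

The model is an ordinary Gaussian linear model in which seasonality is a
linear combination of sine/cosine pairs of the conception date's position
in the year:

    ltl_z_i = b0 + sum_{j=1..k} [ a_j sin(j t_i) + b_j cos(j t_i) ]
              + covariates' g + e_i,        e_i ~ N(0, s^2)

where t_i = 2 pi (day_of_year_i - 1) / days_in_year_i. One pair (k = 1)
gives a pure cosinor: amplitude 2 sqrt(a^2 + b^2) and free phase. Seasonal
significance is a likelihood-ratio test of the model with the Fourier pair
against the same model without it (2 degrees of freedom per pair), using
Gaussian maximum-likelihood log-likelihoods (sigma^2 = RSS/n). The
season-effect size is reported the way field studies report it: the
maximum minus the minimum of the fitted seasonal mean curve over a daily
grid, with the peak/nadir calendar dates, and a case-resampling bootstrap
for their uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GRID_DAYS",
    "conception_angle",
    "conception_angles",
    "fourier_basis",
    "build_design",
    "fit_gaussian_lm",
    "likelihood_ratio_test",
    "select_harmonics",
    "fit_seasonal_model",
    "seasonal_summary",
    "bootstrap_amplitude_ci",
    "covariate_effect_models",
    "ModelFit",
    "LrtResult",
    "SeasonalDesign",
    "SeasonalModel",
    "SeasonalSummary",
    "HarmonicSelection",
    "BootstrapResult",
    "RankDeficiencyError",
    "DesignError",
    "circular_day_difference",
]

#: Number of grid points for the fitted seasonal curve (covers leap years).
GRID_DAYS = 366

_Z975 = stats.norm.ppf(0.975)


class DesignError(ValueError):
    pass


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message names the offending columns."""


# ---------------------------------------------------------------------------
# angles and bases


def conception_angle(date, convention: str = "actual_year") -> float:
    """Angle of a calendar date within its year, in [0, 2 pi).

    ``theta = 2 pi (doy - 1) / D`` with doy the 1-based day of year and D
    the number of days in that year (365/366). ``convention="fixed_365_25"``
    divides by 365.25 instead, for sensitivity runs.
    """
    return float(conception_angles([date], convention=convention)[0])


def conception_angles(dates, convention: str = "actual_year") -> np.ndarray:
    """Vectorized :func:`conception_angle` over a date array."""
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(dates))
    except (ValueError, TypeError) as e:
        raise DesignError(f"invalid conception date: {e}") from e
    if idx.isna().any():
        raise DesignError("invalid (unparseable or missing) conception date")
    doy = idx.dayofyear.to_numpy(dtype=float)
    if convention == "actual_year":
        dlen = np.where(idx.is_leap_year, 366.0, 365.0)
    elif convention == "fixed_365_25":
        dlen = 365.25
    else:
        raise DesignError(f"unknown angle convention {convention!r}")
    return 2.0 * np.pi * (doy - 1.0) / dlen


def fourier_basis(theta: np.ndarray, k: int) -> np.ndarray:
    """Columns sin(j theta), cos(j theta) for j = 1..k (2k columns)."""
    if k < 0:
        raise DesignError("k must be >= 0")
    theta = np.asarray(theta, dtype=float)
    cols = []
    for j in range(1, k + 1):
        cols.append(np.sin(j * theta))
        cols.append(np.cos(j * theta))
    if not cols:
        return np.empty((len(theta), 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class SeasonalDesign:
    """A realized design: response, matrix, and metadata for prediction."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    k: int
    theta: np.ndarray
    n_dropped: int
    #: covariate columns' reference values (means for continuous covariates,
    #: 0 for dummy indicators), used to evaluate the fitted seasonal curve.
    reference_values: np.ndarray
    index: np.ndarray  # row labels of retained records


def _expand_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in covariates:
        if cov not in df.columns:
            raise DesignError(f"unknown covariate {cov!r}")
        s = df[cov]
        if s.dtype.kind in "ifu" and not isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(pd.unique(s.dropna().astype(str)))
            if len(levels) < 2:
                raise DesignError(f"categorical covariate {cov!r} has < 2 levels")
            # reference coding, reference = first level alphabetically
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(df), 0)), names


def build_design(
    records: pd.DataFrame,
    k: int,
    covariates: Sequence[str] = (),
    outcome: str = "ltl_z",
    date_col: str = "conception_date",
    convention: str = "actual_year",
) -> SeasonalDesign:
    """Build the regression design for a seasonal model.

    Rows with a missing outcome, date, or any requested covariate are
    dropped (complete-case analysis; the drop count is recorded). Columns:
    intercept, 2k Fourier columns, then covariates with categorical ones
    reference-coded (reference level = first alphabetically).
    """
    needed = [outcome, date_col] + [c for c in covariates]
    for c in needed:
        if c not in records.columns:
            raise DesignError(f"column {c!r} not in phenotype table")
    mask = records[needed].notna().all(axis=1)
    df = records.loc[mask]
    n_dropped = int((~mask).sum())
    if len(df) == 0:
        raise DesignError("zero complete cases for the requested model")

    theta = conception_angles(df[date_col], convention=convention)
    fb = fourier_basis(theta, k)
    fb_names = [f"{fn}{j}" for j in range(1, k + 1) for fn in ("sin", "cos")]
    cov_mat, cov_names = _expand_covariates(df, covariates)

    X = np.column_stack([np.ones(len(df)), fb, cov_mat])
    columns = ["const"] + fb_names + cov_names
    ref = np.array(
        [
            cov_mat[:, i].mean() if "[" not in name else 0.0
            for i, name in enumerate(cov_names)
        ]
    )
    return SeasonalDesign(
        y=df[outcome].to_numpy(dtype=float),
        X=X,
        columns=columns,
        k=k,
        theta=theta,
        n_dropped=n_dropped,
        reference_values=ref,
        index=df.index.to_numpy(),
    )


# ---------------------------------------------------------------------------
# Gaussian linear model + LRT


@dataclass
class ModelFit:
    """A fitted Gaussian linear model.

    ``loglik`` is the maximized Gaussian log-likelihood with
    sigma2_mle = RSS/n, i.e. -(n/2)(log(2 pi sigma2_mle) + 1);
    ``covariance`` uses the unbiased residual variance RSS/(n-p).
    ``degenerate`` flags an exact (RSS = 0) fit, whose log-likelihood is
    unbounded.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    sigma2_mle: float
    loglik: float
    n: int
    p: int
    rss: float
    columns: list[str] = field(default_factory=list)
    design_description: str = ""
    degenerate: bool = False


def _name_collinear_columns(X: np.ndarray, columns: Sequence[str]) -> list[str]:
    # rank-revealing QR with column pivoting: trailing pivots are dependent
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    dependent = sorted(piv[rank:])
    return [columns[i] if columns else str(i) for i in dependent]


def fit_gaussian_lm(
    y: np.ndarray, X: np.ndarray, columns: Sequence[str] | None = None,
    design_description: str = "",
) -> ModelFit:
    """Ordinary least squares with Gaussian MLE log-likelihood.

    Uses a QR-based least-squares solve. Raises
    :class:`RankDeficiencyError` naming collinear columns when X is not of
    full column rank, and :class:`DesignError` when n <= p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need n > p, got n={n}, p={p}")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        bad = _name_collinear_columns(X, list(columns) if columns else [])
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    # an RSS at round-off scale relative to the response is an exact fit
    degenerate = rss <= 1e-24 * max(1.0, float(y @ y))
    if degenerate:
        loglik = math.inf
        cov = np.zeros((p, p))
    else:
        loglik = -(n / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = rss / (n - p) * xtx_inv
    return ModelFit(
        coefficients=beta,
        covariance=cov,
        sigma2_mle=sigma2,
        loglik=loglik,
        n=n,
        p=p,
        rss=rss,
        columns=list(columns) if columns is not None else [],
        design_description=design_description,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p_value: float


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> LrtResult:
    """Likelihood ratio test of nested Gaussian linear models.

    chi2 = 2 (loglik_full - loglik_reduced), df = p_full - p_reduced,
    p-value from the chi-square upper tail. Both fits must use the same
    response rows (identical n); the adjusted models therefore require
    complete-case alignment before fitting.
    """
    if full.n != reduced.n:
        raise DesignError(
            f"LRT requires identical samples: full n={full.n}, reduced n={reduced.n}"
        )
    df = full.p - reduced.p
    if df < 0:
        raise DesignError("'full' model has fewer parameters than 'reduced'")
    if df == 0:
        return LrtResult(chi2=0.0, df=0, p_value=1.0)
    if full.degenerate and not reduced.degenerate:
        return LrtResult(chi2=math.inf, df=df, p_value=0.0)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df))
    return LrtResult(chi2=float(chi2), df=df, p_value=p)


# ---------------------------------------------------------------------------
# seasonal model driver


@dataclass
class SeasonalModel:
    """A seasonal regression fit together with its design metadata."""

    fit: ModelFit
    design: SeasonalDesign
    covariates: tuple[str, ...]
    outcome: str


def fit_seasonal_model(
    records: pd.DataFrame,
    k: int = 1,
    covariates: Sequence[str] = (),
    outcome: str = "ltl_z",
    convention: str = "actual_year",
) -> SeasonalModel:
    """Fit ``outcome ~ Fourier(k) + covariates`` on complete cases."""
    design = build_design(records, k, covariates, outcome=outcome, convention=convention)
    desc = f"{outcome} ~ Fourier(k={k})" + ("" if not covariates else " + " + " + ".join(covariates))
    fit = fit_gaussian_lm(design.y, design.X, design.columns, design_description=desc)
    return SeasonalModel(fit=fit, design=design, covariates=tuple(covariates), outcome=outcome)


def seasonal_lrt(
    records: pd.DataFrame,
    k: int = 1,
    covariates: Sequence[str] = (),
    outcome: str = "ltl_z",
    convention: str = "actual_year",
) -> tuple[SeasonalModel, SeasonalModel, LrtResult]:
    """Fit the k-pair seasonal model and its no-seasonality baseline on the
    same complete cases and run the LRT (2k degrees of freedom)."""
    full = fit_seasonal_model(records, k, covariates, outcome, convention)
    # restrict the baseline to exactly the same rows
    sub = records.loc[full.design.index]
    reduced = fit_seasonal_model(sub, 0, covariates, outcome, convention)
    return full, reduced, likelihood_ratio_test(full.fit, reduced.fit)


@dataclass
class HarmonicSelection:
    k: int
    #: list of (k_reduced, k_full, LrtResult); the first entry tests the
    #: minimal basis (k=1) against the covariate-only baseline.
    tests: list[tuple[int, int, LrtResult]]


def select_harmonics(
    records: pd.DataFrame,
    covariates: Sequence[str] = (),
    k_max: int = 3,
    alpha: float = 0.05,
    outcome: str = "ltl_z",
    convention: str = "actual_year",
) -> HarmonicSelection:
    """Choose the number of Fourier pairs by sequential forward LRTs.

    Starting from k=1, adds a pair while the 2-df LRT for the added pair is
    significant at ``alpha``; returns the smallest k whose successor pair
    is not significant. Selection never goes below k=1 (the significance
    of k=1 itself against the baseline is recorded in the trail but judged
    separately by the caller).
    """
    if k_max < 1:
        raise DesignError("k_max must be >= 1")
    fits: dict[int, ModelFit] = {}
    design0 = build_design(records, 0, covariates, outcome=outcome, convention=convention)
    rows = design0.index
    sub = records.loc[rows]
    for k in range(0, k_max + 1):
        m = fit_seasonal_model(sub, k, covariates, outcome, convention)
        fits[k] = m.fit
    tests = [(0, 1, likelihood_ratio_test(fits[1], fits[0]))]
    chosen = 1
    for k in range(1, k_max):
        lrt = likelihood_ratio_test(fits[k + 1], fits[k])
        tests.append((k, k + 1, lrt))
        if lrt.p_value < alpha:
            chosen = k + 1
        else:
            break
    return HarmonicSelection(k=chosen, tests=tests)


# ---------------------------------------------------------------------------
# amplitude / phase summaries


@dataclass
class SeasonalSummary:
    """Fitted seasonal mean curve on a daily grid and its shape summary.

    ``amplitude`` is the curve maximum minus minimum (z-score units);
    ``peak_day``/``nadir_day`` are 1-based day-of-year positions of the
    extremes. The confidence band is pointwise Wald, from the coefficient
    covariance.
    """

    amplitude: float
    peak_day: int
    nadir_day: int
    days: np.ndarray
    curve: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def _grid_design(model: SeasonalModel) -> np.ndarray:
    days = np.arange(1, GRID_DAYS + 1)
    theta = 2.0 * np.pi * (days - 1) / GRID_DAYS
    fb = fourier_basis(theta, model.design.k)
    n_cov = len(model.design.reference_values)
    ref = np.tile(model.design.reference_values, (GRID_DAYS, 1)) if n_cov else np.empty((GRID_DAYS, 0))
    return np.column_stack([np.ones(GRID_DAYS), fb, ref])


def seasonal_summary(model: SeasonalModel) -> SeasonalSummary:
    """Evaluate the fitted seasonal mean on a daily grid.

    Continuous covariates are held at their sample means and categorical
    covariates at their reference level, so the curve shows the seasonal
    component for a reference individual. For k=1 the grid amplitude
    agrees with the closed form 2 sqrt(a^2 + b^2) up to the grid
    discretization bound.
    """
    Xg = _grid_design(model)
    curve = Xg @ model.fit.coefficients
    if model.fit.degenerate:
        se = np.zeros(GRID_DAYS)
    else:
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, model.fit.covariance, Xg))
    peak = int(np.argmax(curve))
    nadir = int(np.argmin(curve))
    days = np.arange(1, GRID_DAYS + 1)
    return SeasonalSummary(
        amplitude=float(curve[peak] - curve[nadir]),
        peak_day=int(days[peak]),
        nadir_day=int(days[nadir]),
        days=days,
        curve=curve,
        ci_lower=curve - _Z975 * se,
        ci_upper=curve + _Z975 * se,
    )


def amplitude_closed_form(a: float, b: float) -> tuple[float, float]:
    """k=1 cosinor closed form: (amplitude, peak_day).

    amplitude = 2 sqrt(a^2 + b^2); the curve a sin(t) + b cos(t) peaks at
    t* = atan2(a, b), mapped to a 1-based day on the daily grid scale.
    """
    amp = 2.0 * math.hypot(a, b)
    theta_star = math.atan2(a, b) % (2.0 * math.pi)
    return amp, theta_star / (2.0 * math.pi) * GRID_DAYS + 1.0


def circular_day_difference(a, b, period: float = GRID_DAYS) -> np.ndarray:
    """Signed day difference a - b wrapped into (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2.0, d - period, d)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    amplitude: float
    amplitude_ci: tuple[float, float]
    peak_day: float
    peak_day_ci: tuple[float, float]
    n_boot: int
    n_redrawn: int
    amplitudes: np.ndarray
    peak_days: np.ndarray


def bootstrap_amplitude_ci(
    records: pd.DataFrame,
    k: int = 1,
    covariates: Sequence[str] = (),
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    outcome: str = "ltl_z",
    level: float = 0.95,
    convention: str = "actual_year",
) -> BootstrapResult:
    """Case-resampling bootstrap for the seasonal amplitude and peak date.

    Resamples individuals with replacement, refits the seasonal model, and
    reads amplitude and peak day off the daily grid. Intervals are
    percentile; the peak-day interval is formed on circular deviations
    recentred at the point estimate. Rank-deficient resamples are redrawn
    (counted). Fully reproducible given ``seed``.
    """
    if B < 100:
        raise DesignError("B must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = fit_seasonal_model(records, k, covariates, outcome, convention)
    summ = seasonal_summary(model)
    X, y = model.design.X, model.design.y
    n, p = X.shape
    Xg = _grid_design(model)

    betas = np.empty((B, p))
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        Xb = X[idx]
        beta, _, rank, _ = np.linalg.lstsq(Xb, y[idx], rcond=None)
        if rank < p:
            n_redrawn += 1
            continue
        betas[b] = beta
        b += 1

    curves = betas @ Xg.T  # (B, GRID_DAYS)
    amps = curves.max(axis=1) - curves.min(axis=1)
    peaks = np.argmax(curves, axis=1) + 1.0

    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    amp_ci = (float(np.quantile(amps, lo)), float(np.quantile(amps, hi)))
    dev = circular_day_difference(peaks, summ.peak_day)
    d_lo, d_hi = np.quantile(dev, lo), np.quantile(dev, hi)
    peak_ci = (
        float((summ.peak_day + d_lo - 1) % GRID_DAYS + 1),
        float((summ.peak_day + d_hi - 1) % GRID_DAYS + 1),
    )
    return BootstrapResult(
        amplitude=summ.amplitude,
        amplitude_ci=amp_ci,
        peak_day=float(summ.peak_day),
        peak_day_ci=peak_ci,
        n_boot=B,
        n_redrawn=n_redrawn,
        amplitudes=amps,
        peak_days=peaks,
    )


# ---------------------------------------------------------------------------
# per-predictor effect models

#: Predictors with known seasonal variation get one Fourier pair added.
SEASONAL_PREDICTORS = frozenset(
    {"maternal_bmi", "log_maternal_bmi", "birthweight", "maternal_folate", "log_maternal_folate"}
)


def covariate_effect_models(
    records: pd.DataFrame,
    predictors: Sequence[str],
    adjust: Sequence[str] = ("age", "sex"),
    seasonal_predictors: frozenset = SEASONAL_PREDICTORS,
    outcome: str = "ltl_z",
    convention: str = "actual_year",
) -> pd.DataFrame:
    """Per-predictor effect estimates: ``ltl_z ~ predictor + age + sex``.

    Predictors with known seasonal variation (maternal BMI, birthweight,
    maternal folate) are additionally adjusted with one Fourier pair.
    Returns one row per predictor term (categorical predictors expand to
    one row per non-reference level) with the Wald coefficient, standard
    error and two-sided t-test p-value.
    """
    rows = []
    for pred in predictors:
        if pred not in records.columns:
            raise DesignError(f"unknown predictor {pred!r}")
        nuniq = records[pred].dropna().nunique()
        if nuniq < 2:
            raise DesignError(f"predictor {pred!r} is constant")
        k = 1 if pred in seasonal_predictors else 0
        covs = [pred] + [a for a in adjust if a != pred]
        model = fit_seasonal_model(records, k, covs, outcome, convention)
        fit = model.fit
        se_all = np.sqrt(np.diag(fit.covariance))
        dof = fit.n - fit.p
        for i, name in enumerate(fit.columns):
            if name == pred or name.startswith(f"{pred}["):
                beta = float(fit.coefficients[i])
                se = float(se_all[i])
                t = beta / se if se > 0 else math.inf
                rows.append(
                    {
                        "predictor": pred,
                        "term": name,
                        "beta": beta,
                        "se": se,
                        "p_value": float(2.0 * stats.t.sf(abs(t), dof)),
                        "n": fit.n,
                        "fourier_pairs": k,
                    }
                )
    return pd.DataFrame(rows)
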