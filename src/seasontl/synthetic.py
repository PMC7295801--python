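"""Synthetic cohorts, qPCR plates, and methylation mixtures.

The cohort data this pipeline was designed around (rural Gambian children
with ultrasound-dated conceptions) are not publicly distributable, so this
module generates cohorts with the same statistical structure, plus the
ground truth needed for recovery tests:

* a sinusoidal season-of-conception effect on the telomere-length outcome
  with configurable amplitude (max - min, z-units) and peak day;
* two collection designs: ``age_locked`` (every child sampled at a fixed
  age, so collection date is confounded with conception date, as in a
  toddler cohort sampled at age 2) and ``window_locked`` (all samples
  collected in a fixed Feb-May window, de-confounding the two dates, as in
  a mid-childhood cohort);
* plate structure with per-plate additive/multiplicative batch effects,
  duplicate measurement noise calibrated to a target replicate CV,
  standard dilution series, a reference sample and three control samples
  per plate;
* seasonally varying covariates (maternal BMI, birthweight, maternal
  folate), supplementation arms, leukocyte fractions, and MCAR
  missingness.

All generation is driven by one `numpy` Generator seeded from the config,
so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cells import ReferenceMatrix
from .seasonality import conception_angles

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "emphasis_like",
    "enid_like",
    "generate_cohort",
    "generate_plates",
    "generate_reference_mixtures",
    "CELL_TYPES",
]

CELL_TYPES = ("B", "CD4T", "CD8T", "Gran", "Mono", "NK")
#: typical childhood whole-blood leukocyte proportions (order = CELL_TYPES)
_CELL_PROPS = np.array([0.09, 0.15, 0.10, 0.55, 0.05, 0.06])
_CELL_CONCENTRATION = 60.0  # Dirichlet concentration: tight, realistic spread

GESTATION_DAYS = 280

# true instrument curves used to map quantities to Cq values
_TEL_SLOPE, _TEL_INTERCEPT = -3.45, 16.0
_SCG_SLOPE, _SCG_INTERCEPT = -3.32, 24.0
_STANDARD_DILUTIONS = (1.0, 0.5, 0.25, 0.125, 0.0625)
#: control samples' true T/S (an expected decline with donor age)
_CONTROLS = (("CTRL_A", 1.90), ("CTRL_B", 1.54), ("CTRL_C", 1.09))

# mapping from the latent z-scale outcome to a raw T/S ratio
_TS_BASE, _TS_SCALE = 1.1, 0.2
_TS_FLOOR = 0.02


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``true_amplitude`` is the peak-to-trough seasonal effect in z-units;
    ``peak_day`` the 1-based day of year of the seasonal maximum.
    ``covariate_effects`` maps covariate names (continuous covariates are
    standardized internally; use ``"sex_male"`` for the male indicator) to
    additive effects on the outcome.
    """

    n: int = 218
    design: str = "window_locked"  # or "age_locked"
    true_amplitude: float = 0.6
    peak_day: float = 244.0
    residual_sd: float = 1.0
    covariate_effects: dict = field(default_factory=dict)
    conception_start: str = "2006-07-01"
    conception_years: float = 2.0
    collection_window: tuple[str, str] = ("2016-02-01", "2016-05-31")
    male_fraction: float = 0.55
    birthweight_mean: float = 3069.0
    birthweight_sd: float = 417.0
    bmi_log_median: float = np.log(20.8)
    bmi_log_sd: float = 0.127
    include_folate: bool = False
    folate_log_median: float = np.log(13.0)
    folate_log_sd: float = 0.40
    maternal_arms: tuple[str, ...] = ("UNIMMAP", "placebo")
    maternal_arm_probs: tuple[float, ...] = (0.47, 0.53)
    infant_arms: tuple[str, ...] = ()
    missing_rates: dict = field(default_factory=dict)
    plate_size: int = 30
    plate_shift_sd: float = 0.08
    plate_scale_sd: float = 0.05
    duplicate_cv: float = 0.05
    standard_cq_sd: float = 0.0
    qc_fail_fraction: float = 0.0
    qc_fail_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.true_amplitude < 0:
            raise ValueError("true_amplitude must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.design not in ("age_locked", "window_locked"):
            raise ValueError(f"unknown design {self.design!r}")


def emphasis_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Mid-childhood cohort: fixed Feb-May collection window, n = 218."""
    return SyntheticConfig(seed=seed, **overrides)


def enid_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Toddler cohort: sampled at age ~2, collection confounded with
    conception; larger n, folate measured, four maternal arms, more
    missingness in maternal BMI and birthweight."""
    defaults = dict(
        n=487,
        design="age_locked",
        male_fraction=0.50,
        birthweight_mean=3023.0,
        birthweight_sd=402.0,
        bmi_log_median=float(np.log(20.4)),
        include_folate=True,
        conception_start="2009-07-01",
        conception_years=4.0,
        maternal_arms=("FeFol", "MMN", "PE", "PE+MMN"),
        maternal_arm_probs=(0.25, 0.27, 0.24, 0.24),
        infant_arms=("LNS", "LNS+MMN"),
        missing_rates={"maternal_bmi": 0.29, "birthweight": 0.19},
    )
    defaults.update(overrides)
    return SyntheticConfig(seed=seed, **defaults)


@dataclass
class SyntheticTruth:
    """Ground truth: per-child components pre-missingness, plus config echo."""

    per_child: pd.DataFrame
    config: SyntheticConfig


def _theta_peak(peak_day: float) -> float:
    return 2.0 * np.pi * (peak_day - 1.0) / 365.25


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort phenotype table and its ground truth.

    The outcome column ``ltl_z`` holds the latent (measurement-error-free)
    telomere z-score: seasonal effect + covariate effects + Gaussian
    residual. :func:`generate_plates` turns it into raw qPCR readings.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    start = np.datetime64(config.conception_start, "D")
    span = int(round(config.conception_years * 365.25))
    conception = start + rng.integers(0, span, n).astype("timedelta64[D]")
    theta = conception_angles(conception)

    s = 0.5 * config.true_amplitude * np.cos(theta - _theta_peak(config.peak_day))

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    # seasonally varying covariates: small sinusoids on top of the marginals
    birthweight = (
        rng.normal(config.birthweight_mean, config.birthweight_sd, n)
        + 50.0 * np.cos(theta - _theta_peak(300.0))
    )
    maternal_bmi = np.exp(
        rng.normal(config.bmi_log_median, config.bmi_log_sd, n)
        + 0.02 * np.cos(theta - _theta_peak(60.0))
    )
    if config.include_folate:
        maternal_folate = np.exp(
            rng.normal(config.folate_log_median, config.folate_log_sd, n)
            + 0.075 * np.cos(theta - _theta_peak(230.0))
        )
    else:
        maternal_folate = np.full(n, np.nan)

    maternal_arm = rng.choice(config.maternal_arms, size=n, p=config.maternal_arm_probs)
    infant_arm = (
        rng.choice(config.infant_arms, size=n)
        if config.infant_arms
        else np.full(n, None, dtype=object)
    )
    fractions = rng.dirichlet(_CELL_PROPS * _CELL_CONCENTRATION, size=n)

    if config.design == "age_locked":
        collection = conception + np.timedelta64(GESTATION_DAYS + 2 * 365, "D")
    else:
        w0 = np.datetime64(config.collection_window[0], "D")
        w1 = np.datetime64(config.collection_window[1], "D")
        wspan = int((w1 - w0) / np.timedelta64(1, "D")) + 1
        collection = w0 + rng.integers(0, wspan, n).astype("timedelta64[D]")
    age = ((collection - conception) / np.timedelta64(1, "D") - GESTATION_DAYS) / 365.25
    if np.any(age <= 0):
        raise ValueError("impossible date arithmetic: collection precedes birth")

    # covariate effects on the latent outcome
    effect = np.zeros(n)
    continuous = {
        "birthweight": birthweight,
        "maternal_bmi": maternal_bmi,
        "maternal_folate": maternal_folate,
        "age": age,
    }
    for name, beta in config.covariate_effects.items():
        if name == "sex_male":
            effect += beta * (sex == "male")
        elif name in continuous:
            x = continuous[name]
            effect += beta * (x - np.nanmean(x)) / np.nanstd(x, ddof=1)
        else:
            raise ValueError(f"unknown covariate effect {name!r}")

    noise = rng.normal(0.0, config.residual_sd, n)
    ltl = s + effect + noise

    child_id = np.array([f"C{i:04d}" for i in range(n)])
    cohort = pd.DataFrame(
        {
            "child_id": child_id,
            "sample_id": child_id,
            "conception_date": pd.DatetimeIndex(conception),
            "collection_date": pd.DatetimeIndex(collection),
            "age": age,
            "sex": sex,
            "maternal_bmi": maternal_bmi,
            "birthweight": birthweight,
            "maternal_folate": maternal_folate,
            "maternal_arm": maternal_arm,
            "infant_arm": infant_arm,
            "ltl_z": ltl,
        }
    )
    for j, ct in enumerate(CELL_TYPES):
        cohort[f"frac_{ct}"] = fractions[:, j]

    truth_df = cohort.copy()
    truth_df["theta"] = theta
    truth_df["seasonal_effect"] = s
    truth_df["covariate_effect"] = effect
    truth_df["noise"] = noise

    # MCAR missingness on the analysis table only (truth keeps everything)
    for col, rate in config.missing_rates.items():
        if rate <= 0:
            continue
        targets = (
            [f"frac_{ct}" for ct in CELL_TYPES] if col == "cell_fractions" else [col]
        )
        mask = rng.random(n) < rate
        for t in targets:
            cohort.loc[mask, t] = np.nan

    return cohort, SyntheticTruth(per_child=truth_df, config=config)


# ---------------------------------------------------------------------------
# plates


def _cq_tel(q: np.ndarray) -> np.ndarray:
    return _TEL_INTERCEPT + _TEL_SLOPE * np.log10(q)


def _cq_scg(q: np.ndarray) -> np.ndarray:
    return _SCG_INTERCEPT + _SCG_SLOPE * np.log10(q)


def generate_plates(
    cohort: pd.DataFrame, truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Emit the raw qPCR well table for a cohort.

    Children fill plates of ``plate_size`` in id order; each plate gets an
    additive shift and multiplicative scale on its measured T/S (the batch
    effect), a 5-point standard dilution series per target, a reference
    sample, and three control samples. Every sample is run in duplicate
    with lognormal noise on both target quantities, calibrated so the
    expected duplicate T/S CV equals ``duplicate_cv``. A configurable
    fraction of children get one inflated replicate to force a duplicate
    CV above the QC threshold.

    Updates ``truth.per_child`` with ``plate_id`` and ``true_ts`` and
    returns a well table in the CSV dialect consumed by the qPCR module.
    """
    config = config or truth.config
    if config.plate_size < 1:
        raise ValueError("plate_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = len(cohort)

    ltl = truth.per_child["ltl_z"].to_numpy()
    true_ts = np.clip(_TS_BASE + _TS_SCALE * ltl, _TS_FLOOR, None)
    plate_idx = np.arange(n) // config.plate_size
    n_plates = int(plate_idx.max()) + 1
    plate_ids = np.array([f"P{j + 1:02d}" for j in range(n_plates)])

    truth.per_child = truth.per_child.assign(
        plate_id=plate_ids[plate_idx], true_ts=true_ts
    )

    shifts = rng.normal(0.0, config.plate_shift_sd, n_plates)
    scales = np.exp(rng.normal(0.0, config.plate_scale_sd, n_plates))

    n_fail = int(round(config.qc_fail_fraction * n))
    fail_set = set(rng.choice(n, size=n_fail, replace=False)) if n_fail else set()
    injected = np.zeros(n, dtype=bool)
    injected[list(fail_set)] = True
    truth.per_child = truth.per_child.assign(qc_fail_injected=injected)

    # lognormal log-sd per target replicate, calibrated so the *expected
    # reported* duplicate CV (sample sd of 2 replicates / mean) equals
    # duplicate_cv: the 2-sample sd is biased by c4 = sqrt(2/pi).
    c4 = np.sqrt(2.0 / np.pi)
    sig_each = np.sqrt(np.log1p(config.duplicate_cv**2)) / np.sqrt(2.0) / c4

    rows: list[tuple] = []

    def emit(plate, well, sid, target, cq, rep, role, dil):
        rows.append((plate, well, sid, target, float(cq), rep, role, dil))

    for j in range(n_plates):
        pid = plate_ids[j]
        wellno = 0

        def next_well():
            nonlocal wellno
            wellno += 1
            return f"W{wellno:03d}"

        # standard dilution series (both targets read in the same well)
        for rep in (1, 2):
            for d in _STANDARD_DILUTIONS:
                w = next_well()
                emit(pid, w, "STD", "tel",
                     _cq_tel(np.array(d)) + rng.normal(0, config.standard_cq_sd)
                     if config.standard_cq_sd else _cq_tel(np.array(d)),
                     rep, "standard", d)
                emit(pid, w, "STD", "scg",
                     _cq_scg(np.array(d)) + rng.normal(0, config.standard_cq_sd)
                     if config.standard_cq_sd else _cq_scg(np.array(d)),
                     rep, "standard", d)

        # reference and control samples, subject to the plate batch effect
        specials = [("REF", 1.0, "reference")] + [
            (sid, ts, "control") for sid, ts in _CONTROLS
        ]
        members = list(np.nonzero(plate_idx == j)[0])
        for sid, ts0, role in specials:
            meas = max(scales[j] * ts0 + shifts[j], _TS_FLOOR)
            for rep in (1, 2):
                w = next_well()
                nt = np.exp(rng.normal(0.0, sig_each)) if sig_each > 0 else 1.0
                ns = np.exp(rng.normal(0.0, sig_each)) if sig_each > 0 else 1.0
                emit(pid, w, sid, "tel", _cq_tel(np.array(meas * nt)), rep, role, None)
                emit(pid, w, sid, "scg", _cq_scg(np.array(1.0 * ns)), rep, role, None)

        # cohort samples in duplicate
        for i in members:
            sid = cohort["sample_id"].iloc[i]
            meas = max(scales[j] * true_ts[i] + shifts[j], _TS_FLOOR)
            dna = np.exp(rng.normal(0.0, 0.15))
            for rep in (1, 2):
                w = next_well()
                nt = np.exp(rng.normal(0.0, sig_each)) if sig_each > 0 else 1.0
                ns = np.exp(rng.normal(0.0, sig_each)) if sig_each > 0 else 1.0
                qt = meas * dna * nt
                if rep == 2 and i in fail_set:
                    qt *= config.qc_fail_factor
                qs = dna * ns
                emit(pid, w, sid, "tel", _cq_tel(np.array(qt)), rep, "sample", None)
                emit(pid, w, sid, "scg", _cq_scg(np.array(qs)), rep, "sample", None)

    wells = pd.DataFrame(
        rows,
        columns=["plate_id", "well", "sample_id", "target", "cq",
                 "replicate_idx", "role", "dilution"],
    )
    return wells


# ---------------------------------------------------------------------------
# methylation-like reference mixtures


def generate_reference_mixtures(
    n_samples: int = 50,
    n_markers: int = 120,
    cell_types: tuple[str, ...] = CELL_TYPES,
    noise_sd: float = 0.01,
    alpha=None,
    seed: int | None = None,
) -> tuple[ReferenceMatrix, pd.DataFrame, pd.DataFrame]:
    """Synthetic deconvolution problem: reference, mixed profiles, truth.

    The reference is a markers x cell-types matrix of Beta(0.4, 0.4)
    values (bimodal, methylation-like); true fractions are Dirichlet
    (uniform over the simplex by default); profiles are reference @ w plus
    Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    if n_markers < k:
        raise ValueError("need at least as many markers as cell types")
    ref_vals = rng.beta(0.4, 0.4, size=(n_markers, k))
    marker_ids = tuple(f"cg{i:05d}" for i in range(n_markers))
    reference = ReferenceMatrix(values=ref_vals, marker_ids=marker_ids, cell_types=cell_types)

    alpha = np.ones(k) if alpha is None else np.asarray(alpha, dtype=float)
    w = rng.dirichlet(alpha, size=n_samples)  # (n_samples, k)
    prof = ref_vals @ w.T
    if noise_sd > 0:
        prof = prof + rng.normal(0.0, noise_sd, size=prof.shape)
    prof = np.clip(prof, 0.0, 1.0)

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    profiles = pd.DataFrame(prof, index=list(marker_ids), columns=sample_ids)
    true_fracs = pd.DataFrame(w, index=sample_ids, columns=list(cell_types))
    return reference, profiles, true_fracs
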