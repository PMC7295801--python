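"""Monochrome multiplex qPCR (MMqPCR) plate processing.

Turns raw per-well quantification cycles (Cq) into per-sample relative
telomere length estimates expressed as T/S ratios: the quantity of the
telomere-repeat amplicon (T) relative to a single-copy gene amplicon (S),
each interpolated from a per-plate standard curve fitted to a reference-DNA
dilution series. Includes duplicate-CV quality control and assay-level
coefficient-of-variation reporting.

Conventions
-----------
* Standard curves are fitted per plate and per target; no cross-plate
  pooling.
* T/S is computed per replicate and then averaged ("per_replicate"
  dialect); a "ratio_of_means" dialect (mean T quantity over mean S
  quantity) is available via ``compute_ts_ratio(..., method=...)``.
* All coefficients of variation use the sample (n-1) standard deviation.
* The duplicate-CV QC rule is strict: records with CV *strictly greater*
  than the threshold are excluded; a record exactly at the threshold is
  kept.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Target",
    "Role",
    "QpcrWell",
    "StandardCurve",
    "TSRecord",
    "AssayCvReport",
    "QpcrError",
    "DegenerateCurveError",
    "SingularFitError",
    "InvalidCurveError",
    "fit_standard_curve",
    "quantify",
    "compute_ts_ratio",
    "apply_qc",
    "assay_cvs",
    "process_plates",
    "read_wells_csv",
    "wells_from_frame",
    "records_to_frame",
    "write_ts_records_csv",
]


class Target(str, Enum):
    """Amplicon measured in a well: telomere repeat or single-copy gene."""

    TELOMERE = "tel"
    SINGLE_COPY = "scg"


class Role(str, Enum):
    """What a well's DNA is: study sample, dilution standard, the plate
    reference sample, or an inter-assay control."""

    SAMPLE = "sample"
    STANDARD = "standard"
    REFERENCE = "reference"
    CONTROL = "control"


class QpcrError(ValueError):
    """Base class for qPCR processing errors."""


class DegenerateCurveError(QpcrError):
    """Standard curve requested from fewer than 3 distinct dilution levels."""


class SingularFitError(QpcrError):
    """No variance in log10(dilution); the line is not identifiable."""


class InvalidCurveError(QpcrError):
    """Quantification attempted against a curve with non-negative slope."""


@dataclass(frozen=True)
class QpcrWell:
    """One well's reading for one target.

    In MMqPCR both amplicons are read in the same physical well, so the
    same (plate_id, well) pair normally appears twice, once per target.
    ``dilution`` is the relative concentration of the dilution series and
    is defined only for standards.
    """

    plate_id: str
    well: str
    sample_id: str
    target: Target
    cq: float
    replicate_idx: int = 1
    role: Role = Role.SAMPLE
    dilution: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cq) and self.cq > 0):
            raise QpcrError(
                f"well {self.plate_id}/{self.well}: cq must be finite and > 0, got {self.cq}"
            )
        if self.replicate_idx < 1:
            raise QpcrError("replicate_idx must be >= 1")
        if self.role == Role.STANDARD:
            if self.dilution is None or not (self.dilution > 0):
                raise QpcrError(
                    f"standard well {self.plate_id}/{self.well} requires dilution > 0"
                )


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Cq versus log10(relative concentration).

    ``efficiency`` is the per-cycle amplification efficiency implied by the
    slope, ``10**(-1/slope) - 1`` (1.0 means perfect doubling, slope
    -3.3219).
    """

    plate_id: str
    target: Target
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int


@dataclass
class TSRecord:
    """Per-sample T/S ratio with duplicate variability and QC status.

    ``ts_ratio`` is NaN when every replicate failed to amplify;
    ``replicate_cv`` is NaN when fewer than two complete replicates were
    available (QC then defers to :func:`apply_qc`, which excludes it).
    """

    sample_id: str
    plate_id: str
    ts_ratio: float
    replicate_cv: float
    n_replicates: int
    qc_pass: bool = True
    exclusion_reason: str | None = None


@dataclass(frozen=True)
class AssayCvReport:
    """Intra-assay (duplicate-level) and inter-assay (cross-plate) CVs.

    ``inter_assay_cv`` is None when no reference/control sample appears on
    at least two plates.
    """

    intra_assay_cv: float
    inter_assay_cv: float | None
    n_samples: int
    n_plates: int


# ---------------------------------------------------------------------------
# standard curves


def fit_standard_curve(wells: Sequence[QpcrWell]) -> StandardCurve:
    """Fit the per-plate, per-target standard curve from dilution wells.

    Ordinary least squares of Cq on log10(dilution). All wells must be
    standards from a single plate and target.

    Raises
    ------
    DegenerateCurveError
        Fewer than three distinct dilution levels.
    SingularFitError
        Zero variance in log10(dilution).
    """
    wells = list(wells)
    if not wells:
        raise DegenerateCurveError("no standard wells supplied")
    plates = {w.plate_id for w in wells}
    targets = {w.target for w in wells}
    if len(plates) != 1 or len(targets) != 1:
        raise QpcrError("standard wells must come from one plate and one target")
    for w in wells:
        if w.role != Role.STANDARD:
            raise QpcrError(f"non-standard well {w.well} passed to fit_standard_curve")

    x = np.log10([w.dilution for w in wells])
    y = np.array([w.cq for w in wells], dtype=float)
    if len(set(np.round(x, 12))) < 3:
        raise DegenerateCurveError(
            f"standard curve needs >= 3 distinct dilution levels, got {len(set(x))}"
        )
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in log10(dilution)")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    eff = float(10.0 ** (-1.0 / slope) - 1.0) if slope != 0 else float("nan")
    return StandardCurve(
        plate_id=wells[0].plate_id,
        target=wells[0].target,
        slope=float(slope),
        intercept=float(intercept),
        efficiency=eff,
        r_squared=float(r2),
        n_points=len(wells),
    )


def quantify(cq: float, curve: StandardCurve) -> float:
    """Relative quantity implied by a Cq under a standard curve.

    Inverts the curve: ``10 ** ((cq - intercept) / slope)``.
    """
    if not curve.slope < 0:
        raise InvalidCurveError(
            f"curve {curve.plate_id}/{curve.target.value} has slope "
            f"{curve.slope} >= 0; not a valid amplification curve"
        )
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


# ---------------------------------------------------------------------------
# T/S ratios


def _sample_cv(values: np.ndarray) -> float:
    """sd/mean with the n-1 standard deviation; NaN for < 2 values."""
    if len(values) < 2:
        return float("nan")
    m = float(np.mean(values))
    if m == 0:
        return float("nan")
    return float(np.std(values, ddof=1) / m)


def compute_ts_ratio(
    sample_wells: Sequence[QpcrWell],
    curve_t: StandardCurve,
    curve_s: StandardCurve,
    method: str = "per_replicate",
) -> TSRecord:
    """Compute a sample's T/S ratio from its wells on one plate.

    Replicates missing either target are dropped (logged). With
    ``method="per_replicate"`` (default) the T/S ratio is the mean of the
    per-replicate ratios and the duplicate CV is the sd/mean of those
    ratios; with ``method="ratio_of_means"`` the ratio of mean quantities
    is reported instead (the CV is still computed from per-replicate
    ratios, since the duplicate QC rule is defined on them).
    """
    if method not in ("per_replicate", "ratio_of_means"):
        raise ValueError(f"unknown T/S method {method!r}")
    wells = list(sample_wells)
    if not wells:
        raise QpcrError("no wells supplied")
    sample_ids = {w.sample_id for w in wells}
    plate_ids = {w.plate_id for w in wells}
    if len(sample_ids) != 1 or len(plate_ids) != 1:
        raise QpcrError("wells must belong to one sample on one plate")
    sample_id, plate_id = wells[0].sample_id, wells[0].plate_id

    by_rep: dict[int, dict[Target, float]] = defaultdict(dict)
    for w in wells:
        by_rep[w.replicate_idx][w.target] = w.cq

    qt, qs = [], []
    n_dropped = 0
    for rep_idx in sorted(by_rep):
        cqs = by_rep[rep_idx]
        if Target.TELOMERE not in cqs or Target.SINGLE_COPY not in cqs:
            n_dropped += 1
            logger.info(
                "sample %s plate %s replicate %d incomplete (missing target); dropped",
                sample_id,
                plate_id,
                rep_idx,
            )
            continue
        qt.append(quantify(cqs[Target.TELOMERE], curve_t))
        qs.append(quantify(cqs[Target.SINGLE_COPY], curve_s))

    if not qt:
        return TSRecord(
            sample_id=sample_id,
            plate_id=plate_id,
            ts_ratio=float("nan"),
            replicate_cv=float("nan"),
            n_replicates=0,
        )

    ratios = np.asarray(qt) / np.asarray(qs)
    if method == "per_replicate":
        ts = float(np.mean(ratios))
    else:
        ts = float(np.mean(qt) / np.mean(qs))
    return TSRecord(
        sample_id=sample_id,
        plate_id=plate_id,
        ts_ratio=ts,
        replicate_cv=_sample_cv(ratios),
        n_replicates=len(ratios),
    )


def apply_qc(
    records: Iterable[TSRecord], cv_threshold: float = 0.15
) -> tuple[list[TSRecord], list[TSRecord]]:
    """Partition T/S records into (kept, excluded) under the duplicate-CV rule.

    Excluded are: amplification failures (no usable replicate), records
    whose duplicate CV is undefined (single replicate), and records with
    duplicate CV strictly above ``cv_threshold``. Input records are not
    mutated; annotated copies are returned.
    """
    kept: list[TSRecord] = []
    excluded: list[TSRecord] = []
    for rec in records:
        reason = None
        if rec.n_replicates == 0 or not math.isfinite(rec.ts_ratio):
            reason = "amplification failure"
        elif not math.isfinite(rec.replicate_cv):
            reason = "duplicate CV undefined (fewer than 2 replicates)"
        elif rec.replicate_cv > cv_threshold:
            reason = "duplicate CV > threshold"
        if reason is None:
            kept.append(dataclasses.replace(rec, qc_pass=True, exclusion_reason=None))
        else:
            excluded.append(dataclasses.replace(rec, qc_pass=False, exclusion_reason=reason))
    logger.info(
        "QC: kept %d, excluded %d (threshold %.3g)", len(kept), len(excluded), cv_threshold
    )
    return kept, excluded


def assay_cvs(
    records: Iterable[TSRecord],
    reference_ids: Iterable[str],
    control_ids: Iterable[str],
) -> AssayCvReport:
    """Assay-level CV summary over QC-passed records.

    * intra-assay CV: mean duplicate (replicate-level) CV across kept
      records with a defined CV;
    * inter-assay CV: for each reference/control sample measured on >= 2
      plates, the sd/mean of its per-plate T/S values, averaged across
      those samples. None when no sample is common to >= 2 plates.
    """
    kept = [r for r in records if r.qc_pass and math.isfinite(r.ts_ratio)]
    cvs = [r.replicate_cv for r in kept if math.isfinite(r.replicate_cv)]
    intra = float(np.mean(cvs)) if cvs else float("nan")

    common = set(reference_ids) | set(control_ids)
    per_sample_plate: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for r in kept:
        if r.sample_id in common:
            per_sample_plate[r.sample_id][r.plate_id].append(r.ts_ratio)

    inter_cvs = []
    for sid, plates in per_sample_plate.items():
        plate_means = np.array([np.mean(v) for v in plates.values()])
        if len(plate_means) >= 2:
            inter_cvs.append(_sample_cv(plate_means))
    inter = float(np.mean(inter_cvs)) if inter_cvs else None

    return AssayCvReport(
        intra_assay_cv=intra,
        inter_assay_cv=inter,
        n_samples=len(kept),
        n_plates=len({r.plate_id for r in kept}),
    )


# ---------------------------------------------------------------------------
# plate-level driver and CSV interfaces

_CSV_COLUMNS = [
    "plate_id",
    "well",
    "sample_id",
    "target",
    "cq",
    "replicate_idx",
    "role",
    "dilution",
]


def read_wells_csv(path) -> list[QpcrWell]:
    """Read a raw plate table (one row per well per target) into wells.

    Expected header: ``plate_id,well,sample_id,target,cq,replicate_idx,
    role,dilution`` with target values "tel"/"scg" and empty dilution for
    non-standards.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "sample_id": str})
    return wells_from_frame(df)


def wells_from_frame(df: pd.DataFrame) -> list[QpcrWell]:
    """Validate a raw well table (same dialect as the CSV) into wells."""
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise QpcrError(f"wells CSV missing columns: {sorted(missing)}")
    wells = []
    for row in df.itertuples(index=False):
        dil = getattr(row, "dilution")
        wells.append(
            QpcrWell(
                plate_id=str(row.plate_id),
                well=str(row.well),
                sample_id=str(row.sample_id),
                target=Target(row.target),
                cq=float(row.cq),
                replicate_idx=int(row.replicate_idx),
                role=Role(row.role),
                dilution=None if pd.isna(dil) else float(dil),
            )
        )
    return wells


def wells_to_frame(wells: Iterable[QpcrWell]) -> pd.DataFrame:
    rows = [
        {
            "plate_id": w.plate_id,
            "well": w.well,
            "sample_id": w.sample_id,
            "target": w.target.value,
            "cq": w.cq,
            "replicate_idx": w.replicate_idx,
            "role": w.role.value,
            "dilution": w.dilution,
        }
        for w in wells
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_to_frame(records: Iterable[TSRecord]) -> pd.DataFrame:
    """TSRecords as a tidy table (one row per sample per plate)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plate_id": r.plate_id,
                "ts_ratio": r.ts_ratio,
                "replicate_cv": r.replicate_cv,
                "n_replicates": r.n_replicates,
                "qc_pass": r.qc_pass,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in records
        ]
    )


def write_ts_records_csv(records: Iterable[TSRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def process_plates(
    wells: Sequence[QpcrWell],
    cv_threshold: float = 0.15,
    method: str = "per_replicate",
) -> dict:
    """Run the full plate workflow: curves -> T/S -> QC -> assay CVs.

    Returns a dict with keys ``curves`` (per plate/target), ``kept`` and
    ``excluded`` TSRecord lists, and ``report`` (:class:`AssayCvReport`).
    Reference and control sample ids are taken from well roles.
    """
    curves: dict[tuple[str, Target], StandardCurve] = {}
    by_plate_target: dict[tuple[str, Target], list[QpcrWell]] = defaultdict(list)
    for w in wells:
        if w.role == Role.STANDARD:
            by_plate_target[(w.plate_id, w.target)].append(w)
    for key, ws in by_plate_target.items():
        curves[key] = fit_standard_curve(ws)

    by_sample: dict[tuple[str, str], list[QpcrWell]] = defaultdict(list)
    reference_ids, control_ids = set(), set()
    for w in wells:
        if w.role == Role.STANDARD:
            continue
        if w.role == Role.REFERENCE:
            reference_ids.add(w.sample_id)
        elif w.role == Role.CONTROL:
            control_ids.add(w.sample_id)
        by_sample[(w.plate_id, w.sample_id)].append(w)

    records = []
    for (plate_id, _sid), ws in sorted(by_sample.items()):
        ct = curves.get((plate_id, Target.TELOMERE))
        cs = curves.get((plate_id, Target.SINGLE_COPY))
        if ct is None or cs is None:
            raise QpcrError(f"plate {plate_id} is missing a standard curve")
        records.append(compute_ts_ratio(ws, ct, cs, method=method))

    kept, excluded = apply_qc(records, cv_threshold=cv_threshold)
    report = assay_cvs(kept, reference_ids, control_ids)
    return {
        "curves": curves,
        "kept": kept,
        "excluded": excluded,
        "report": report,
        "reference_ids": sorted(reference_ids),
        "control_ids": sorted(control_ids),
    }
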