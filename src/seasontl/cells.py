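"""Reference-based white-cell composition estimation.

Leukocyte telomere length is measured on whole blood, so differences in
white-cell composition can masquerade as telomere-length differences.
Composition is estimated Houseman-style: each sample's methylation-like
marker profile is modelled as a convex mixture of cell-type reference
profiles, and the mixing weights are recovered by least squares
constrained to the probability simplex (w >= 0, sum w = 1).

The solver is the Lawson-Hanson active-set non-negative least squares on a
system augmented with a heavily weighted sum-to-one row, followed by an
exact renormalization onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["ReferenceMatrix", "CellCompositionError", "estimate_fractions", "estimate_fractions_frame"]

#: Weight of the sum-to-one row in the augmented NNLS system. Large enough
#: that the equality constraint dominates the marker residuals.
SUM_WEIGHT = 1000.0


class CellCompositionError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceMatrix:
    """Expected marker signal per cell type (markers x cell types, in [0,1])."""

    values: np.ndarray
    marker_ids: tuple[str, ...]
    cell_types: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        m, k = v.shape
        if m != len(self.marker_ids) or k != len(self.cell_types):
            raise CellCompositionError("reference shape does not match labels")
        if m < k:
            raise CellCompositionError("need at least as many markers as cell types")
        if v.min() < 0 or v.max() > 1:
            raise CellCompositionError("reference entries must lie in [0, 1]")
        if np.linalg.matrix_rank(v) < k:
            raise CellCompositionError("reference matrix is rank deficient")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            marker_ids=tuple(str(i) for i in df.index),
            cell_types=tuple(str(c) for c in df.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.marker_ids), columns=list(self.cell_types))


def estimate_fractions(
    profile,
    reference: ReferenceMatrix,
    sum_weight: float = SUM_WEIGHT,
    maxiter: int = 10_000,
) -> np.ndarray:
    """Estimate cell-type fractions for one sample profile.

    Solves ``min || profile - R w ||^2  s.t.  w >= 0, sum(w) = 1``. When
    ``profile`` is a pandas Series it is aligned to the reference's marker
    ids; a plain array must already be in reference marker order.

    Returns the fraction vector over ``reference.cell_types`` (sums to 1
    to 1e-8).
    """
    R = reference.values
    if isinstance(profile, pd.Series):
        missing = set(reference.marker_ids) - set(map(str, profile.index))
        if missing:
            raise CellCompositionError(f"profile missing markers: {sorted(missing)[:5]} ...")
        p = profile.loc[list(reference.marker_ids)].to_numpy(dtype=float)
    else:
        p = np.asarray(profile, dtype=float)
        if p.shape != (R.shape[0],):
            raise CellCompositionError(
                f"profile has {p.shape} values; reference expects {R.shape[0]} markers"
            )
    if not np.all(np.isfinite(p)):
        raise CellCompositionError("profile contains non-finite values")

    k = R.shape[1]
    A = np.vstack([R, np.full((1, k), sum_weight)])
    b = np.concatenate([p, [sum_weight]])
    w, _ = nnls(A, b, maxiter=maxiter)
    total = w.sum()
    if total <= 0:
        raise CellCompositionError("degenerate solution: all fractions zero")
    return w / total


def estimate_fractions_frame(profiles: pd.DataFrame, reference: ReferenceMatrix) -> pd.DataFrame:
    """Fractions for a markers x samples profile table; rows = samples."""
    out = {}
    for col in profiles.columns:
        out[col] = estimate_fractions(profiles[col], reference)
    return pd.DataFrame.from_dict(out, orient="index", columns=list(reference.cell_types))
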