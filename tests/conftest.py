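import numpy as np
import pandas as pd
import pytest

from seasontl.qpcr import QpcrWell, Role, StandardCurve, Target, fit_standard_curve


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_standards(plate="P1", target=Target.TELOMERE, slope=-3.5, intercept=30.0,
                   dilutions=(1.0, 0.5, 0.25, 0.125, 0.0625), noise=None, rng=None):
    """Standard wells on (or near) an exact line cq = intercept + slope*log10(d)."""
    wells = []
    for i, d in enumerate(dilutions):
        cq = intercept + slope * np.log10(d)
        if noise:
            cq += rng.normal(0, noise)
        wells.append(
            QpcrWell(plate_id=plate, well=f"W{i:02d}", sample_id="STD", target=target,
                     cq=float(cq), replicate_idx=1, role=Role.STANDARD, dilution=d)
        )
    return wells


def make_curve(slope=-3.3219, intercept=25.0, plate="P1", target=Target.TELOMERE):
    eff = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(plate_id=plate, target=target, slope=slope, intercept=intercept,
                         efficiency=eff, r_squared=1.0, n_points=5)


@pytest.fixture
def curves():
    """A telomere and a single-copy curve with different slopes/intercepts."""
    ct = make_curve(slope=-3.45, intercept=16.0, target=Target.TELOMERE)
    cs = make_curve(slope=-3.32, intercept=24.0, target=Target.SINGLE_COPY)
    return ct, cs


def sample_wells_from_ratios(ratios, curve_t, curve_s, sample_id="S1", plate="P1", qs=1.0):
    """Wells for one sample whose per-replicate T/S ratios are exactly `ratios`."""
    wells = []
    for rep, r in enumerate(ratios, start=1):
        cq_t = curve_t.intercept + curve_t.slope * np.log10(r * qs)
        cq_s = curve_s.intercept + curve_s.slope * np.log10(qs)
        wells.append(QpcrWell(plate, f"T{rep}", sample_id, Target.TELOMERE, float(cq_t), rep))
        wells.append(QpcrWell(plate, f"T{rep}", sample_id, Target.SINGLE_COPY, float(cq_s), rep))
    return wells
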