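"""Standard-curve amplification-efficiency QC.

A standard curve is a serial dilution of pooled RNA (5-fold steps for the
mRNA assays, 4-fold for the miRNA assays) measured in triplicate. Cq is
regressed on log10(relative input); the amplification efficiency follows from
the slope as

    E = 10^(-1/slope) - 1

so a slope of -1/log10(2) = -3.3219 is exactly 100% (perfect doubling each
cycle). An assay passes when 90% <= E <= 110% and the squared Pearson
correlation of the fit (R^2) is at least 0.98; failing assays are annotated
and reported, never silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "StandardCurve",
    "EfficiencyResult",
    "StandardCurveEfficiency",
    "fit_standard_curve",
    "classify_assays",
    "read_standard_curves",
    "EFFICIENCY_PASS_RANGE",
    "R2_PASS_THRESHOLD",
]

EFFICIENCY_PASS_RANGE = (90.0, 110.0)  # percent
R2_PASS_THRESHOLD = 0.98


@dataclass(frozen=True)
class StandardCurve:
    """One assay's dilution series: (dilution_step, cq) pairs.

    ``dilution_step`` 0 is the undiluted pool; each step divides input by
    ``dilution_factor``, so log10(relative input) = -step * log10(factor).
    """

    assay_id: str
    points: tuple[tuple[int, float], ...]  # (dilution_step, cq)
    dilution_factor: float

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if len({s for s, _ in self.points}) < 3:
            raise ValueError(
                f"standard curve for {self.assay_id} needs >= 3 distinct dilution steps"
            )


@dataclass(frozen=True)
class EfficiencyResult:
    assay_id: str
    slope: float  # cycles per log10(input)
    efficiency_pct: float
    r_squared: float
    pass_efficiency: bool
    pass_linearity: bool
    dynamic_range: tuple[float, float]  # (min, max) log10 relative input


class StandardCurveEfficiency(BaseEstimator):
    """OLS fit of Cq on log10(relative input) for one dilution series.

    Parameters
    ----------
    average_replicates : bool, default True
        Average triplicate reactions per dilution step before fitting;
        set False to fit on raw replicates.

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_, intercept_, efficiency_pct_, r_squared_, pass_efficiency_,
    pass_linearity_, dynamic_range_
    """

    def __init__(self, average_replicates: bool = True):
        self.average_replicates = average_replicates

    def fit(self, curve: StandardCurve) -> "StandardCurveEfficiency":
        pts = pd.DataFrame(curve.points, columns=["step", "cq"])
        if self.average_replicates:
            pts = pts.groupby("step", as_index=False)["cq"].mean()
        x = -pts["step"].to_numpy(float) * np.log10(curve.dilution_factor)
        y = pts["cq"].to_numpy(float)
        res = stats.linregress(x, y)
        if res.slope >= 0:
            raise ValueError(f"non-amplifying curve for {curve.assay_id} (slope >= 0)")
        self.assay_id_ = curve.assay_id
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.efficiency_pct_ = float((10.0 ** (-1.0 / res.slope) - 1.0) * 100.0)
        self.r_squared_ = float(res.rvalue**2)
        lo, hi = EFFICIENCY_PASS_RANGE
        self.pass_efficiency_ = bool(lo <= self.efficiency_pct_ <= hi)
        self.pass_linearity_ = bool(self.r_squared_ >= R2_PASS_THRESHOLD)
        self.dynamic_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, log10_input: np.ndarray) -> np.ndarray:
        """Predicted Cq for given log10(relative input)."""
        return self.intercept_ + self.slope_ * np.asarray(log10_input, float)

    def result(self) -> EfficiencyResult:
        return EfficiencyResult(
            assay_id=self.assay_id_,
            slope=self.slope_,
            efficiency_pct=self.efficiency_pct_,
            r_squared=self.r_squared_,
            pass_efficiency=self.pass_efficiency_,
            pass_linearity=self.pass_linearity_,
            dynamic_range=self.dynamic_range_,
        )


def fit_standard_curve(curve: StandardCurve, average_replicates: bool = True) -> EfficiencyResult:
    """Fit one standard curve and return its :class:`EfficiencyResult`."""
    return StandardCurveEfficiency(average_replicates).fit(curve).result()


def classify_assays(results: Iterable[EfficiencyResult]) -> pd.DataFrame:
    """Per-assay pass/fail QC report with summary flags.

    Assays out of the 90-110% efficiency window or below R^2 = 0.98 are
    annotated (``fail_efficiency`` / ``fail_linearity``), never dropped.
    """
    results = list(results)
    if not results:
        raise ValueError("classify_assays needs at least one EfficiencyResult")
    rows = []
    for r in results:
        flags = []
        if not r.pass_efficiency:
            flags.append("fail_efficiency")
        if not r.pass_linearity:
            flags.append("fail_linearity")
        rows.append(
            dict(
                assay_id=r.assay_id,
                slope=r.slope,
                efficiency_pct=r.efficiency_pct,
                r_squared=r.r_squared,
                pass_efficiency=r.pass_efficiency,
                pass_linearity=r.pass_linearity,
                flags=";".join(flags) or "pass",
            )
        )
    return pd.DataFrame(rows)


def read_standard_curves(path, dilution_factors: dict[str, float], dialect: str = "\t") -> list[StandardCurve]:
    """Read curves from a delimited file: assay_id, dilution_step, replicate, cq."""
    df = pd.read_csv(path, sep=dialect)
    curves = []
    for aid, grp in df.groupby("assay_id", sort=True):
        pts = tuple((int(s), float(c)) for s, c in zip(grp["dilution_step"], grp["cq"]))
        curves.append(StandardCurve(str(aid), pts, dilution_factors[str(aid)]))
    return curves
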