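"""ΔCq relative expression, fold changes and nonparametric group tests.

A reference scheme names 1-3 reference assays; the combined reference Cq of a
sample is their arithmetic mean (the geometric mean of the linear-scale
quantities). Per sample,

    dCq = Cq_target - Cq_ref,    relative quantity = 2^(-dCq)

assuming 100% amplification efficiency (base 2; an efficiency-corrected base
1+E per assay can be supplied). Group contrasts use

    fold change(A, B) = 2^(-(mean dCq_A - mean dCq_B))

and the Mann-Whitney U test for independent groups, with significance stars
* p <= 0.05, ** p <= 0.01, *** p <= 0.001. Samples missing any scheme assay
(undetermined) are excluded for that scheme and reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CqTable

__all__ = [
    "ReferenceScheme",
    "RelativeExpression",
    "GroupComparison",
    "combined_reference_cq",
    "relative_expression",
    "fold_change",
    "mann_whitney",
    "stars_for_p",
    "group_contrast",
]

#: Enumeration is used for the exact two-sided p when the pooled sample is
#: this small and tie-free; larger or tied samples use the normal
#: approximation with tie and continuity corrections.
EXACT_MAX_POOLED_N = 12


@dataclass(frozen=True)
class ReferenceScheme:
    """A named combination of 1-3 reference assays (mean-Cq combination)."""

    name: str
    reference_assays: tuple[str, ...]
    combine_rule: str = "mean_cq"

    def __post_init__(self) -> None:
        if not 1 <= len(self.reference_assays) <= 3:
            raise ValueError("a reference scheme uses 1-3 assays")
        if self.combine_rule != "mean_cq":
            raise ValueError(f"unknown combine rule {self.combine_rule!r}")


@dataclass
class RelativeExpression:
    """Per-sample ΔCq and relative quantity under one scheme."""

    scheme: ReferenceScheme
    target: str
    delta_cq: pd.Series  # indexed by sample_id
    rel_quantity: pd.Series
    excluded_samples: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GroupComparison:
    contrast: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str
    fold_change: float


def stars_for_p(p: float) -> str:
    """Significance stars with closed thresholds (p = 0.05 earns '*')."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def combined_reference_cq(cq_by_assay: dict[str, float], scheme: ReferenceScheme) -> float:
    """Arithmetic-mean combined reference Cq for one sample.

    Raises KeyError if any scheme assay is missing (the caller excludes the
    sample for this scheme).
    """
    vals = [cq_by_assay[a] for a in scheme.reference_assays]
    if any(v is None or not math.isfinite(v) for v in vals):
        raise KeyError("undetermined reference assay")
    return float(np.mean(vals))


def relative_expression(
    table: CqTable, target: str, scheme: ReferenceScheme, base: float = 2.0
) -> RelativeExpression:
    """Per-sample ΔCq and base^(-ΔCq) for one target under one scheme.

    Samples with the target or any reference undetermined are excluded and
    listed in ``excluded_samples``.
    """
    wide = table.wide()
    needed = list(dict.fromkeys([target, *scheme.reference_assays]))
    missing = [c for c in needed if c not in wide.columns]
    if missing:
        raise KeyError(f"assays not in table: {missing}")
    ok = wide[needed].notna().all(axis=1)
    if not ok.any():
        raise ValueError("no samples with target and all references determined")
    ref = wide.loc[ok, list(scheme.reference_assays)].mean(axis=1)
    dcq = wide.loc[ok, target] - ref
    return RelativeExpression(
        scheme=scheme,
        target=target,
        delta_cq=dcq.rename("delta_cq"),
        rel_quantity=(base ** (-dcq)).rename("rel_quantity"),
        excluded_samples=sorted(wide.index[~ok]),
    )


def fold_change(
    relexpr: RelativeExpression,
    groups: pd.Series,
    contrast: tuple[str, str],
    base: float = 2.0,
) -> float:
    """base^(-(mean dCq_A - mean dCq_B)) for contrast (A, B).

    ``groups`` maps sample_id -> group label. Equivalent to the ratio of
    group geometric-mean relative quantities.
    """
    a, b = contrast
    g = groups.reindex(relexpr.delta_cq.index)
    da = relexpr.delta_cq[g == a]
    db = relexpr.delta_cq[g == b]
    if len(da) == 0 or len(db) == 0:
        raise ValueError(f"empty group in contrast {contrast}")
    return float(base ** (-(da.mean() - db.mean())))


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p for tie-free samples via scipy's
    exact null distribution (full enumeration over rank assignments)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    contrast: str = "A vs B",
    fold: float = float("nan"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Exact p by enumeration when n1 + n2 <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction. Identical constant samples give U = n1*n2/2 and
    p = 1.
    """
    x = np.asarray(list(group_a), float)
    y = np.asarray(list(group_b), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        u, p = x.size * y.size / 2.0, 1.0
    else:
        tie_free = np.unique(pooled).size == pooled.size
        if x.size + y.size <= EXACT_MAX_POOLED_N and tie_free:
            u, p = _exact_two_sided_p(x, y)
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return GroupComparison(
        contrast=contrast,
        n_a=int(x.size),
        n_b=int(y.size),
        u_statistic=float(u),
        p_value=float(p),
        stars=stars_for_p(p),
        fold_change=float(fold),
    )


def group_contrast(
    table: CqTable,
    target: str,
    scheme: ReferenceScheme,
    group_field: str = "group",
    contrast: tuple[str, str] = ("DSS", "control"),
    base: float = 2.0,
) -> GroupComparison:
    """Fold change plus Mann-Whitney comparison for one contrast."""
    rel = relative_expression(table, target, scheme, base)
    groups = table.meta_frame()[group_field]
    fc = fold_change(rel, groups, contrast, base)
    g = groups.reindex(rel.delta_cq.index)
    a, b = contrast
    return mann_whitney(
        rel.delta_cq[g == a], rel.delta_cq[g == b],
        contrast=f"{target} ({scheme.name}): {a} vs {b}", fold=fc,
    )
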