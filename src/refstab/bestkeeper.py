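"""BestKeeper-style descriptive stability scoring.

For each candidate reference gene and stratum of samples, compute descriptive
statistics of the raw Cq values — geometric and arithmetic mean, min, max,
median, standard deviation and coefficient of variation — and rank genes by
SD (lowest SD = most stable). A gene with SD > 1 cycle is flagged as
inconsistently expressed.

Two dispersion conventions are offered: the sample standard deviation
(``"sample"``, n-1 denominator; the default) and the mean absolute deviation
from the arithmetic mean (``"mad"``), the dispersion statistic of the original
BestKeeper spreadsheet. Results report which convention was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cq_data import CqTable, stratify

__all__ = [
    "BestKeeperResult",
    "BestKeeperStability",
    "bestkeeper_descriptives",
    "rank_by_sd",
    "SD_CONSISTENCY_LIMIT",
]

#: SD above this many cycles flags a gene as inconsistently expressed.
SD_CONSISTENCY_LIMIT = 1.0


@dataclass(frozen=True)
class BestKeeperResult:
    assay_id: str
    stratum: str
    n: int
    geo_mean_cq: float
    arith_mean_cq: float
    min_cq: float
    max_cq: float
    median_cq: float
    sd_cq: float
    cv_pct: float
    consistent: bool
    rank: int | None = None


def _dispersion(values: np.ndarray, convention: str) -> float:
    if convention == "sample":
        return float(np.std(values, ddof=1))
    if convention == "mad":
        return float(np.mean(np.abs(values - values.mean())))
    raise ValueError(f"unknown SD convention {convention!r}")


def bestkeeper_descriptives(
    cq_values: Iterable[float],
    assay_id: str = "",
    stratum: str = "",
    sd_convention: str = "sample",
) -> BestKeeperResult:
    """Descriptive stability statistics for one gene in one stratum.

    Requires >= 2 determined, strictly positive Cq values. The geometric mean
    is exp(mean(ln Cq)) and CV% is 100 * SD / arithmetic mean.
    """
    v = np.asarray(list(cq_values), float)
    if v.size < 2:
        raise ValueError("bestkeeper_descriptives needs >= 2 Cq values")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("Cq values must be positive and finite")
    sd = _dispersion(v, sd_convention)
    am = float(v.mean())
    return BestKeeperResult(
        assay_id=assay_id,
        stratum=stratum,
        n=int(v.size),
        geo_mean_cq=float(np.exp(np.mean(np.log(v)))),
        arith_mean_cq=am,
        min_cq=float(v.min()),
        max_cq=float(v.max()),
        median_cq=float(np.median(v)),
        sd_cq=sd,
        cv_pct=100.0 * sd / am,
        consistent=bool(sd <= SD_CONSISTENCY_LIMIT),
    )


class BestKeeperStability(BaseEstimator):
    """Rank genes by Cq dispersion within each stratum.

    Parameters
    ----------
    sd_convention : {"sample", "mad"}, default "sample"

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        One row per (stratum, gene) with all descriptives and the rank
        (1 = lowest SD; ties broken by lower CV%, then assay_id).
    ranking_ : dict[str, list[str]]
        Gene order per stratum, most stable first.
    consensus_rank_ : pandas.Series
        Mean of per-stratum ranks per gene (a convenience summary of ours,
        not part of the original method).
    """

    def __init__(self, sd_convention: str = "sample"):
        self.sd_convention = sd_convention

    def fit(
        self,
        X: pd.DataFrame,
        strata: Mapping[str, Sequence[str]] | None = None,
    ) -> "BestKeeperStability":
        """Fit on a samples x genes Cq matrix (NaN = undetermined/excluded).

        ``strata`` maps stratum label -> sample ids; default is a single
        stratum "all" containing every row of ``X``.
        """
        if strata is None:
            strata = {"all": list(X.index)}
        rows = []
        for label, ids in strata.items():
            sub = X.loc[[i for i in ids if i in X.index]]
            stratum_size = len(sub)
            for gene in X.columns:
                vals = sub[gene].dropna().to_numpy(float)
                r = bestkeeper_descriptives(vals, gene, str(label), self.sd_convention)
                d = vars(r).copy()
                d["n_excluded"] = stratum_size - r.n
                rows.append(d)
        df = pd.DataFrame(rows)
        # rank ascending by SD; ties -> lower CV%, then assay_id
        df = df.sort_values(["stratum", "sd_cq", "cv_pct", "assay_id"]).reset_index(drop=True)
        df["rank"] = df.groupby("stratum").cumcount() + 1
        self.results_ = df
        self.ranking_ = {
            s: list(g.sort_values("rank")["assay_id"]) for s, g in df.groupby("stratum")
        }
        self.consensus_rank_ = (
            df.groupby("assay_id")["rank"].mean().sort_values()
        )
        return self


def rank_by_sd(
    table: CqTable,
    genes: Sequence[str],
    strata_by: Sequence[str] = (),
    sd_convention: str = "sample",
) -> pd.DataFrame:
    """Per-stratum BestKeeper descriptives and ranks for a merged CqTable.

    ``strata_by`` names metadata fields (e.g. ``("group",)`` or
    ``("group", "sex")``); empty means a single stratum of all samples.
    Undetermined samples are excluded per gene, with the usable n reported.
    """
    wide = table.wide()[list(genes)]
    if strata_by:
        parts = stratify(table, strata_by)
        strata = {
            "/".join(map(str, key)): list(sub.meta) for key, sub in parts.items()
        }
    else:
        strata = {"all": list(wide.index)}
    est = BestKeeperStability(sd_convention).fit(wide, strata)
    return est.results_
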