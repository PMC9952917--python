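"""Model-based reference-gene stability (NormFinder-style).

The model treats the log-scale expression (here: Cq, which is -log2
abundance up to a constant; stability is invariant to the global sign) of
gene i in sample j of group g as

    y_igj = alpha_ig + beta_gj + eps_igj,      eps_igj ~ N(0, sigma2_ig)

i.e. a gene-by-group mean, a sample-specific effect shared by all genes
(overall RNA amount/quality of that sample), and gene- and group-specific
noise. Stability of a gene combines two sources of variation:

* intragroup: the gene-specific noise variance sigma2_ig, estimated from the
  two-way-centered residuals with an unbiased correction for the fact that k
  genes share each sample effect. With S_ig the per-gene mean squared
  residual (n_g - 1 denominator), E[S_ig] = sigma2_ig (k-2)/k + sigma2bar_g/k,
  so sigma2bar_g = sum_i S_ig / (k-1) and
  sigma2_ig = max(0, (S_ig - sigma2bar_g/k) * k/(k-2)).
* intergroup: the deviation d_ig of the gene's group mean from its overall
  mean (doubly centered across genes and groups, so systematic group
  differences common to all genes — which normalization would remove — do
  not count). The d_ig are shrunken toward zero in empirical-Bayes fashion
  by their sampling variance v_ig = sigma2_ig / n_ig, with the between-gene
  variance of true deviations gamma2 estimated from the spread of the d_ig.

The stability value of gene i is the group average of

    |d_ig * gamma2 / (gamma2 + v_ig)| + sqrt(v_ig)

— lower is more stable. The noise penalty is the unshrunken intragroup
standard error, so a gene can never improve its score by being noisy. The best two-gene combination averages the two
genes' intergroup deviations and halves the averaged intragroup noise (the
variance of a mean of two independent errors), with prior variance gamma2/2
for the averaged deviation, and is found by exhaustive pair search.

At least three candidate genes are required (k >= 3; the variance correction
is undefined otherwise) and every group needs >= 2 samples. Undetermined
entries are excluded pairwise (per-gene n reported); the two-way centering
then alternates to convergence instead of closing in one pass.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cq_data import CqTable

__all__ = [
    "NormFinderStability",
    "normfinder_stability",
    "normfinder_single_group",
    "best_two_gene_combination",
]


def _two_way_center(X: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Residuals after removing sample (row) and gene (column) effects.

    For complete data one alternation is exact; with missing entries the
    row/column nan-means are alternated to convergence.
    """
    R = X.copy()
    for _ in range(max_iter):
        col = np.nanmean(R, axis=0)
        R = R - col[None, :]
        row = np.nanmean(R, axis=1)
        R = R - row[:, None]
        if np.nanmax(np.abs(np.nanmean(R, axis=0))) < tol:
            break
    return R


def _group_variances(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased gene-specific noise variances for one group's samples x genes.

    Returns (sigma2 per gene, n per gene). Negative corrected estimates are
    floored at zero.
    """
    n, k = X.shape
    if k < 3:
        raise ValueError("NormFinder needs >= 3 candidate genes")
    n_i = np.sum(~np.isnan(X), axis=0)
    if n < 2 or np.any(n_i < 2):
        raise ValueError("every group needs >= 2 samples per gene")
    R = _two_way_center(X)
    S = np.nansum(R**2, axis=0) / (n_i - 1)
    sbar = S.sum() / (k - 1)
    sigma2 = np.clip((S - sbar / k) * k / (k - 2), 0.0, None)
    return sigma2, n_i


class NormFinderStability(BaseEstimator):
    """Model-based stability values, ranking and best two-gene combination.

    Parameters
    ----------
    negate : bool, default False
        Negate Cq to log-expression orientation first. Stability values are
        invariant to the global sign; the flag only affects the sign of the
        reported intergroup deviations.

    Attributes (after :meth:`fit`)
    ------------------------------
    genes_ : list of gene names (column order)
    stability_ : pandas.Series, stability value per gene (lower = stabler)
    ranking_ : list of genes, most stable first (ties broken by name)
    best_gene_ : str
    intragroup_variance_ : DataFrame gene x group, cycles^2
    intergroup_deviation_ : DataFrame gene x group (signed, cycles)
    gamma2_ : float, estimated variance of true intergroup deviations
    n_ : DataFrame gene x group, samples used (pairwise exclusion)
    best_pair_ : (gene, gene) or None (single-group mode)
    best_pair_stability_ : float or None
    """

    def __init__(self, negate: bool = False):
        self.negate = negate

    # -- core fit --------------------------------------------------------
    def fit(self, X: pd.DataFrame, groups: Sequence | None = None) -> "NormFinderStability":
        """Fit on a samples x genes Cq matrix; ``groups`` aligns with rows.

        With ``groups=None`` the single-group degenerate mode is used:
        stability is the square root of the estimated gene-specific noise
        variance, with no intergroup terms.
        """
        X = X.astype(float)
        self.genes_ = list(X.columns)
        k = len(self.genes_)
        if k < 3:
            raise ValueError("NormFinder needs >= 3 candidate genes")
        M = X.to_numpy(float)
        if self.negate:
            M = -M

        if groups is None:
            sigma2, n_i = _group_variances(M)
            self.single_group_ = True
            self.intragroup_variance_ = pd.DataFrame({"all": sigma2}, index=self.genes_)
            self.intergroup_deviation_ = pd.DataFrame({"all": np.zeros(k)}, index=self.genes_)
            self.n_ = pd.DataFrame({"all": n_i}, index=self.genes_)
            self.gamma2_ = 0.0
            stab = np.sqrt(sigma2)
            self.best_pair_ = None
            self.best_pair_stability_ = None
        else:
            groups = np.asarray(groups)
            if len(groups) != len(X):
                raise ValueError("groups must align with the rows of X")
            labels = sorted(pd.unique(groups))
            G = len(labels)
            if G < 2:
                raise ValueError("need >= 2 groups (or groups=None for single-group mode)")
            self.single_group_ = False
            sigma2 = np.empty((k, G))
            n_ig = np.empty((k, G), dtype=int)
            A = np.empty((k, G))
            for g, lab in enumerate(labels):
                sub = M[groups == lab]
                s2, n_i = _group_variances(sub)
                sigma2[:, g] = s2
                n_ig[:, g] = n_i
                A[:, g] = np.nanmean(sub, axis=0)
            # doubly centered gene x group mean deviations
            d = A - A.mean(axis=1, keepdims=True) - A.mean(axis=0, keepdims=True) + A.mean()
            v = sigma2 / n_ig
            gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (G - 1)) - v.mean())
            stab = self._stability_from(d, v, gamma2).mean(axis=1)
            self.intragroup_variance_ = pd.DataFrame(sigma2, index=self.genes_, columns=labels)
            self.intergroup_deviation_ = pd.DataFrame(d, index=self.genes_, columns=labels)
            self.n_ = pd.DataFrame(n_ig, index=self.genes_, columns=labels)
            self.gamma2_ = float(gamma2)
            self._d, self._v = d, v
            self._find_best_pair()

        self.stability_ = pd.Series(stab, index=self.genes_, name="stability")
        order = sorted(self.genes_, key=lambda g: (self.stability_[g], g))
        self.ranking_ = order
        self.best_gene_ = order[0]
        return self

    @staticmethod
    def _stability_from(d: np.ndarray, v: np.ndarray, gamma2: float) -> np.ndarray:
        """Per-(gene, group) stability: |shrunken d| + intragroup SE.

        The deviation is shrunk by its sampling variance (genes measured
        noisily cannot fake a large systematic deviation) but the noise
        penalty stays the unshrunken standard error sqrt(sigma2/n), so a
        noisier gene is never rewarded for its noise.
        """
        shrink = gamma2 / (gamma2 + v) if gamma2 > 0 else np.zeros_like(v)
        return np.abs(d * shrink) + np.sqrt(v)

    def _pair_stability(self, i: int, j: int) -> float:
        d = (self._d[i] + self._d[j]) / 2.0
        v = (self._v[i] + self._v[j]) / 4.0
        return float(self._stability_from(d, v, self.gamma2_ / 2.0).mean())

    def _find_best_pair(self) -> None:
        best, best_val = None, np.inf
        for i, j in itertools.combinations(range(len(self.genes_)), 2):
            val = self._pair_stability(i, j)
            pair = (self.genes_[i], self.genes_[j])
            if val < best_val or (val == best_val and (best is None or pair < best)):
                best, best_val = pair, val
        self.best_pair_ = best
        self.best_pair_stability_ = best_val

    def pair_stabilities(self) -> pd.Series:
        """Combined stability for every gene pair (two-group mode only)."""
        if self.single_group_:
            raise ValueError("pair stabilities require grouped mode")
        vals = {}
        for i, j in itertools.combinations(range(len(self.genes_)), 2):
            vals[(self.genes_[i], self.genes_[j])] = self._pair_stability(i, j)
        return pd.Series(vals).sort_values()

    def report(self) -> pd.DataFrame:
        """Per-gene summary table (stability, rank, per-group components)."""
        df = pd.DataFrame({"stability": self.stability_})
        df["rank"] = [self.ranking_.index(g) + 1 for g in df.index]
        for g in self.intragroup_variance_.columns:
            df[f"intragroup_var[{g}]"] = self.intragroup_variance_[g]
            df[f"intergroup_dev[{g}]"] = self.intergroup_deviation_[g]
            df[f"n[{g}]"] = self.n_[g]
        return df.sort_values("rank")


# ---------------------------------------------------------------------------
# Function wrappers over CqTable
# ---------------------------------------------------------------------------

def normfinder_stability(
    table: CqTable, genes: Sequence[str], group_field: str = "group"
) -> NormFinderStability:
    """Fit the grouped stability model on a merged CqTable."""
    wide = table.wide()[list(genes)]
    meta = table.meta_frame().loc[wide.index]
    return NormFinderStability().fit(wide, meta[group_field].to_numpy())


def normfinder_single_group(table: CqTable, genes: Sequence[str]) -> NormFinderStability:
    """Degenerate no-grouping mode: stability = gene noise SD."""
    wide = table.wide()[list(genes)]
    return NormFinderStability().fit(wide, groups=None)


def best_two_gene_combination(result: NormFinderStability) -> tuple[tuple[str, str], float]:
    """The exhaustively-searched best pair and its combined stability."""
    if result.best_pair_ is None:
        raise ValueError("best pair requires grouped mode")
    return result.best_pair_, result.best_pair_stability_
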