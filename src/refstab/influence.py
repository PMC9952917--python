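"""Multivariate factor-influence analysis: design PCA and PLS modeling.

The inter/intra-experimental factors of a designed animal study — experiment
label (E1-E9), sex, DSS treatment (concentration, duration), duration of
inflammation and histology category — are coded into a centered,
unit-variance design matrix (one-hot for categoricals, numeric as-is; with
the default study structure this yields 20 factor/factor-level columns).

Two stages:

* PCA of the design evaluates how well the samples were randomized over the
  factors: with perfectly balanced, uncorrelated factors every component
  explains an equal share, so the number of components needed to reach 96%
  or 99.9% cumulative explained variance (relative to the total column
  count) measures the collinearity of the design.

* PLS regression predicts a response — absolute Cq of a target assay, or
  its ΔCq under a normalization scheme — from the design. The model is
  validated by R² (in-sample), Q² (K-fold cross-validated, 1 - PRESS/TSS)
  and a response-permutation test. Per-factor influence is read from the
  regression-coefficient-space loadings: fold submodels provide a jackknife
  mean and SD per factor (sign-aligned to the full model), means are
  normalized so their squares sum to one, and a factor is significant when
  its loading SD does not exceed |mean| (an SD larger than the mean marks
  the loading, hence the factor, as non-significant).

R² and Q² are invariant to affine rescaling of the response, so they are
identical on the scaled and raw response spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .cq_data import CqTable, HISTOLOGY_CATEGORIES
from .normalization import ReferenceScheme, relative_expression

__all__ = [
    "FactorDesign",
    "PCARandomization",
    "PLSInfluence",
    "PLSInfluenceReport",
    "build_design",
    "pca_randomization",
    "pls_fit",
    "cross_validated_q2",
    "loading_significance",
    "permutation_test",
    "influence_comparison",
    "DEFAULT_FACTORS",
]

DEFAULT_FACTORS = (
    "experiment",
    "sex",
    "dss_concentration",
    "dss_duration",
    "inflammation_duration",
    "histology",
)

CATEGORICAL_FACTORS = {"experiment", "sex", "group", "histology"}


@dataclass
class FactorDesign:
    """Centered, unit-variance factor/factor-level design matrix."""

    X: pd.DataFrame  # samples x scaled columns
    means: pd.Series
    sds: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class PCARandomization:
    explained_variance_ratio: np.ndarray
    cumulative: np.ndarray
    total_factor_count: int

    def n_components_at(self, threshold: float) -> int:
        """Smallest m with cumulative explained variance >= threshold."""
        return int(np.searchsorted(self.cumulative, threshold - 1e-12) + 1)


def build_design(
    meta: pd.DataFrame, factors: Sequence[str] = DEFAULT_FACTORS
) -> FactorDesign:
    """Code metadata into the scaled design matrix.

    Categorical factors are one-hot expanded over their full level sets (all
    levels kept: the blocks row-sum to 1, collinearity is PLS/PCA-safe);
    numeric factors enter as single columns. Columns are ordered
    deterministically by factor then level. Constant columns are dropped
    with a warning.
    """
    blocks: list[pd.DataFrame] = []
    for f in factors:
        if f not in meta.columns:
            raise KeyError(f"metadata has no factor {f!r}")
        col = meta[f]
        if f in CATEGORICAL_FACTORS:
            if f == "histology":
                levels = list(HISTOLOGY_CATEGORIES)
                unknown = set(col) - set(levels)
                if unknown:
                    raise ValueError(f"unknown histology categories {sorted(unknown)}")
            elif f == "sex":
                levels = ["female", "male"]
            else:
                levels = sorted(col.unique())
            oh = pd.DataFrame(
                {f"{f}={lv}": (col == lv).astype(float) for lv in levels},
                index=meta.index,
            )
            blocks.append(oh)
        else:
            blocks.append(col.astype(float).to_frame(f))
    raw = pd.concat(blocks, axis=1)
    sds = raw.std(ddof=1)
    dropped = list(raw.columns[sds == 0])
    if dropped:
        warnings.warn(f"dropping constant design columns: {dropped}")
    raw = raw.drop(columns=dropped)
    means = raw.mean()
    sds = raw.std(ddof=1)
    X = (raw - means) / sds
    return FactorDesign(X=X, means=means, sds=sds, dropped=dropped)


def pca_randomization(design: FactorDesign) -> PCARandomization:
    """Explained-variance spectrum of the scaled design."""
    X = design.X.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 columns")
    pca = PCA(n_components=min(X.shape)).fit(X)
    ratios = pca.explained_variance_ratio_
    return PCARandomization(
        explained_variance_ratio=ratios,
        cumulative=np.cumsum(ratios),
        total_factor_count=design.n_columns,
    )


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> dict:
    """Latent-component PLS fit; returns scores, weights, coefficients, r2.

    With orthonormal X and full components the coefficients coincide with
    the multiple-regression (OLS) solution.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    model = PLSRegression(n_components=n_components, scale=False).fit(X, y[:, None])
    yhat = model.predict(X).ravel()
    return dict(
        model=model,
        scores=model.x_scores_,
        weights=model.x_weights_,
        coefficients=model.coef_.ravel(),
        fitted=yhat,
        r2=_r2(y, yhat),
    )


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded permutation split into n_folds near-equal folds."""
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= n_folds <= n_samples")
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def cross_validated_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Q² = 1 - PRESS/TSS over held-out K-fold predictions."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if folds is None:
        folds = _fold_indices(n, n_folds, np.random.default_rng(seed))
    pred = np.empty(n)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        ncomp = min(n_components, len(train) - 1, X.shape[1])
        m = PLSRegression(n_components=ncomp, scale=False).fit(X[train], y[train, None])
        pred[test] = m.predict(X[test]).ravel()
    press = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss, pred


@dataclass
class PLSInfluenceReport:
    """Per-factor influence of one PLS model (one response, one scheme)."""

    response: str
    n_components: int
    factors: pd.DataFrame  # loading_mean, loading_sd, normalized_loading/sd, significant
    r2: float
    q2: float
    permutation: dict | None = None  # n_perm, r2_null, q2_null, passed

    def summed_loading(self, prefix: str) -> float:
        """Sum of |normalized loading means| over factor columns starting
        with ``prefix`` (e.g. 'experiment=')."""
        sel = self.factors.index.str.startswith(prefix)
        return float(self.factors.loc[sel, "normalized_loading"].abs().sum())


class PLSInfluence(BaseEstimator):
    """PLS factor-influence model with loading significance and validation.

    Parameters
    ----------
    n_components : int or "auto"
        "auto" keeps adding components while Q² improves by more than 0.01.
    n_folds : int, default 7
    n_perm : int, default 100
        Response permutations for the validation test (minimum 20).
    random_state : int, default 0
    run_permutation : bool, default True

    Attributes (after :meth:`fit`)
    ------------------------------
    n_components_, coefficients_, r2_, q2_, loading_mean_, loading_sd_,
    normalized_loading_, significant_, ambiguous_sign_, permutation_
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        n_folds: int = 7,
        n_perm: int = 100,
        random_state: int = 0,
        run_permutation: bool = True,
    ):
        self.n_components = n_components
        self.n_folds = n_folds
        self.n_perm = n_perm
        self.random_state = random_state
        self.run_permutation = run_permutation

    # -- internals -------------------------------------------------------
    def _q2_for(self, X, y, ncomp, folds) -> float:
        return cross_validated_q2(X, y, ncomp, folds=folds)[0]

    def _select_components(self, X, y, folds) -> int:
        max_comp = min(X.shape[0] - 1, X.shape[1], int(np.linalg.matrix_rank(X)))
        best_n, best_q2 = 1, self._q2_for(X, y, 1, folds)
        for ncomp in range(2, max_comp + 1):
            q2 = self._q2_for(X, y, ncomp, folds)
            if q2 - best_q2 > 0.01:
                best_n, best_q2 = ncomp, q2
            else:
                break
        return best_n

    def fit(self, X: pd.DataFrame, y: np.ndarray, response: str = "response") -> "PLSInfluence":
        """Fit on a scaled design (DataFrame) and a response vector.

        The response is centered and scaled to unit variance internally;
        R²/Q² are unaffected by that scaling.
        """
        self.columns_ = list(X.columns) if hasattr(X, "columns") else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
        Xa = np.asarray(X, float)
        ya = np.asarray(y, float).ravel()
        if ya.std(ddof=0) == 0:
            raise ValueError("constant response")
        ys = (ya - ya.mean()) / ya.std(ddof=1)
        rng = np.random.default_rng(self.random_state)
        folds = _fold_indices(len(ys), self.n_folds, rng)

        ncomp = (
            self._select_components(Xa, ys, folds)
            if self.n_components == "auto"
            else int(self.n_components)
        )
        self.n_components_ = ncomp

        full = pls_fit(Xa, ys, ncomp)
        self.coefficients_ = pd.Series(full["coefficients"], index=self.columns_)
        self.r2_ = full["r2"]
        self.q2_, self.cv_predictions_ = cross_validated_q2(Xa, ys, ncomp, folds=folds)

        # jackknife loadings over the CV submodels, sign-aligned to the full fit
        coef_full = full["coefficients"]
        fold_coefs = []
        for test in folds:
            train = np.setdiff1d(np.arange(len(ys)), test)
            nc = min(ncomp, len(train) - 1, Xa.shape[1])
            sub = PLSRegression(n_components=nc, scale=False).fit(Xa[train], ys[train, None])
            c = sub.coef_.ravel()
            if np.dot(c, coef_full) < 0:
                c = -c
            fold_coefs.append(c)
        C = np.vstack(fold_coefs)
        mean = C.mean(axis=0)
        sd = C.std(axis=0, ddof=1)
        norm = float(np.sqrt(np.sum(mean**2)))
        if norm == 0:
            raise ValueError("degenerate model: all jackknife loading means are zero")
        self.loading_mean_ = pd.Series(mean, index=self.columns_)
        self.loading_sd_ = pd.Series(sd, index=self.columns_)
        self.normalized_loading_ = self.loading_mean_ / norm
        self.normalized_loading_sd_ = self.loading_sd_ / norm
        self.significant_ = self.loading_sd_ <= self.loading_mean_.abs()
        # near-zero full-model loadings make the sign alignment ambiguous
        scale = float(np.abs(coef_full).max())
        self.ambiguous_sign_ = pd.Series(
            np.abs(coef_full) < 1e-8 * max(scale, 1.0), index=self.columns_
        )

        self.permutation_ = None
        if self.run_permutation:
            self.permutation_ = permutation_test(
                Xa, ys, ncomp, n_perm=self.n_perm,
                seed=self.random_state, n_folds=self.n_folds,
                r2_obs=self.r2_, q2_obs=self.q2_,
            )
        self._response_label = response
        return self

    def report(self) -> PLSInfluenceReport:
        factors = pd.DataFrame(
            {
                "loading_mean": self.loading_mean_,
                "loading_sd": self.loading_sd_,
                "normalized_loading": self.normalized_loading_,
                "normalized_loading_sd": self.normalized_loading_sd_,
                "significant": self.significant_,
                "ambiguous_sign": self.ambiguous_sign_,
            }
        )
        return PLSInfluenceReport(
            response=self._response_label,
            n_components=self.n_components_,
            factors=factors,
            r2=self.r2_,
            q2=self.q2_,
            permutation=self.permutation_,
        )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_perm: int = 100,
    seed: int = 0,
    n_folds: int = 7,
    r2_obs: float | None = None,
    q2_obs: float | None = None,
) -> dict:
    """Response-permutation validation of a PLS model.

    The response is permuted ``n_perm`` times (seeded); R² and Q² are
    recomputed for each scrambled pairing. The model passes when the
    unpermuted R² and Q² both exceed the 95th percentile of their null
    distributions.
    """
    if n_perm < 20:
        raise ValueError("permutation test needs n_perm >= 20")
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    if r2_obs is None:
        r2_obs = pls_fit(X, y, n_components)["r2"]
    if q2_obs is None:
        folds = _fold_indices(len(y), n_folds, rng)
        q2_obs = cross_validated_q2(X, y, n_components, folds=folds)[0]
    r2_null = np.empty(n_perm)
    q2_null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        r2_null[i] = pls_fit(X, yp, n_components)["r2"]
        folds = _fold_indices(len(yp), n_folds, rng)
        q2_null[i] = cross_validated_q2(X, yp, n_components, folds=folds)[0]
    passed = bool(
        r2_obs > np.quantile(r2_null, 0.95) and q2_obs > np.quantile(q2_null, 0.95)
    )
    return dict(
        n_perm=n_perm, r2_obs=float(r2_obs), q2_obs=float(q2_obs),
        r2_null=r2_null, q2_null=q2_null, passed=passed,
    )


def loading_significance(
    X: pd.DataFrame,
    y: np.ndarray,
    n_components: int | str = "auto",
    n_folds: int = 7,
    seed: int = 0,
    response: str = "response",
    n_perm: int = 100,
    run_permutation: bool = True,
) -> PLSInfluenceReport:
    """Fit :class:`PLSInfluence` and return its report."""
    est = PLSInfluence(
        n_components=n_components, n_folds=n_folds, n_perm=n_perm,
        random_state=seed, run_permutation=run_permutation,
    ).fit(X, y, response=response)
    return est.report()


def influence_comparison(
    table: CqTable,
    target: str,
    schemes: Mapping[str, ReferenceScheme | None],
    factors: Sequence[str] = DEFAULT_FACTORS,
    n_components: int | str = "auto",
    n_folds: int = 7,
    n_perm: int = 100,
    seed: int = 0,
    run_permutation: bool = True,
) -> dict[str, PLSInfluenceReport]:
    """Like-for-like factor-influence reports across normalization schemes.

    ``schemes`` maps scheme label to a :class:`ReferenceScheme`, or to None
    for the absolute (unnormalized Cq) response. All models are fitted on the
    intersection of samples usable under every scheme, so factor loadings
    are directly comparable.
    """
    wide = table.wide()
    # common sample set: target plus every scheme's references determined
    usable = wide[target].notna()
    for sch in schemes.values():
        if sch is not None:
            for a in sch.reference_assays:
                usable &= wide[a].notna()
    ids = list(wide.index[usable])
    if not ids:
        raise ValueError("no samples usable under every scheme")
    sub = table.subset(ids)
    meta = sub.meta_frame()
    design = build_design(meta, factors)
    sub_wide = sub.wide().loc[design.X.index]
    out: dict[str, PLSInfluenceReport] = {}
    for label, sch in schemes.items():
        if sch is None:
            y = sub_wide[target].to_numpy(float)
            resp = f"{target} (absolute)"
        else:
            rel = relative_expression(sub, target, sch)
            y = rel.delta_cq.reindex(design.X.index).to_numpy(float)
            resp = f"{target} (dCq vs {sch.name})"
        out[label] = loading_significance(
            design.X, y, n_components=n_components, n_folds=n_folds,
            seed=seed, response=resp, n_perm=n_perm,
            run_permutation=run_permutation,
        )
    return out
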