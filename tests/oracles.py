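"""Independent brute-force oracles used to pin the fast implementations.

Each oracle recomputes a quantity through a deliberately different route:
explicit least squares on dummy designs, full enumeration, direct textbook
formulas — never through the package code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# BestKeeper descriptives: direct formulas
# ---------------------------------------------------------------------------

def bestkeeper_oracle(values: np.ndarray) -> dict:
    v = np.asarray(values, float)
    n = len(v)
    am = sum(v) / n
    sd = math.sqrt(sum((x - am) ** 2 for x in v) / (n - 1))
    return dict(
        geo_mean=math.exp(sum(math.log(x) for x in v) / n),
        arith_mean=am,
        sd=sd,
        cv_pct=100.0 * sd / am,
        median=float(np.median(v)),
    )


# ---------------------------------------------------------------------------
# Model-based stability: explicit least-squares two-way fit per group
# ---------------------------------------------------------------------------

def _group_residuals_lstsq(X: np.ndarray) -> np.ndarray:
    """Residuals of y_ij = alpha_i + beta_j via lstsq on a dummy design."""
    n, k = X.shape
    y = X.reshape(-1)  # sample-major: rows j, genes i flattened
    rows = []
    for j in range(n):
        for i in range(k):
            gene = np.zeros(k)
            gene[i] = 1.0
            sample = np.zeros(n)
            sample[j] = 1.0
            rows.append(np.concatenate([gene, sample]))
    Z = np.vstack(rows)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return (y - Z @ beta).reshape(n, k)


def normfinder_oracle(X: np.ndarray, groups: np.ndarray) -> dict:
    """Stability values via the explicit least-squares route.

    Same model and variance corrections as the package estimator, but
    residuals come from lstsq on a dummy design and every aggregation is an
    explicit loop.
    """
    X = np.asarray(X, float)
    labels = sorted(set(groups))
    n_samples, k = X.shape
    G = len(labels)
    sigma2 = np.zeros((k, G))
    v = np.zeros((k, G))
    A = np.zeros((k, G))
    for g, lab in enumerate(labels):
        sub = X[np.asarray(groups) == lab]
        n = sub.shape[0]
        R = _group_residuals_lstsq(sub)
        S = np.array([sum(R[j, i] ** 2 for j in range(n)) / (n - 1) for i in range(k)])
        sbar = sum(S) / (k - 1)
        for i in range(k):
            sigma2[i, g] = max(0.0, (S[i] - sbar / k) * k / (k - 2))
            v[i, g] = sigma2[i, g] / n
            A[i, g] = sum(sub[:, i]) / n
    grand = A.mean()
    d = np.zeros((k, G))
    for i in range(k):
        for g in range(G):
            d[i, g] = A[i, g] - A[i, :].mean() - A[:, g].mean() + grand
    gamma2 = max(0.0, float((d**2).sum()) / ((k - 1) * (G - 1)) - float(v.mean()))
    stab = np.zeros(k)
    for i in range(k):
        acc = 0.0
        for g in range(G):
            shrink = gamma2 / (gamma2 + v[i, g]) if gamma2 > 0 else 0.0
            acc += abs(d[i, g] * shrink) + math.sqrt(v[i, g])
        stab[i] = acc / G
    return dict(stability=stab, sigma2=sigma2, d=d, gamma2=gamma2, v=v)


def normfinder_pair_oracle(X: np.ndarray, groups: np.ndarray) -> dict:
    """Exhaustive pair stabilities from the oracle decomposition."""
    base = normfinder_oracle(X, groups)
    d, v, gamma2 = base["d"], base["v"], base["gamma2"]
    k, G = d.shape
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        gp = gamma2 / 2.0
        acc = 0.0
        for g in range(G):
            dp = (d[i, g] + d[j, g]) / 2.0
            vp = (v[i, g] + v[j, g]) / 4.0
            shrink = gp / (gp + vp) if gp > 0 else 0.0
            acc += abs(dp * shrink) + math.sqrt(vp)
        out[(i, j)] = acc / G
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney: full enumeration of group assignments
# ---------------------------------------------------------------------------

def mann_whitney_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for tie-free samples by enumerating every
    C(n1+n2, n1) assignment of the pooled values to group one."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires tie-free data"
    n1 = len(x)

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        return float(sum(1.0 for xi in a for yi in b if xi > yi))

    u_obs = u_stat(x, y)
    us = [
        u_stat(pooled[list(idx)], np.delete(pooled, list(idx)))
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


# ---------------------------------------------------------------------------
# OLS / eigen oracles for the multivariate stage
# ---------------------------------------------------------------------------

def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return beta


def pca_cumulative_oracle(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    return np.cumsum(eig) / eig.sum()
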