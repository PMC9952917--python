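import numpy as np
import pandas as pd
import pytest

from refstab.influence import (
    PLSInfluence,
    build_design,
    cross_validated_q2,
    influence_comparison,
    loading_significance,
    pca_randomization,
    permutation_test,
    pls_fit,
)
from refstab.normalization import ReferenceScheme
from oracles import ols_coefficients, pca_cumulative_oracle


def rand_design(rng, n=60, p=8):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])


# -- design building ---------------------------------------------------------

def test_default_study_design_has_20_factor_levels(wide_meta):
    _, meta = wide_meta
    design = build_design(meta)
    assert design.n_columns == 20
    # one-hot blocks row-sum to 1 before scaling
    exp_cols = [c for c in design.means.index if c.startswith("experiment=")]
    assert len(exp_cols) == 9
    # scaled columns are centered
    assert np.allclose(design.X.mean(), 0.0, atol=1e-12)


def test_constant_columns_dropped_with_warning(wide_meta):
    _, meta = wide_meta
    sub = meta[meta["experiment"] == "E1"]
    with pytest.warns(UserWarning, match="constant design columns"):
        design = build_design(sub)
    assert all(not c.startswith("experiment=E2") for c in design.X.columns)


def test_unknown_histology_rejected(wide_meta):
    _, meta = wide_meta
    bad = meta.copy()
    bad.iloc[0, bad.columns.get_loc("histology")] = "weird"
    with pytest.raises(ValueError, match="histology"):
        build_design(bad)


# -- PCA randomization -------------------------------------------------------

def test_isotropic_design_needs_every_component():
    c = 6
    X = pd.DataFrame(np.kron(np.eye(c), np.ones((10, 1))))  # balanced one-hot
    X = (X - X.mean()) / X.std(ddof=1)
    # drop one redundant column to make it full rank isotropic
    design = build_stub(X.iloc[:, :-1])
    pca = pca_randomization(design)
    assert np.allclose(pca.explained_variance_ratio.sum(), 1.0, atol=1e-10)
    assert pca.n_components_at(0.999) == c - 1


def build_stub(X):
    from refstab.influence import FactorDesign

    return FactorDesign(X=X, means=X.mean(), sds=X.std(ddof=1))


def test_duplicated_column_reduces_rank():
    rng = np.random.default_rng(0)
    X = rand_design(rng, p=5)
    X["dup"] = X["x0"]
    pca = pca_randomization(build_stub(X))
    assert pca.explained_variance_ratio[-1] == pytest.approx(0.0, abs=1e-12)


def test_component_counts_match_eigen_oracle():
    rng = np.random.default_rng(1)
    X = rand_design(rng, n=80, p=12)
    pca = pca_randomization(build_stub(X))
    cum = pca_cumulative_oracle(X.to_numpy())
    for thr in (0.5, 0.9, 0.96, 0.999):
        assert pca.n_components_at(thr) == int(np.searchsorted(cum, thr - 1e-12) + 1)
    assert pca.n_components_at(0.96) <= pca.n_components_at(0.999)


# -- PLS core ----------------------------------------------------------------

def test_perfect_predictor_gives_r2_one():
    # orthonormal columns: one latent component suffices for an exact fit
    rng = np.random.default_rng(2)
    M = rng.normal(size=(60, 8))
    M -= M.mean(axis=0)  # centering first keeps the QR basis mean-zero
    Q, _ = np.linalg.qr(M)
    y = Q[:, 3].copy()
    fit = pls_fit(Q, y, n_components=1)
    assert fit["r2"] == pytest.approx(1.0, abs=1e-10)
    assert np.argmax(np.abs(fit["coefficients"])) == 3


def test_orthogonal_response_gives_near_zero_r2():
    rng = np.random.default_rng(3)
    X = rand_design(rng, n=200)
    y = rng.normal(size=200)
    y -= X.to_numpy() @ ols_coefficients(X.to_numpy(), y)  # project out X
    fit = pls_fit(X.to_numpy(), y, n_components=2)
    assert fit["r2"] < 0.05


def test_full_component_fit_equals_ols():
    rng = np.random.default_rng(4)
    X = rand_design(rng, n=50, p=7)
    y = rng.normal(size=50)
    fit = pls_fit(X.to_numpy(), y, n_components=7)
    np.testing.assert_allclose(
        fit["coefficients"], ols_coefficients(X.to_numpy(), y), atol=1e-8
    )


def test_q2_limits():
    rng = np.random.default_rng(5)
    X = rand_design(rng, n=70, p=6)
    y = X.to_numpy() @ rng.normal(size=6)  # noiseless linear response
    q2, _ = cross_validated_q2(X.to_numpy(), y, n_components=6, n_folds=7, seed=0)
    assert q2 >= 0.999


def test_q2_nonpositive_for_pure_noise_and_below_r2():
    rng = np.random.default_rng(6)
    neg, le_r2 = 0, 0
    for seed in range(100):
        X = rand_design(rng, n=40, p=8)
        y = rng.normal(size=40)
        fit = pls_fit(X.to_numpy(), y, n_components=2)
        q2, _ = cross_validated_q2(X.to_numpy(), y, 2, n_folds=5, seed=seed)
        neg += q2 <= 0
        le_r2 += q2 <= fit["r2"]
    assert neg >= 90
    assert le_r2 >= 99


def test_fold_requirements():
    rng = np.random.default_rng(7)
    X = rand_design(rng, n=10, p=3)
    with pytest.raises(ValueError, match="n_folds"):
        cross_validated_q2(X.to_numpy(), rng.normal(size=10), 2, n_folds=1)
    with pytest.raises(ValueError, match="n_folds"):
        cross_validated_q2(X.to_numpy(), rng.normal(size=10), 2, n_folds=11)


# -- loading significance ----------------------------------------------------

def test_single_driver_is_significant_noise_is_not():
    sig_hits, noise_flags = 0, []
    rng = np.random.default_rng(8)
    for seed in range(100):
        X = rand_design(rng, n=60, p=6)
        y = 2.0 * X["x1"].to_numpy() + rng.normal(0, 0.3, 60)
        rep = loading_significance(
            X, y, n_components=2, n_folds=5, seed=seed, run_permutation=False
        )
        sig_hits += bool(rep.factors.loc["x1", "significant"])
        others = rep.factors.drop("x1")
        noise_flags.append(others["significant"].mean())
        assert (rep.factors["normalized_loading"] ** 2).sum() == pytest.approx(1.0, abs=1e-9)
    assert sig_hits >= 90
    assert np.mean(noise_flags) < 0.5  # noise factors mostly non-significant
    assert abs(rep.factors.loc["x1", "normalized_loading"]) > 0.9


def test_all_noise_model_usually_fails_permutation():
    """A pure-noise response yields a weak model that the permutation test
    rejects in the large majority of replicates (the pass rate stays near
    the nominal false-positive level)."""
    rng = np.random.default_rng(9)
    passes = 0
    for seed in range(10):
        X = rand_design(rng, n=50, p=8)
        y = rng.normal(size=50)
        rep = loading_significance(X, y, n_components=2, n_folds=5, seed=seed, n_perm=30)
        assert rep.r2 < 0.5
        passes += rep.permutation["passed"]
    assert passes <= 2


def test_permutation_detects_strong_signal():
    rng = np.random.default_rng(10)
    X = rand_design(rng, n=60, p=6)
    y = X.to_numpy() @ rng.normal(size=6) + rng.normal(0, 0.2, 60)
    perm = permutation_test(X.to_numpy(), y, n_components=3, n_perm=30, seed=0, n_folds=5)
    assert perm["passed"]
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(X.to_numpy(), y, 2, n_perm=10)


def test_reports_reproducible_bit_for_bit():
    rng = np.random.default_rng(11)
    X = rand_design(rng, n=40, p=5)
    y = X["x0"].to_numpy() + np.random.default_rng(1).normal(0, 0.5, 40)
    a = loading_significance(X, y, n_components=2, n_folds=4, seed=7, n_perm=20)
    b = loading_significance(X, y, n_components=2, n_folds=4, seed=7, n_perm=20)
    assert a.r2 == b.r2 and a.q2 == b.q2
    pd.testing.assert_frame_equal(a.factors, b.factors)
    np.testing.assert_array_equal(a.permutation["q2_null"], b.permutation["q2_null"])


# -- scheme comparison -------------------------------------------------------

def test_absolute_scheme_uses_raw_cq_and_identical_schemes_match(analysis_table):
    schemes = {
        "absolute": None,
        "ER": ReferenceScheme("ER", ("EEF2", "RPLP0")),
        "ER2": ReferenceScheme("ER2", ("EEF2", "RPLP0")),
    }
    reports = influence_comparison(
        analysis_table, "TNFR1", schemes, n_components=2, n_folds=5,
        run_permutation=False,
    )
    pd.testing.assert_frame_equal(reports["ER"].factors, reports["ER2"].factors)
    assert reports["absolute"].response.endswith("(absolute)")
    assert reports["absolute"].r2 != reports["ER"].r2


def test_normalization_shrinks_experiment_influence(analysis_table):
    reports = influence_comparison(
        analysis_table, "TNFR1",
        {"absolute": None, "ER": ReferenceScheme("ER", ("EEF2", "RPLP0"))},
        n_components=2, n_folds=5, run_permutation=False,
    )
    assert (
        reports["ER"].summed_loading("experiment=")
        < reports["absolute"].summed_loading("experiment=")
    )
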