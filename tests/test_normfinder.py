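import numpy as np
import pandas as pd
import pytest

from conftest import two_group_matrix
from refstab.normfinder import NormFinderStability, best_two_gene_combination
from oracles import normfinder_oracle, normfinder_pair_oracle


def fit(X, groups):
    return NormFinderStability().fit(X, groups)


def test_requires_three_genes_and_two_per_group():
    X = pd.DataFrame(np.random.default_rng(0).normal(26, 1, (6, 2)), columns=list("ab"))
    with pytest.raises(ValueError, match="3 candidate genes"):
        NormFinderStability().fit(X, ["A"] * 3 + ["B"] * 3)
    X3 = pd.DataFrame(np.random.default_rng(0).normal(26, 1, (4, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match=">= 2 samples"):
        NormFinderStability().fit(X3, ["A", "B", "B", "B"])


def test_constant_genes_all_tie_with_minimal_stability():
    X = pd.DataFrame(
        {"b": np.full(10, 26.0), "a": np.full(10, 30.0), "c": np.full(10, 28.0)}
    )
    est = fit(X, ["A"] * 5 + ["B"] * 5)
    assert np.allclose(est.stability_, est.stability_.iloc[0])
    assert est.ranking_ == ["a", "b", "c"]  # lexicographic tie-break
    assert est.best_gene_ == "a"


def test_matches_least_squares_oracle():
    rng = np.random.default_rng(42)
    for _ in range(25):
        X, groups = two_group_matrix(
            rng,
            noise_sds=rng.uniform(0.1, 1.5, 4),
            group_shifts=rng.normal(0, 1, 4),
            n_per_group=6,
        )
        est = fit(X, groups)
        o = normfinder_oracle(X.to_numpy(), groups)
        np.testing.assert_allclose(est.stability_.to_numpy(), o["stability"], atol=1e-8)
        np.testing.assert_allclose(
            est.intragroup_variance_.to_numpy(), o["sigma2"], atol=1e-8
        )


def test_location_invariance_per_gene():
    rng = np.random.default_rng(3)
    X, groups = two_group_matrix(rng, [0.3, 0.6, 0.9], [0.0, 0.5, -0.5])
    base = fit(X, groups).stability_
    shifted = X.copy()
    shifted["g1"] += 7.5  # constant shift of one gene everywhere
    np.testing.assert_allclose(fit(shifted, groups).stability_, base, atol=1e-10)


def test_global_sign_invariance():
    rng = np.random.default_rng(4)
    X, groups = two_group_matrix(rng, [0.2, 0.7, 1.1], [0.0, 1.0, -0.3])
    a = fit(X, groups).stability_
    b = NormFinderStability(negate=True).fit(X, groups).stability_
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_within_group_sample_permutation_invariance():
    rng = np.random.default_rng(5)
    X, groups = two_group_matrix(rng, [0.2, 0.5, 1.0], [0.0, 0.0, 1.0])
    base = fit(X, groups).stability_
    perm = np.concatenate(
        [rng.permutation(np.where(groups == g)[0]) for g in ("A", "B")]
    )
    permuted = fit(X.iloc[perm].reset_index(drop=True), groups[perm])
    np.testing.assert_allclose(permuted.stability_, base, atol=1e-10)


def test_noise_inflation_does_not_improve_stability():
    """Raising one gene's noise SD raises its stability value on average."""
    lo, hi = [], []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X, groups = two_group_matrix(rng, [0.3, 0.4, 0.4, 0.4], [1.0, 0.0, 0.0, 0.5])
        lo.append(fit(X, groups).stability_["g1"])
        rng = np.random.default_rng(seed)
        X2, groups = two_group_matrix(rng, [0.3, 1.2, 0.4, 0.4], [1.0, 0.0, 0.0, 0.5])
        hi.append(fit(X2, groups).stability_["g1"])
    assert np.mean(hi) > np.mean(lo)


def test_single_group_mode_recovers_noise_ordering():
    """The low-noise gene (SD 0.1) scores as more stable than the noisy
    gene (SD 1.0) in essentially every replicate."""
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        X, _ = two_group_matrix(rng, [0.1, 1.0, 0.4], [0.0, 0.0, 0.0])
        est = NormFinderStability().fit(X, groups=None)
        hits += est.stability_["g0"] < est.stability_["g1"]
    assert hits / 200 >= 0.99


def test_single_and_two_group_modes_agree_under_null():
    """When both groups come from one distribution the grouped mode picks
    the same most-stable gene as the pure-variance single-group mode in
    most replicates (the grouped intergroup terms are then pure noise)."""
    agree = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X, groups = two_group_matrix(rng, [0.1, 0.5, 1.5], [0.0, 0.0, 0.0])
        grouped = fit(X, groups).ranking_
        single = NormFinderStability().fit(X, groups=None).ranking_
        agree += grouped[0] == single[0]
    assert agree / 100 >= 0.75


def test_pair_of_identical_stable_genes_beats_or_ties_singles():
    rng = np.random.default_rng(8)
    n = 40
    groups = np.repeat(["A", "B"], n // 2)
    shared = 26.0 + rng.normal(0, 0.05, n)
    X = pd.DataFrame(
        {"t1": shared, "t2": shared + rng.normal(0, 0.01, n),
         "noisy": 28 + rng.normal(0, 1.0, n)}
    )
    est = fit(X, groups)
    pair = est.pair_stabilities()[("t1", "t2")]
    assert pair <= max(est.stability_["t1"], est.stability_["t2"]) + 1e-12


def test_opposite_group_shifts_cancel_in_pair():
    rng = np.random.default_rng(9)
    X, groups = two_group_matrix(
        rng, [0.2, 0.2, 0.2, 0.2], [1.5, -1.5, 0.0, 0.0], n_per_group=30
    )
    est = fit(X, groups)
    pair = est.pair_stabilities()[("g0", "g1")]
    assert pair < est.stability_["g0"]
    assert pair < est.stability_["g1"]


def test_exhaustive_pair_search_matches_oracle_enumeration():
    rng = np.random.default_rng(10)
    X, groups = two_group_matrix(
        rng, rng.uniform(0.1, 1.0, 5), rng.normal(0, 0.8, 5), n_per_group=10
    )
    est = fit(X, groups)
    oracle = normfinder_pair_oracle(X.to_numpy(), groups)
    genes = list(X.columns)
    mine = est.pair_stabilities()
    for (i, j), val in oracle.items():
        assert mine[(genes[i], genes[j])] == pytest.approx(val, abs=1e-8)
    best_idx = min(oracle, key=oracle.get)
    assert best_two_gene_combination(est)[0] == (genes[best_idx[0]], genes[best_idx[1]])


def test_dropping_censored_gene_keeps_best_choices():
    """On a panel with a clearly most-stable reference and a TBP-like
    censored assay, excluding the censored gene leaves the best gene and
    the best two-gene combination unchanged (the censored gene influences
    the others only through the shared centering)."""
    from refstab.simulate import GeneParams, GeneratorConfig, generate_study

    genes = (
        GeneParams("R1", "mRNA", "reference", 26.0, 0.20, 2.0, 0.10, 0.0, 0.25),
        GeneParams("R2", "mRNA", "reference", 27.0, 0.20, 2.2, 0.10, 0.0, 0.35),
        GeneParams("R3", "mRNA", "reference", 28.0, 0.20, 2.4, 0.40, 0.0, 0.90),
        GeneParams("R4", "mRNA", "reference", 29.0, 0.20, 2.6, 0.50, 0.0, 1.10),
        GeneParams("TBPish", "mRNA", "reference", 38.5, 0.20, 2.3, 0.30, 0.0, 1.20),
    )
    cfg = GeneratorConfig(genes=genes)
    agree_best = agree_pair = 0
    n_seeds = 10
    for seed in range(n_seeds):
        table = generate_study(cfg, seed=seed).analysis_table()
        wide = table.wide()
        groups = table.meta_frame().loc[wide.index, "group"].to_numpy()
        full = fit(wide[["R1", "R2", "R3", "R4", "TBPish"]], groups)
        assert wide["TBPish"].isna().any()  # the censored gene really censors
        reduced = fit(wide[["R1", "R2", "R3", "R4"]], groups)
        agree_best += full.best_gene_ == reduced.best_gene_
        agree_pair += set(full.best_pair_) == set(reduced.best_pair_)
        # the noisy genes never become the best choice in either panel
        assert full.best_gene_ in {"R1", "R2"} and reduced.best_gene_ in {"R1", "R2"}
    assert agree_best >= 8
    assert agree_pair >= 8
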