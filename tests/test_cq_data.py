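import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refstab.cq_data import (
    AssayInfo,
    CqTable,
    CqValidationError,
    SampleMeta,
    handle_undetermined,
    merge_replicates,
    read_cq_table,
    stratify,
    write_cq_table,
)

ASSAYS = {"EEF2": AssayInfo("EEF2", "mRNA", "reference")}
META = {
    "S1": SampleMeta("S1", "E1", "female", "control"),
    "S2": SampleMeta("S2", "E1", "male", "DSS", 2.5, 5, 7, "moderate"),
}


def _long_file(text: str) -> io.StringIO:
    return io.StringIO(text)


def test_read_long_merges_and_flags_undetermined():
    table, report = read_cq_table(
        _long_file(
            "sample_id\tassay_id\treplicate\tcq\n"
            "S1\tEEF2\t1\t26.0\nS1\tEEF2\t2\t26.2\n"
            "S2\tEEF2\t1\tUndetermined\nS2\tEEF2\t2\tUndetermined\n"
        ),
        META,
        ASSAYS,
    )
    merged = merge_replicates(table)
    row = merged.measurements.set_index("sample_id")
    assert row.loc["S1", "cq"] == pytest.approx(26.1)
    assert bool(row.loc["S2", "undetermined"]) and np.isnan(row.loc["S2", "cq"])
    assert (report["reason"] == "undetermined").sum() == 2


def test_missing_metadata_names_the_sample():
    with pytest.raises(CqValidationError, match="S9"):
        read_cq_table(
            _long_file("sample_id\tassay_id\treplicate\tcq\nS9\tEEF2\t1\t26.0\n"),
            META,
            ASSAYS,
        )


def test_cq_above_cycle_limit_rejected():
    with pytest.raises(CqValidationError, match="cycle limit"):
        read_cq_table(
            _long_file("sample_id\tassay_id\treplicate\tcq\nS1\tEEF2\t1\t46.0\n"),
            META,
            ASSAYS,
        )


@pytest.mark.parametrize(
    "reps, expected, flagged",
    [((26.0, 26.2), 26.1, False), ((26.0, 26.0), 26.0, False), ((24.0, 28.0), 26.0, True)],
)
def test_merge_rule_mean_and_discordance_flag(reps, expected, flagged):
    rows = [
        dict(sample_id="S1", assay_id="EEF2", replicate=i + 1, cq=c, undetermined=False)
        for i, c in enumerate(reps)
    ]
    table = CqTable(pd.DataFrame(rows), META, ASSAYS)
    merged = merge_replicates(table, discordance_sd_threshold=0.5)
    row = merged.measurements.iloc[0]
    assert row["cq"] == pytest.approx(expected)
    assert bool(row["discordant"]) is flagged


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    reps=st.lists(st.floats(min_value=10, max_value=40), min_size=2, max_size=4),
    seed=st.integers(0, 1000),
)
def test_merge_is_replicate_order_invariant(reps, seed):
    perm = np.random.default_rng(seed).permutation(len(reps))

    def build(values):
        rows = [
            dict(sample_id="S1", assay_id="EEF2", replicate=i + 1, cq=v, undetermined=False)
            for i, v in enumerate(values)
        ]
        return merge_replicates(CqTable(pd.DataFrame(rows), META, ASSAYS))

    a = build(reps).measurements.iloc[0]["cq"]
    b = build([reps[i] for i in perm]).measurements.iloc[0]["cq"]
    assert a == pytest.approx(b, abs=1e-12)


def test_undetermined_policies(analysis_table, default_study):
    merged = merge_replicates(default_study.cq_table)
    n_undet = int(merged.measurements["undetermined"].sum())
    excluded, report = handle_undetermined(merged, "exclude")
    assert len(excluded.measurements) == len(merged.measurements) - n_undet
    assert report["n_undetermined"].sum() == n_undet
    censored, _ = handle_undetermined(merged, "censor_at_limit")
    cens = censored.measurements[censored.measurements["censored"]]
    assert len(cens) == n_undet
    assert set(cens["cq"]) <= {40.0, 45.0}  # class cycle limits


def test_roundtrip_write_read_bit_identical(analysis_table, tmp_path):
    path = tmp_path / "cq.tsv"
    write_cq_table(analysis_table, path)
    back, _ = read_cq_table(
        path, analysis_table.meta, analysis_table.assays, layout="long"
    )
    merged_back = merge_replicates(back)
    a = analysis_table.measurements.sort_values(["sample_id", "assay_id"])["cq"].to_numpy()
    b = merged_back.measurements.sort_values(["sample_id", "assay_id"])["cq"].to_numpy()
    assert np.array_equal(a, b)  # exact, thanks to repr round-trip


def test_stratify_partitions_disjoint_exhaustive(analysis_table):
    strata = stratify(analysis_table, ["group", "sex"])
    sizes = {k: len(v.meta) for k, v in strata.items()}
    assert sizes == {
        ("DSS", "female"): 47, ("DSS", "male"): 50,
        ("control", "female"): 10, ("control", "male"): 10,
    }
    all_ids = [s for t in strata.values() for s in t.meta]
    assert sorted(all_ids) == sorted(analysis_table.meta)
    assert len(stratify(analysis_table, ["experiment"])) == 9


def test_control_sample_invariants_enforced():
    with pytest.raises(CqValidationError):
        SampleMeta("X", "E1", "female", "control", histology="mild")
    with pytest.raises(CqValidationError):
        SampleMeta("X", "E1", "female", "DSS", 2.5, 5, 0, "normal")
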