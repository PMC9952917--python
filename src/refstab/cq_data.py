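"""Data model and I/O for qPCR quantification-cycle (Cq) tables.

A study is a collection of Cq measurements (one or more technical replicates
per sample x assay reaction, some of them "undetermined", i.e. never crossing
the fluorescence threshold within the cycle limit) together with per-sample
experimental metadata (experiment label, sex, treatment group, DSS dose and
duration, duration of inflammation, histology category, fixation time).

The canonical on-disk layout is long format::

    sample_id  assay_id  replicate  cq

with ``Undetermined`` (or an empty cell) marking reactions with no detectable
amplification. A wide layout (one assay per column, replicates merged) is also
read and written. Metadata live in a separate delimited table keyed by
``sample_id``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "AssayInfo",
    "CqTable",
    "CqValidationError",
    "read_cq_table",
    "write_cq_table",
    "merge_replicates",
    "handle_undetermined",
    "stratify",
    "MRNA_CYCLE_LIMIT",
    "MIRNA_CYCLE_LIMIT",
    "HISTOLOGY_CATEGORIES",
]

#: Protocol cycle limits: 45 cycles for the mRNA assays, 40 for the miRNA
#: assays. A reaction whose Cq would exceed the limit is "undetermined".
MRNA_CYCLE_LIMIT = 45.0
MIRNA_CYCLE_LIMIT = 40.0

HISTOLOGY_CATEGORIES = (
    "normal",
    "mild",
    "moderate",
    "severe",
    "erosion",
    "heterogeneous",
)

UNDETERMINED_TOKENS = {"undetermined", "undet", "na", "nan", ""}


class CqValidationError(ValueError):
    """Raised when a Cq table violates a structural invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Experimental metadata for one FFPE sample (one mouse)."""

    sample_id: str
    experiment: str
    sex: str  # "female" | "male"
    group: str  # "control" | "DSS"
    dss_concentration: float = 0.0  # percent w/v; 0 for control
    dss_duration: float = 0.0  # days of DSS administration; 0 for control
    inflammation_duration: float = 0.0  # days of water after DSS (0-90)
    histology: str = "normal"
    fixation_time: float | None = None  # weeks
    storage_note: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise CqValidationError(f"unknown sex {self.sex!r} for {self.sample_id}")
        if self.group not in ("control", "DSS"):
            raise CqValidationError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.histology not in HISTOLOGY_CATEGORIES:
            raise CqValidationError(
                f"unknown histology {self.histology!r} for {self.sample_id}"
            )
        if self.group == "control":
            if self.histology != "normal" or self.dss_concentration != 0:
                raise CqValidationError(
                    f"control sample {self.sample_id} must have normal histology "
                    "and zero DSS concentration"
                )
        elif self.histology == "normal":
            raise CqValidationError(
                f"DSS sample {self.sample_id} cannot have normal histology"
            )


@dataclass(frozen=True)
class AssayInfo:
    """Registry entry for one qPCR assay."""

    assay_id: str
    assay_class: str  # "mRNA" | "miRNA"
    role: str  # "reference" | "target"
    amplicon_length: int | None = None

    def __post_init__(self) -> None:
        if self.assay_class not in ("mRNA", "miRNA"):
            raise CqValidationError(f"unknown assay class {self.assay_class!r}")
        if self.role not in ("reference", "target"):
            raise CqValidationError(f"unknown assay role {self.role!r}")


@dataclass
class CqTable:
    """A validated Cq study: long-format measurements + metadata + registry.

    Parameters
    ----------
    measurements : pandas.DataFrame
        Long format with columns ``sample_id, assay_id, replicate, cq,
        undetermined`` (cq is NaN when undetermined). After
        :func:`merge_replicates` each (sample, assay) appears once with
        ``replicate == 0`` and extra columns ``replicate_sd`` and
        ``discordant``.
    meta : dict[str, SampleMeta]
    assays : dict[str, AssayInfo]
    max_cycles : dict[str, float]
        Cycle limit per assay class.
    """

    measurements: pd.DataFrame
    meta: dict[str, SampleMeta]
    assays: dict[str, AssayInfo]
    max_cycles: dict[str, float] = field(
        default_factory=lambda: {"mRNA": MRNA_CYCLE_LIMIT, "miRNA": MIRNA_CYCLE_LIMIT}
    )
    merged: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.measurements
        required = {"sample_id", "assay_id", "replicate", "cq", "undetermined"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise CqValidationError(f"measurements missing columns {sorted(missing_cols)}")
        orphan = sorted(set(df["sample_id"]) - set(self.meta))
        if orphan:
            raise CqValidationError(
                f"samples without metadata: {', '.join(map(str, orphan))}"
            )
        unknown = sorted(set(df["assay_id"]) - set(self.assays))
        if unknown:
            raise CqValidationError(f"assays not in registry: {', '.join(unknown)}")
        det = df[~df["undetermined"]]
        if det["cq"].isna().any():
            bad = det[det["cq"].isna()].iloc[0]
            raise CqValidationError(
                f"determined measurement without Cq at ({bad.sample_id}, {bad.assay_id})"
            )
        limits = det["assay_id"].map(
            lambda a: self.max_cycles[self.assays[a].assay_class]
        )
        over = det["cq"] > limits
        if over.any():
            bad = det[over].iloc[0]
            raise CqValidationError(
                f"Cq {bad.cq} exceeds cycle limit at ({bad.sample_id}, {bad.assay_id})"
            )
        if (det["cq"] <= 0).any():
            bad = det[det["cq"] <= 0].iloc[0]
            raise CqValidationError(
                f"nonpositive Cq at ({bad.sample_id}, {bad.assay_id})"
            )

    # -- convenience accessors ------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.meta)

    def meta_frame(self) -> pd.DataFrame:
        """Per-sample metadata as a DataFrame indexed by sample_id."""
        rows = [vars(m) for m in self.meta.values()]
        return pd.DataFrame(rows).set_index("sample_id").sort_index()

    def wide(self) -> pd.DataFrame:
        """Merged sample x assay Cq matrix (NaN where undetermined/absent)."""
        if not self.merged:
            raise CqValidationError("call merge_replicates() before wide()")
        det = self.measurements[~self.measurements["undetermined"]]
        return det.pivot(index="sample_id", columns="assay_id", values="cq").sort_index()

    def cq_values(self, assay_id: str, sample_ids: Iterable[str] | None = None) -> np.ndarray:
        """Determined merged Cq values for one assay (optionally a subset)."""
        df = self.measurements
        m = (df["assay_id"] == assay_id) & (~df["undetermined"])
        if sample_ids is not None:
            m &= df["sample_id"].isin(set(sample_ids))
        return df.loc[m, "cq"].to_numpy(float)

    def subset(self, sample_ids: Iterable[str]) -> "CqTable":
        keep = set(sample_ids)
        df = self.measurements[self.measurements["sample_id"].isin(keep)].reset_index(drop=True)
        meta = {s: m for s, m in self.meta.items() if s in keep}
        return CqTable(df, meta, dict(self.assays), dict(self.max_cycles), self.merged)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_cq_cell(value: object) -> tuple[float, bool]:
    """Return (cq, undetermined) for one raw table cell."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan, True
    text = str(value).strip()
    if text.lower() in UNDETERMINED_TOKENS:
        return np.nan, True
    return float(text), False


def read_meta_table(path_or_buf, dialect: str = "\t") -> dict[str, SampleMeta]:
    """Read a per-sample metadata table keyed by sample_id."""
    df = pd.read_csv(path_or_buf, sep=dialect)
    meta: dict[str, SampleMeta] = {}
    known = {f for f in SampleMeta.__dataclass_fields__}
    for _, row in df.iterrows():
        kw = {k: row[k] for k in df.columns if k in known}
        kw["sample_id"] = str(kw["sample_id"])
        if "fixation_time" in kw and pd.isna(kw["fixation_time"]):
            kw["fixation_time"] = None
        if "storage_note" in kw and pd.isna(kw.get("storage_note")):
            kw["storage_note"] = None
        meta[kw["sample_id"]] = SampleMeta(**kw)
    return meta


def read_cq_table(
    path,
    meta: Mapping[str, SampleMeta] | str,
    assays: Mapping[str, AssayInfo],
    layout: str = "long",
    dialect: str = "\t",
    max_cycles: Mapping[str, float] | None = None,
) -> tuple[CqTable, pd.DataFrame]:
    """Read a delimited Cq table plus metadata into a validated :class:`CqTable`.

    Returns the table and a parse report (one row per flagged/undetermined
    cell). ``meta`` may be a mapping or a path to a metadata table.
    """
    if isinstance(meta, (str, io.IOBase)) or hasattr(meta, "read"):
        meta = read_meta_table(meta, dialect)
    raw = pd.read_csv(path, sep=dialect, dtype=str)
    report_rows = []
    if layout == "long":
        rows = []
        for _, row in raw.iterrows():
            cq, undet = _parse_cq_cell(row["cq"])
            rows.append(
                dict(
                    sample_id=str(row["sample_id"]),
                    assay_id=str(row["assay_id"]),
                    replicate=int(row.get("replicate", 1)),
                    cq=cq,
                    undetermined=undet,
                )
            )
            if undet:
                report_rows.append(
                    dict(sample_id=row["sample_id"], assay_id=row["assay_id"], reason="undetermined")
                )
        df = pd.DataFrame(rows)
    elif layout == "wide":
        assay_cols = [c for c in raw.columns if c != "sample_id"]
        rows = []
        for _, row in raw.iterrows():
            for a in assay_cols:
                cq, undet = _parse_cq_cell(row[a])
                rows.append(
                    dict(sample_id=str(row["sample_id"]), assay_id=a, replicate=1, cq=cq, undetermined=undet)
                )
                if undet:
                    report_rows.append(dict(sample_id=row["sample_id"], assay_id=a, reason="undetermined"))
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    kwargs = {} if max_cycles is None else {"max_cycles": dict(max_cycles)}
    table = CqTable(df, dict(meta), dict(assays), **kwargs)
    report = pd.DataFrame(report_rows, columns=["sample_id", "assay_id", "reason"])
    return table, report


def write_cq_table(table: CqTable, path, dialect: str = "\t") -> None:
    """Write the long-format canonical layout (Undetermined spelled out)."""
    df = table.measurements.copy()
    df["cq"] = df.apply(
        lambda r: "Undetermined" if r["undetermined"] else repr(float(r["cq"])), axis=1
    )
    df[["sample_id", "assay_id", "replicate", "cq"]].to_csv(path, sep=dialect, index=False)


# ---------------------------------------------------------------------------
# Replicate merging / undetermined handling / stratification
# ---------------------------------------------------------------------------

def merge_replicates(
    table: CqTable,
    rule: str = "mean",
    discordance_sd_threshold: float = 0.5,
) -> CqTable:
    """Collapse technical replicates to one Cq per (sample, assay).

    The merge rule is the arithmetic mean of the replicate Cq values (median by
    config). Measurements whose replicate SD exceeds
    ``discordance_sd_threshold`` cycles are flagged ``discordant`` but kept. A
    (sample, assay) pair is undetermined after merging iff all its replicates
    were undetermined.
    """
    if rule not in ("mean", "median"):
        raise ValueError(f"unknown merge rule {rule!r}")
    agg = np.mean if rule == "mean" else np.median
    rows = []
    for (sid, aid), grp in table.measurements.groupby(["sample_id", "assay_id"], sort=True):
        det = grp[~grp["undetermined"]]
        if len(det) == 0:
            rows.append(
                dict(sample_id=sid, assay_id=aid, replicate=0, cq=np.nan,
                     undetermined=True, replicate_sd=np.nan, discordant=False)
            )
            continue
        vals = det["cq"].to_numpy(float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            dict(sample_id=sid, assay_id=aid, replicate=0, cq=float(agg(vals)),
                 undetermined=False, replicate_sd=sd,
                 discordant=sd > discordance_sd_threshold)
        )
    df = pd.DataFrame(rows)
    return CqTable(df, dict(table.meta), dict(table.assays), dict(table.max_cycles), merged=True)


def handle_undetermined(
    table: CqTable, policy: str = "exclude"
) -> tuple[CqTable, pd.DataFrame]:
    """Apply the undetermined policy to a merged table.

    ``exclude`` (default) removes undetermined (sample, assay) pairs, matching
    how TBP-undetermined samples were left out of the stability calculations;
    ``censor_at_limit`` sets Cq to the class cycle limit with a ``censored``
    flag. Returns the table plus an exclusion report with per-assay counts.
    """
    if not table.merged:
        raise CqValidationError("handle_undetermined requires a merged table")
    df = table.measurements.copy()
    undet = df[df["undetermined"]]
    report = (
        undet.groupby("assay_id").size().rename("n_undetermined").reset_index()
        if len(undet)
        else pd.DataFrame(columns=["assay_id", "n_undetermined"])
    )
    if policy == "exclude":
        df = df[~df["undetermined"]].reset_index(drop=True)
        df["censored"] = False
    elif policy == "censor_at_limit":
        df["censored"] = df["undetermined"]
        limits = df["assay_id"].map(
            lambda a: table.max_cycles[table.assays[a].assay_class]
        )
        df.loc[df["undetermined"], "cq"] = limits[df["undetermined"]]
        df["undetermined"] = False
    else:
        raise ValueError(f"unknown undetermined policy {policy!r}")
    out = CqTable(df, dict(table.meta), dict(table.assays), dict(table.max_cycles), merged=True)
    return out, report


def stratify(table: CqTable, by: Sequence[str]) -> dict[tuple, CqTable]:
    """Partition samples into named subtables by metadata fields.

    The strata are disjoint and exhaustive; empty strata cannot arise because
    levels are taken from the data. Keys are tuples of field values in the
    order of ``by``.
    """
    mf = table.meta_frame()
    for f in by:
        if f not in mf.columns:
            raise KeyError(f"unknown metadata field {f!r}")
    out: dict[tuple, CqTable] = {}
    for key, grp in mf.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        out[key] = table.subset(grp.index)
    return out
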