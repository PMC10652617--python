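"""Merge assay behavioural metrics with per-mosquito life-history records.

Mosquitoes are tracked anonymously inside the cone, so behavioural metrics
exist at the assay level; the merge attaches each assay's metrics to every
mosquito monitored from that assay (five cohabiting mosquitoes per cone
test), producing the analysis-ready table that downstream mixed-model and
survival fits consume.  Haematin is carried through as reported (ug/ml, a
proxy for blood meal weight); converting it via a spectrophotometric
standard curve is wet-lab territory, not this tool's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import CONE_OCCUPANCY, AssayMetrics, metrics_to_table

LIFE_HISTORY_COLUMNS = [
    "mosquito_id", "assay_id", "strain", "treatment", "fed_1h", "fed_24h",
    "haematin", "wing_length", "death_day", "dead_24h",
]

KNOWN_TREATMENTS = {"UT", "P2", "P3", "OS", "IG2"}


class MergeIntegrityError(ValueError):
    """Raised when records cannot be joined consistently."""


@dataclass(frozen=True)
class ValidationIssue:
    mosquito_id: str
    field: str
    message: str


def read_life_history(path: str | Path) -> pd.DataFrame:
    """Read a life-history CSV, checking the expected column schema."""
    df = pd.read_csv(path)
    missing = [c for c in LIFE_HISTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"life-history table missing columns: {missing}")
    return df


def validate_life_history(records: pd.DataFrame) -> list[ValidationIssue]:
    """Report invariant violations without rejecting the table.

    Checked: the 24-h feeding opportunity is only offered to mosquitoes that
    did not feed at 1 h; haematin, wing length and death day are
    non-negative; treatment labels are known (unknown ones are flagged, not
    fatal — trial nets happen).
    """
    issues: list[ValidationIssue] = []
    for _, row in records.iterrows():
        mid = str(row.get("mosquito_id", "?"))
        if bool(row.get("fed_1h")) and bool(row.get("fed_24h")):
            issues.append(ValidationIssue(
                mid, "fed_24h",
                "fed_24h recorded although the mosquito fed at 1 h",
            ))
        for col in ("haematin", "wing_length", "death_day"):
            val = row.get(col)
            if pd.notna(val) and float(val) < 0:
                issues.append(ValidationIssue(mid, col, f"negative value {val}"))
        treatment = row.get("treatment")
        if pd.isna(treatment) or str(treatment).strip() == "":
            issues.append(ValidationIssue(mid, "treatment", "missing treatment label"))
        elif str(treatment) not in KNOWN_TREATMENTS:
            issues.append(ValidationIssue(
                mid, "treatment", f"unrecognized treatment {treatment!r}"
            ))
    return issues


def merge_life_history(
    metrics: Sequence[AssayMetrics] | pd.DataFrame,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Left-join life-history records onto their assay's behavioural metrics.

    Every record's ``assay_id`` must resolve to exactly one metrics row;
    orphan records raise :class:`MergeIntegrityError` listing the offenders,
    as do duplicated (assay_id, mosquito_id) pairs.  Assays with other than
    five monitored mosquitoes produce a warning, not an error.  The output
    has one row per record, metric columns appended.
    """
    mtable = metrics if isinstance(metrics, pd.DataFrame) else metrics_to_table(list(metrics))
    if mtable["assay_id"].duplicated().any():
        dupes = sorted(mtable.loc[mtable["assay_id"].duplicated(), "assay_id"])
        raise MergeIntegrityError(f"duplicate assay_id in metrics: {dupes}")
    dup_pairs = records.duplicated(subset=["assay_id", "mosquito_id"])
    if dup_pairs.any():
        pairs = records.loc[dup_pairs, ["assay_id", "mosquito_id"]].values.tolist()
        raise MergeIntegrityError(f"duplicate (assay_id, mosquito_id) pairs: {pairs}")
    known = set(mtable["assay_id"])
    orphans = sorted(set(records["assay_id"]) - known)
    if orphans:
        raise MergeIntegrityError(
            f"records reference unknown assay_id(s): {orphans}"
        )
    sizes = records.groupby("assay_id").size()
    odd = sizes[sizes != CONE_OCCUPANCY]
    for assay, n in odd.items():
        warnings.warn(
            f"assay {assay!r} has {n} life-history records "
            f"(expected {CONE_OCCUPANCY})",
            stacklevel=2,
        )
    merged = records.merge(mtable, on="assay_id", how="left", validate="m:1")
    assert len(merged) == len(records)
    return merged


def write_merged(merged: pd.DataFrame, path: str | Path) -> None:
    """Write the merged table as UTF-8 CSV; missing values as empty fields."""
    merged.to_csv(path, index=False, na_rep="")
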