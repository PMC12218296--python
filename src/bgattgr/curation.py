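"""Bioactivity data curation.

Turns a raw ChEMBL-style bioactivity table (compound id, SMILES, relation
symbol, IC50 in nM) into labeled, de-duplicated compound records and a
seeded train/independent-test split.

Curation rules
--------------
* only measurements reported with an exact relation (``=``) are kept;
* rows with missing IC50 are dropped;
* exact duplicate (compound_id, ic50_nM) pairs are collapsed;
* replicate measurements of one compound are aggregated (mean pIC50 by
  default) but the compound is discarded outright when the standard
  deviation of its replicate pIC50 values exceeds a cutoff (default 2);
* pIC50 = -log10(IC50 in molar) = 9 - log10(IC50 in nM);
* activity labels: active if pIC50 > 6, inactive if pIC50 < 5, the
  intermediate band [5, 6] is excluded from all downstream datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityLabel",
    "RawBioactivityRow",
    "CompoundRecord",
    "DatasetSplit",
    "CurationError",
    "CurationReport",
    "ic50_to_pic50",
    "label_compound",
    "filter_rows",
    "curate",
    "split_train_test",
    "read_bioactivity_csv",
    "write_records_csv",
]


class CurationError(ValueError):
    """Raised when curation cannot proceed (empty input, exhausted data...)."""


class ActivityLabel(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    INTERMEDIATE = "intermediate"


EXACT_RELATIONS = {"="}
KNOWN_RELATIONS = {"=", "<", ">", "<=", ">="}


@dataclass(frozen=True)
class RawBioactivityRow:
    """One raw assay measurement as extracted from the source table."""

    compound_id: str
    smiles: str
    relation: str
    ic50_nM: float | None
    assay_type: str = "IC50"

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("relation symbol must be non-empty")
        if self.ic50_nM is not None and not (self.ic50_nM > 0):
            raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM}")


@dataclass(frozen=True)
class CompoundRecord:
    """One curated compound with its potency and activity class."""

    compound_id: str
    smiles: str
    pic50: float
    label: ActivityLabel


@dataclass
class DatasetSplit:
    train: list[CompoundRecord]
    test: list[CompoundRecord]
    seed: int

    def class_counts(self, side: str) -> dict[str, int]:
        records = self.train if side == "train" else self.test
        counts: dict[str, int] = {}
        for r in records:
            counts[r.label.value] = counts.get(r.label.value, 0) + 1
        return counts


@dataclass
class CurationReport:
    """Per-step drop counts accumulated while filtering."""

    n_input: int = 0
    dropped_relation: int = 0
    dropped_missing_ic50: int = 0
    dropped_exact_duplicates: int = 0
    dropped_high_replicate_sd: int = 0
    dropped_intermediate: int = 0
    n_output: int = 0
    steps: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def ic50_to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nM to pIC50 = -log10(IC50 in molar).

    1000 nM = 1 uM = 1e-6 M maps to pIC50 6; 1 nM maps to 9.
    """
    if not (ic50_nM > 0):
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse transform; round-trips with :func:`ic50_to_pic50`."""
    return 10.0 ** (9.0 - pic50)


def label_compound(pic50: float) -> ActivityLabel:
    """Assign the activity class from potency.

    Active above pIC50 6 (sub-micromolar), inactive below 5, the [5, 6]
    band is 'intermediate' and excluded downstream.
    """
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    if pic50 > 6:
        return ActivityLabel.ACTIVE
    if pic50 < 5:
        return ActivityLabel.INACTIVE
    return ActivityLabel.INTERMEDIATE


def filter_rows(
    rows: Sequence[RawBioactivityRow],
    sd_cutoff: float = 2.0,
    report: CurationReport | None = None,
) -> list[RawBioactivityRow]:
    """Apply the relation / missing-value / duplicate / replicate-SD filters.

    Keeps one row per surviving (compound_id, ic50_nM) pair; a compound whose
    replicate pIC50 standard deviation exceeds ``sd_cutoff`` is dropped
    entirely.  Idempotent.  Raises :class:`CurationError` on empty input or
    when every row is filtered out.
    """
    if len(rows) == 0:
        raise CurationError("empty input: no bioactivity rows to curate")
    rep = report if report is not None else CurationReport()
    rep.n_input = len(rows)

    kept: list[RawBioactivityRow] = []
    for row in rows:
        if row.relation not in EXACT_RELATIONS:
            rep.dropped_relation += 1
            continue
        if row.ic50_nM is None:
            rep.dropped_missing_ic50 += 1
            continue
        kept.append(row)

    seen: set[tuple[str, float]] = set()
    deduped: list[RawBioactivityRow] = []
    for row in kept:
        key = (row.compound_id, row.ic50_nM)
        if key in seen:
            rep.dropped_exact_duplicates += 1
            continue
        seen.add(key)
        deduped.append(row)

    by_compound: dict[str, list[RawBioactivityRow]] = {}
    order: list[str] = []
    for row in deduped:
        if row.compound_id not in by_compound:
            order.append(row.compound_id)
        by_compound.setdefault(row.compound_id, []).append(row)

    surviving: list[RawBioactivityRow] = []
    for cid in order:
        group = by_compound[cid]
        pic50s = np.array([ic50_to_pic50(r.ic50_nM) for r in group])
        if len(group) > 1 and float(np.std(pic50s, ddof=1)) > sd_cutoff:
            rep.dropped_high_replicate_sd += len(group)
            continue
        surviving.extend(group)

    rep.n_output = len(surviving)
    if not surviving:
        raise CurationError(
            "all rows filtered out "
            f"(relation: {rep.dropped_relation}, missing IC50: "
            f"{rep.dropped_missing_ic50}, duplicates: "
            f"{rep.dropped_exact_duplicates}, replicate SD: "
            f"{rep.dropped_high_replicate_sd})"
        )
    return surviving


def curate(
    rows: Sequence[RawBioactivityRow],
    sd_cutoff: float = 2.0,
    aggregate: str = "mean",
    keep_intermediate: bool = False,
    report: CurationReport | None = None,
) -> list[CompoundRecord]:
    """Full curation: filter, collapse replicates, label, drop intermediates.

    ``aggregate`` is the replicate statistic, ``mean`` (default) or
    ``median`` of the replicate pIC50 values.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    rep = report if report is not None else CurationReport()
    filtered = filter_rows(rows, sd_cutoff=sd_cutoff, report=rep)

    by_compound: dict[str, list[RawBioactivityRow]] = {}
    order: list[str] = []
    for row in filtered:
        if row.compound_id not in by_compound:
            order.append(row.compound_id)
        by_compound.setdefault(row.compound_id, []).append(row)

    records: list[CompoundRecord] = []
    agg = np.mean if aggregate == "mean" else np.median
    for cid in order:
        group = by_compound[cid]
        pic50 = float(agg([ic50_to_pic50(r.ic50_nM) for r in group]))
        label = label_compound(pic50)
        if label is ActivityLabel.INTERMEDIATE and not keep_intermediate:
            rep.dropped_intermediate += 1
            continue
        records.append(CompoundRecord(cid, group[0].smiles, pic50, label))
    rep.n_output = len(records)
    if not records:
        raise CurationError("no compounds left after labeling")
    return records


def split_train_test(
    records: Sequence[CompoundRecord],
    n_test_active: int,
    n_test_inactive: int,
    seed: int,
) -> DatasetSplit:
    """Hold out a per-class test set sampled uniformly without replacement.

    Deterministic for a fixed seed; the remainder forms the training set in
    the original record order.
    """
    if any(r.label is ActivityLabel.INTERMEDIATE for r in records):
        raise ValueError("records must not contain intermediate compounds")
    actives = [i for i, r in enumerate(records) if r.label is ActivityLabel.ACTIVE]
    inactives = [i for i, r in enumerate(records) if r.label is ActivityLabel.INACTIVE]
    if n_test_active > len(actives) or n_test_inactive > len(inactives):
        raise CurationError(
            f"requested test counts ({n_test_active} active, {n_test_inactive} "
            f"inactive) exceed availability ({len(actives)}, {len(inactives)})"
        )
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    if n_test_active:
        test_idx.update(rng.choice(actives, size=n_test_active, replace=False).tolist())
    if n_test_inactive:
        test_idx.update(rng.choice(inactives, size=n_test_inactive, replace=False).tolist())
    test = [records[i] for i in sorted(test_idx)]
    train = [r for i, r in enumerate(records) if i not in test_idx]
    return DatasetSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# CSV I/O

def read_bioactivity_csv(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> list[RawBioactivityRow]:
    """Read a raw bioactivity table.

    ``columns`` remaps the expected header names
    ``{"id", "smiles", "relation", "ic50_nM"}`` to those present in the file.
    """
    cols = {"id": "id", "smiles": "smiles", "relation": "relation", "ic50_nM": "ic50_nM"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype={cols["id"]: str, cols["relation"]: str})
    rows = []
    for _, r in df.iterrows():
        ic50 = r[cols["ic50_nM"]]
        rows.append(
            RawBioactivityRow(
                compound_id=str(r[cols["id"]]),
                smiles=str(r[cols["smiles"]]),
                relation=str(r[cols["relation"]]),
                ic50_nM=None if pd.isna(ic50) else float(ic50),
            )
        )
    return rows


def write_records_csv(records: Iterable[CompoundRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"id": r.compound_id, "smiles": r.smiles, "pic50": round(r.pic50, 6), "label": r.label.value}
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    return [
        CompoundRecord(str(r["id"]), str(r["smiles"]), float(r["pic50"]), ActivityLabel(r["label"]))
        for _, r in df.iterrows()
    ]
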