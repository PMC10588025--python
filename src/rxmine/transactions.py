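"""Patient-level ATC transactions and demographic stratification.

Each patient contributes one "basket": the deduplicated set of their ATC codes
truncated to one hierarchy level L ∈ {1..5}.  Support is computed against the
full patient roster N, so patients whose entire record set was censored away
(non-T2DM patients holding only A10 drugs) stay in N with an empty item set.
Baskets are built overall and for every (gender × age-category) stratum,
including the "all" margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .ingestion import AGE_CATEGORIES, ATC_LEVEL_LENGTHS

ALL = "all"


@dataclass
class TransactionSet:
    """A collection of per-patient item sets at one ATC level and stratum."""

    level: int
    stratum: tuple[str, str] = (ALL, ALL)  # (gender, age_category)
    patient_ids: list[str] = field(default_factory=list)
    items: list[frozenset[str]] = field(default_factory=list)
    n_diabetic: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.items)

    def __post_init__(self) -> None:
        if self.level not in ATC_LEVEL_LENGTHS:
            raise ValueError(f"ATC level must be 1..5, got {self.level}")
        if len(self.patient_ids) != len(self.items):
            raise ValueError("patient_ids and items must align")
        if self.n_diabetic > len(self.items):
            raise ValueError("n_diabetic cannot exceed n_patients")


def build_transactions(
    claims: pd.DataFrame,
    level: int,
    labels: pd.Series,
    roster: Iterable[str] | None = None,
) -> TransactionSet:
    """Aggregate mapped (post-censoring) claims into one basket per patient.

    ``labels`` maps patient_id → is_t2dm and, absent an explicit ``roster``,
    defines the patient universe: labeled patients with no surviving records
    emit empty baskets but still count toward N.
    """
    if level not in ATC_LEVEL_LENGTHS:
        raise ValueError(f"ATC level must be 1..5, got {level}")
    col = f"atc_l{level}"
    grouped = claims.groupby("patient_id")[col].agg(frozenset)
    ids = sorted(labels.index) if roster is None else sorted(roster)
    empty: frozenset[str] = frozenset()
    items = [grouped.get(pid, empty) for pid in ids]
    n_diabetic = int(labels.reindex(ids, fill_value=False).astype(bool).sum())
    return TransactionSet(
        level=level, patient_ids=ids, items=items, n_diabetic=n_diabetic
    )


def stratify(
    claims: pd.DataFrame,
    level: int,
    labels: pd.Series,
    demographics: pd.DataFrame,
    include_margins: bool = True,
) -> dict[tuple[str, str], TransactionSet]:
    """Build one TransactionSet per (gender, age-category) stratum.

    ``demographics`` is indexed by patient_id with ``gender`` and
    ``age_category`` columns.  With margins, each patient lands in exactly four
    strata: their cell, the two one-way margins, and the grand total.  Empty
    strata are omitted.
    """
    genders = ["male", "female"] + ([ALL] if include_margins else [])
    cats = list(AGE_CATEGORIES) + ([ALL] if include_margins else [])
    out: dict[tuple[str, str], TransactionSet] = {}
    demo = demographics.reindex(labels.index)
    for g in genders:
        for c in cats:
            mask = pd.Series(True, index=demo.index)
            if g != ALL:
                mask &= demo["gender"] == g
            if c != ALL:
                mask &= demo["age_category"] == c
            ids = demo.index[mask]
            if len(ids) == 0:
                continue
            sub = claims[claims["patient_id"].isin(set(ids))]
            ts = build_transactions(sub, level, labels.loc[ids], roster=ids)
            ts.stratum = (g, c)
            out[(g, c)] = ts
    return out


def write_basket(ts: TransactionSet, path: str | Path) -> None:
    """Serialize as a basket file: one line per patient, tab-separated codes.

    The de-facto transaction format of common ARM tools; empty baskets emit
    an empty line so that N is recoverable from the line count.
    """
    with open(path, "w") as fh:
        for codes in ts.items:
            fh.write("\t".join(sorted(codes)) + "\n")


def read_basket(path: str | Path, level: int, n_diabetic: int = 0) -> TransactionSet:
    """Read a basket file written by :func:`write_basket`."""
    items: list[frozenset[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            items.append(frozenset(line.split("\t")) if line else frozenset())
    ids = [str(i) for i in range(len(items))]
    return TransactionSet(
        level=level, patient_ids=ids, items=items, n_diabetic=n_diabetic
    )
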