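"""Claims ingestion and attribute mapping.

Reads delimited pharmacy-claims tables into a canonical pandas DataFrame
(one row per dispensed drug), removes patients with missing demographics
(MCAR listwise deletion), builds a unique patient identifier from the
insurance ID and serial, and attaches the five ATC hierarchy levels, the
prescriber specialty, and the patient age category to every record.

Canonical claim columns
-----------------------
``insurance_id, insurance_serial, prescription_id, age, gender,
prescriber_code, national_drug_code`` — ``age`` is a nullable float (years),
``gender`` is ``"male"``/``"female"``/missing, everything else is a string.

Mapped claims additionally carry ``patient_id, generic_name, atc_l1 .. atc_l5,
prescriber_specialty, age_category``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ColumnMap

logger = logging.getLogger(__name__)

PATIENT_ID_DELIMITER = "|"

AGE_CATEGORIES = ("Young", "Middle-Aged", "Old")

#: ATC code lengths by hierarchy level
ATC_LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

CLAIM_COLUMNS = [
    "insurance_id",
    "insurance_serial",
    "prescription_id",
    "age",
    "gender",
    "prescriber_code",
    "national_drug_code",
]

_GENDER_ALIASES = {
    "male": "male",
    "m": "male",
    "1": "male",
    "female": "female",
    "f": "female",
    "2": "female",
}


@dataclass
class IngestionSummary:
    """Record-conservation bookkeeping for one ingestion run."""

    n_input: int = 0
    n_dropped_missing_demographics: int = 0
    n_dropped_unmapped_drug: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_dropped_missing_demographics
            + self.n_dropped_unmapped_drug
        )
        if total != self.n_input:
            raise AssertionError(
                f"record conservation violated: {self.n_input} in, {total} accounted"
            )


def age_to_category(age: int | float) -> str:
    """Map an age in years onto {Young, Middle-Aged, Old}.

    The three half-open intervals [0, 30), [30, 45), [45, inf) partition the
    non-negative ages.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age < 30:
        return "Young"
    if age < 45:
        return "Middle-Aged"
    return "Old"


def ages_to_categories(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`age_to_category`; missing ages map to missing."""
    bins = pd.cut(
        ages, [-0.5, 29.5, 44.5, np.inf], labels=AGE_CATEGORIES, right=True
    )
    return bins.astype(object).where(ages.notna())


def construct_patient_id(insurance_id: str, insurance_serial: str) -> str:
    """Combine insurance ID and serial into a unique patient identifier.

    Families share an insurance ID and are told apart by the serial, so the
    pair identifies one person.  A delimiter that may not occur in either
    component keeps the mapping injective (``("0012", "03")`` and
    ``("00120", "3")`` must not collide).
    """
    for name, part in (("insurance_id", insurance_id), ("insurance_serial", insurance_serial)):
        if not part:
            raise ValueError(f"{name} must be non-empty")
        if PATIENT_ID_DELIMITER in part:
            raise ValueError(
                f"{name} {part!r} contains the reserved delimiter {PATIENT_ID_DELIMITER!r}"
            )
    return f"{insurance_id}{PATIENT_ID_DELIMITER}{insurance_serial}"


def _normalize_gender(raw: pd.Series) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower()
    out = s.map(_GENDER_ALIASES)
    return out.astype(object).where(out.notna())


def read_claims(
    path: str | Path,
    columns: ColumnMap | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a delimited claims file into the canonical claim schema.

    Unparseable age or gender values become missing rather than errors; a
    mandatory column absent from the header is a configuration error naming
    the column.
    """
    columns = columns or ColumnMap()
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    colmap = columns.as_dict()
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise KeyError(
            f"claims file {path} lacks configured column(s): {', '.join(missing)}"
        )
    out = pd.DataFrame(
        {canon: df[src] for canon, src in colmap.items()}
    )
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    out.loc[(out["age"] < 0) | (out["age"] > 120), "age"] = np.nan
    out["gender"] = _normalize_gender(out["gender"])
    empty_code = out["national_drug_code"].astype(str).str.strip() == ""
    if empty_code.any():
        raise ValueError(
            f"{int(empty_code.sum())} rows have an empty national_drug_code"
        )
    return out.reset_index(drop=True)


def read_drug_mapping(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read the national-drug-code → (generic name, ATC levels 1–5) table.

    Validates the prefix-consistency of each ATC chain: level k must be a
    prefix of level k+1 and have the canonical code length.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str).set_index("national_drug_id")
    validate_atc_chain(df)
    return df


def validate_atc_chain(drug_map: pd.DataFrame) -> None:
    for level, length in ATC_LEVEL_LENGTHS.items():
        col = f"atc_l{level}"
        bad_len = drug_map[col].str.len() != length
        if bad_len.any():
            raise ValueError(
                f"{col}: {int(bad_len.sum())} codes do not have length {length}"
            )
    for level in range(1, 5):
        lo, hi = drug_map[f"atc_l{level}"], drug_map[f"atc_l{level + 1}"]
        broken = [c for c, a, b in zip(drug_map.index, lo, hi) if not b.startswith(a)]
        if broken:
            raise ValueError(
                f"ATC chain broken (level {level} not a prefix of level {level + 1}) "
                f"for national codes: {broken[:5]}"
            )


def read_specialty_mapping(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read the prescriber-code → specialty table."""
    df = pd.read_csv(path, sep=delimiter, dtype=str).set_index("prescriber_code")
    return df


def drop_missing_demographics(
    claims: pd.DataFrame, missing_rule: str = "any"
) -> tuple[pd.DataFrame, int]:
    """Listwise-delete every record of patients with missing demographics.

    A single missing age or gender anywhere in a patient's history removes the
    patient's entire prescription set; under MCAR this deletion is unbiased.
    ``missing_rule="all"`` relaxes to dropping only patients missing both.
    Returns the surviving records and the number dropped.  Idempotent.
    """
    if missing_rule not in ("any", "all"):
        raise ValueError(f"missing_rule must be 'any' or 'all', got {missing_rule!r}")
    key = [claims["insurance_id"], claims["insurance_serial"]]
    row_missing_age = claims["age"].isna()
    row_missing_gender = claims["gender"].isna()
    if missing_rule == "any":
        row_bad = row_missing_age | row_missing_gender
    else:
        row_bad = row_missing_age & row_missing_gender
    patient_bad = row_bad.groupby(key).transform("max")
    kept = claims.loc[~patient_bad].reset_index(drop=True)
    return kept, int(patient_bad.sum())


def map_attributes(
    claims: pd.DataFrame,
    drug_map: pd.DataFrame,
    specialty_map: pd.DataFrame,
    missing_rule: str = "any",
) -> tuple[pd.DataFrame, IngestionSummary]:
    """Full mapping step: demographics filter, patient IDs, ATC/specialty/age.

    Records whose national drug code is absent from the mapping table are
    dropped and counted (the patient's other records survive); prescriber
    codes absent from the specialty table are flagged as ``"Unknown"`` rather
    than dropped.  Patient age is resolved to the earliest record's value —
    with no date column, the minimum age across the history.
    """
    summary = IngestionSummary(n_input=len(claims))
    kept, n_demo = drop_missing_demographics(claims, missing_rule)
    summary.n_dropped_missing_demographics = n_demo

    mappable = kept["national_drug_code"].isin(drug_map.index)
    summary.n_dropped_unmapped_drug = int((~mappable).sum())
    if summary.n_dropped_unmapped_drug:
        logger.warning(
            "dropping %d records with national drug codes absent from the mapping",
            summary.n_dropped_unmapped_drug,
        )
    mapped = kept.loc[mappable].copy()

    mapped["patient_id"] = (
        mapped["insurance_id"] + PATIENT_ID_DELIMITER + mapped["insurance_serial"]
    )
    drug_cols = ["generic_name", "atc_l1", "atc_l2", "atc_l3", "atc_l4", "atc_l5"]
    for col in drug_cols:
        mapped[col] = mapped["national_drug_code"].map(drug_map[col])

    spec_lookup = mapped["prescriber_code"].map(specialty_map["specialty"])
    n_unknown = int(spec_lookup.isna().sum())
    if n_unknown:
        logger.warning(
            "%d records have prescriber codes absent from the specialty mapping; "
            "flagged as 'Unknown'",
            n_unknown,
        )
    mapped["prescriber_specialty"] = spec_lookup.fillna("Unknown")

    # age per prescription may disagree across a patient's history; resolve to
    # the earliest (minimum, absent dates) and categorize once per patient
    resolved_age = mapped.groupby("patient_id")["age"].transform("min")
    mapped["age"] = resolved_age
    mapped["age_category"] = ages_to_categories(resolved_age)

    summary.n_retained = len(mapped)
    summary.check()
    logger.info(
        "ingestion: %d records in, %d retained, %d dropped (demographics), "
        "%d dropped (unmapped drug)",
        summary.n_input,
        summary.n_retained,
        summary.n_dropped_missing_demographics,
        summary.n_dropped_unmapped_drug,
    )
    return mapped.reset_index(drop=True), summary
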