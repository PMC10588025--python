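"""End-to-end orchestration: claims → phenotype → transactions → rules.

A thin convenience layer gluing the stage modules together for the common
case (one cohort, one ATC level); each stage remains individually usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .arm import AssociationRule, mine_rules
from .config import AppConfig
from .ingestion import IngestionSummary, map_attributes
from .phenotyping import censor_a10, phenotype
from .reporting import RuleReport, filter_diabetes_rules, rank_and_truncate
from .transactions import TransactionSet, build_transactions, stratify


@dataclass
class PipelineResult:
    mapped_claims: pd.DataFrame
    ingestion: IngestionSummary
    patients: pd.DataFrame  # phenotype output, one row per patient
    censored_claims: pd.DataFrame
    n_censored_records: int

    @property
    def labels(self) -> pd.Series:
        return self.patients["is_t2dm"]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_diabetic(self) -> int:
        return int(self.patients["is_t2dm"].sum())

    _transaction_cache: dict = field(default_factory=dict)

    def transactions(self, level: int) -> TransactionSet:
        if level not in self._transaction_cache:
            self._transaction_cache[level] = build_transactions(
                self.censored_claims, level, self.labels
            )
        return self._transaction_cache[level]

    def stratified(self, level: int) -> dict[tuple[str, str], TransactionSet]:
        demo = self.patients[["gender", "age_category"]]
        return stratify(self.censored_claims, level, self.labels, demo)


def prepare(
    claims: pd.DataFrame,
    drug_map: pd.DataFrame,
    specialty_map: pd.DataFrame,
    cfg: AppConfig | None = None,
) -> PipelineResult:
    """Ingest raw canonical claims and run phenotyping + A10 censoring."""
    cfg = cfg or AppConfig()
    mapped, summary = map_attributes(
        claims, drug_map, specialty_map, missing_rule=cfg.phenotype.missing_rule
    )
    patients = phenotype(mapped, cfg.phenotype)
    censored, n_censored = censor_a10(mapped, patients["is_t2dm"])
    return PipelineResult(
        mapped_claims=mapped,
        ingestion=summary,
        patients=patients,
        censored_claims=censored,
        n_censored_records=n_censored,
    )


def mine_report(
    result: PipelineResult,
    level: int,
    cfg: AppConfig | None = None,
    k: int = 30,
    lift_floor: float = 2.0,
) -> tuple[list[AssociationRule], RuleReport]:
    """Mine one ATC level and build the diabetes-anchored top-k report."""
    cfg = cfg or AppConfig()
    ts = result.transactions(level)
    rules = mine_rules(ts, cfg.mining)
    report = rank_and_truncate(
        filter_diabetes_rules(rules), level, k=k, lift_floor=lift_floor
    )
    return rules, report
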