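"""Diabetes-anchored rule reports and threshold grid search.

The reporting conventions: keep only rules whose antecedent consists entirely
of diabetes drugs (ATC level-2 class A10 or its descendants) and whose
consequent is a non-diabetes drug; drop rules with lift ≤ 2.0 (strict); sort
level 2 by the diabetic-prevalence indicator and deeper levels by lift; and
truncate to the top 30 — levels with fewer qualifying rules report them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .arm import AssociationRule, generate_rules, mine_frequent_itemsets
from .config import MiningConfig
from .transactions import TransactionSet

A10_PREFIX = "A10"


@dataclass
class RuleReport:
    level: int
    stratum: tuple[str, str]
    sort_key: str  # "prevalence" or "lift"
    k: int
    lift_floor: float
    rules: list[AssociationRule] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the LHS / RHS / metric column layout."""
        return pd.DataFrame(
            {
                "lhs": [", ".join(sorted(r.antecedent)) for r in self.rules],
                "rhs": [r.consequent for r in self.rules],
                "joint_count": [r.joint_count for r in self.rules],
                "support": [r.support for r in self.rules],
                "confidence": [r.confidence for r in self.rules],
                "lift": [r.lift for r in self.rules],
                "prevalence": [r.prevalence for r in self.rules],
            }
        )


def filter_diabetes_rules(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Keep rules reading "diabetes drugs ⇒ other drug".

    Antecedent must be non-empty and lie entirely under A10; the consequent
    must lie outside A10.
    """
    return [
        r
        for r in rules
        if r.antecedent
        and all(item.startswith(A10_PREFIX) for item in r.antecedent)
        and not r.consequent.startswith(A10_PREFIX)
    ]


def _sort_key_for_level(level: int) -> str:
    return "prevalence" if level == 2 else "lift"


def rank_and_truncate(
    rules: list[AssociationRule],
    level: int,
    k: int = 30,
    lift_floor: float = 2.0,
    sort_key: str | None = None,
) -> RuleReport:
    """Apply the lift floor (strict), sort, and keep the top k.

    Level 2 sorts by the prevalence indicator (the most-prescribed drug
    classes among diabetics); levels 3–5 by lift.  Ties break by confidence
    (descending) then antecedent code order, so reports are deterministic.
    """
    sort_key = sort_key or _sort_key_for_level(level)
    if sort_key not in ("prevalence", "lift"):
        raise ValueError(f"sort_key must be 'prevalence' or 'lift', got {sort_key!r}")
    passing = [r for r in rules if r.lift > lift_floor]
    if sort_key == "prevalence" and any(r.prevalence is None for r in passing):
        raise ValueError("prevalence sort requested but rules lack prevalence")
    passing.sort(
        key=lambda r: (
            -(r.prevalence if sort_key == "prevalence" else r.lift),
            -r.confidence,
            tuple(sorted(r.antecedent)),
            r.consequent,
        )
    )
    return RuleReport(
        level=level,
        stratum=(("all", "all")),
        sort_key=sort_key,
        k=k,
        lift_floor=lift_floor,
        rules=passing[:k],
    )


def threshold_sweep(
    ts: TransactionSet,
    support_grid: list[float],
    confidence_grid: list[float],
) -> pd.DataFrame:
    """Grid search over (min_support, min_confidence).

    One row per cell with the itemset, rule, and diabetes-anchored rule
    counts obtained by full mining at that cell; counts are non-increasing
    along each axis (anti-monotonicity).  Selection among cells is left to
    the analyst.
    """
    if not support_grid or not confidence_grid:
        raise ValueError("both grids must be non-empty")
    rows = []
    for s in sorted(support_grid):
        itemsets = mine_frequent_itemsets(ts, MiningConfig(min_support=s))
        for c in sorted(confidence_grid):
            cfg = MiningConfig(min_support=s, min_confidence=c)
            rules = generate_rules(itemsets, ts, cfg)
            rows.append(
                {
                    "min_support": s,
                    "min_confidence": c,
                    "n_itemsets": len(itemsets),
                    "n_rules": len(rules),
                    "n_diabetes_rules": len(filter_diabetes_rules(rules)),
                }
            )
    return pd.DataFrame(rows)
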