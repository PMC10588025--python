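"""FP-Growth frequent-itemset mining and association rules, from scratch.

The miner follows the classic frequent-pattern-growth scheme: transactions
are compressed into a prefix tree (FP-tree) whose paths share common frequent
prefixes, and itemsets are mined recursively from per-item conditional
pattern bases without candidate generation.  Counts are kept as exact
integers throughout; support, confidence, lift, and the diabetic-prevalence
indicator are computed as fractions only at rule emission.

Definitions, for a rule A → B over N patients with σ(A→B) patients holding
both sides:

* support    Supp(A→B) = σ(A→B) / N
* confidence Conf(A→B) = Supp(A→B) / Supp(A)
* lift       Conf(A→B) / Supp(B)  (observed-to-expected under independence)
* prevalence σ(A→B) / n_diabetic — the fraction of diabetic patients
  co-prescribed the rule's drugs; a cohort-specific indicator that rescales
  support from all patients to the diabetic subpopulation.

A brute-force subset-enumeration miner is included as an independent oracle
for equivalence testing; it is never the production path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .config import MiningConfig
from .transactions import TransactionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support_count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    """A → B with single-item consequent and exact joint count σ(A→B)."""

    antecedent: frozenset[str]
    consequent: str
    joint_count: int
    support: float
    confidence: float
    lift: float
    prevalence: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lhs = ", ".join(sorted(self.antecedent))
        return f"{{{lhs}}} => {self.consequent}"


def support_count_threshold(min_support: float, n: int) -> int:
    """Minimum transaction count for frequency: ceil(min_support × N).

    Frequency is non-strict (count ≥ threshold), matching the classic
    algorithm; at least one occurrence is always required.
    """
    return max(1, math.ceil(min_support * n - 1e-12))


def find_frequent_items(
    transactions: Sequence[frozenset[str]], min_count: int
) -> list[tuple[str, int]]:
    """Items meeting the count threshold, by descending count then code.

    The returned order is the global insertion order of the FP-tree; a fixed
    total order (any would do) makes mining deterministic.
    """
    counts: dict[str, int] = {}
    for t in transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    frequent = [(i, c) for i, c in counts.items() if c >= min_count]
    frequent.sort(key=lambda ic: (-ic[1], ic[0]))
    return frequent


class FPNode:
    __slots__ = ("item", "count", "parent", "children", "next_link")

    def __init__(self, item: str | None, parent: "FPNode | None") -> None:
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.next_link: FPNode | None = None  # header-table chain


class FPTree:
    """Prefix tree over frequency-ordered transactions with a header table.

    Every root-to-node path spells the frequent-item prefix of at least one
    transaction; a node's count is the number of transactions containing that
    prefix, and the counts along an item's header chain sum to the item's
    support count.
    """

    def __init__(self, item_order: Sequence[str]) -> None:
        self.root = FPNode(None, None)
        self.rank = {item: i for i, item in enumerate(item_order)}
        self.header: dict[str, FPNode] = {}
        self._tails: dict[str, FPNode] = {}

    def insert(self, items: Iterable[str], count: int = 1) -> None:
        """Insert a transaction (filtered + sorted to the global order)."""
        path = sorted(
            (i for i in items if i in self.rank), key=self.rank.__getitem__
        )
        node = self.root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                tail = self._tails.get(item)
                if tail is None:
                    self.header[item] = child
                else:
                    tail.next_link = child
                self._tails[item] = child
            child.count += count
            node = child

    def item_count(self, item: str) -> int:
        total = 0
        node = self.header.get(item)
        while node is not None:
            total += node.count
            node = node.next_link
        return total

    def prefix_paths(self, item: str) -> list[tuple[list[str], int]]:
        """Conditional pattern base: (path-to-root items, count) per node."""
        paths = []
        node = self.header.get(item)
        while node is not None:
            path = []
            up = node.parent
            while up is not None and up.item is not None:
                path.append(up.item)
                up = up.parent
            if path:
                paths.append((path, node.count))
            node = node.next_link
        return paths


def build_fp_tree(
    transactions: Sequence[frozenset[str]], item_order: Sequence[str]
) -> FPTree:
    tree = FPTree(item_order)
    for t in transactions:
        tree.insert(t)
    return tree


def _mine(
    tree: FPTree,
    min_count: int,
    suffix: tuple[str, ...],
    out: dict[frozenset[str], int],
    max_size: int | None,
) -> None:
    # iterate items least-frequent first so conditional trees shrink
    for item in reversed(list(tree.header)):
        count = tree.item_count(item)
        if count < min_count:
            continue
        itemset = suffix + (item,)
        out[frozenset(itemset)] = count
        if max_size is not None and len(itemset) >= max_size:
            logger.warning(
                "max_itemset_size=%d reached at %s; deeper patterns truncated",
                max_size,
                sorted(itemset),
            )
            continue
        base = tree.prefix_paths(item)
        if not base:
            continue
        cond_counts: dict[str, int] = {}
        for path, c in base:
            for p in path:
                cond_counts[p] = cond_counts.get(p, 0) + c
        cond_order = sorted(
            (i for i, c in cond_counts.items() if c >= min_count),
            key=lambda i: (-cond_counts[i], i),
        )
        if not cond_order:
            continue
        cond_tree = FPTree(cond_order)
        for path, c in base:
            cond_tree.insert(path, c)
        _mine(cond_tree, min_count, itemset, out, max_size)


def mine_frequent_itemsets(
    ts: TransactionSet, cfg: MiningConfig | None = None
) -> list[FrequentItemset]:
    """All itemsets with support_count ≥ ceil(min_support × N), via FP-Growth.

    N is the full patient roster of ``ts`` (empty baskets included), which is
    also the support denominator.
    """
    cfg = cfg or MiningConfig()
    n = ts.n_patients
    if n == 0:
        return []
    min_count = support_count_threshold(cfg.min_support, n)
    order = [i for i, _ in find_frequent_items(ts.items, min_count)]
    tree = build_fp_tree(ts.items, order)
    found: dict[frozenset[str], int] = {}
    _mine(tree, min_count, (), found, cfg.max_itemset_size)
    return [
        FrequentItemset(items=s, support_count=c, support=c / n)
        for s, c in found.items()
    ]


def brute_force_itemsets(
    ts: TransactionSet, cfg: MiningConfig | None = None, max_items: int = 20
) -> list[FrequentItemset]:
    """Independent oracle: enumerate every subset of the frequent items and
    count support by direct scan.

    Exponential in the number of frequent items, hence guarded; use only on
    small instances.
    """
    cfg = cfg or MiningConfig()
    n = ts.n_patients
    if n == 0:
        return []
    min_count = support_count_threshold(cfg.min_support, n)
    singles = find_frequent_items(ts.items, min_count)
    if len(singles) > max_items:
        raise ValueError(
            f"{len(singles)} frequent items exceeds the brute-force guard "
            f"({max_items}); this oracle is for small instances only"
        )
    items = [i for i, _ in singles]
    out: list[FrequentItemset] = []
    for size in range(1, len(items) + 1):
        if cfg.max_itemset_size is not None and size > cfg.max_itemset_size:
            break
        any_frequent = False
        for combo in combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for t in ts.items if s <= t)
            if count >= min_count:
                out.append(FrequentItemset(s, count, count / n))
                any_frequent = True
        if not any_frequent:
            break  # downward closure: no larger set can be frequent
    return out


def generate_rules(
    itemsets: Iterable[FrequentItemset],
    ts: TransactionSet,
    cfg: MiningConfig | None = None,
) -> list[AssociationRule]:
    """Emit every rule (S \\ {b}) → b over frequent S with |S| ≥ 2.

    Consequents are single items, matching the reporting convention of the
    analysis.  Support/confidence thresholds: support is inherited from
    itemset frequency; confidence must reach min_confidence.  Prevalence is
    attached when the transaction set knows its diabetic count.
    """
    cfg = cfg or MiningConfig()
    n = ts.n_patients
    counts = {fi.items: fi.support_count for fi in itemsets}
    rules: list[AssociationRule] = []
    for s, joint in counts.items():
        if len(s) < 2:
            continue
        for b in s:
            antecedent = s - {b}
            ante_count = counts.get(antecedent)
            if ante_count is None:
                # cannot happen for FP-Growth/brute-force output (downward
                # closure); guards hand-built itemset lists
                continue
            confidence = joint / ante_count
            if confidence < cfg.min_confidence:
                continue
            b_count = counts.get(frozenset((b,)))
            if b_count is None:
                continue
            lift = confidence / (b_count / n)
            rules.append(
                AssociationRule(
                    antecedent=antecedent,
                    consequent=b,
                    joint_count=joint,
                    support=joint / n,
                    confidence=confidence,
                    lift=lift,
                    prevalence=(
                        joint / ts.n_diabetic if ts.n_diabetic > 0 else None
                    ),
                )
            )
    return rules


def compute_prevalence(rule: AssociationRule, ts: TransactionSet) -> float:
    """Diabetic-prevalence indicator: σ(A→B) / n_diabetic.

    Equivalently support × N / n_diabetic, which is how it is recovered when
    only the support fraction is known.
    """
    if ts.n_diabetic <= 0:
        raise ValueError("prevalence undefined: transaction set has no diabetics")
    return rule.joint_count / ts.n_diabetic


def mine_rules(
    ts: TransactionSet, cfg: MiningConfig | None = None
) -> list[AssociationRule]:
    """Convenience: FP-Growth then rule generation."""
    cfg = cfg or MiningConfig()
    return generate_rules(mine_frequent_itemsets(ts, cfg), ts, cfg)
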