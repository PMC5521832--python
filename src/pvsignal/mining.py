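"""Apriori association-rule mining over report-level transactions.

Each report becomes one transaction whose items are its drug names (all
role codes — co-medications matter for risk-factor discovery, not just
suspected drugs), its history terms, optionally its age band, and a
consequent flag item ("thromboembolism" by default) when the report is
an event case. Rules X -> Y restricted to the flag consequent are scored
with

    support    = P(X and Y) = n(X and Y) / D,
    confidence = P(X and Y) / P(X),
    lift       = P(X and Y) / (P(X) P(Y)) = confidence / P(Y),

where D is the number of transactions. A confidence-1 rule with
consequent Y therefore always has lift D / n(Y) exactly.

The miner is the classic level-wise apriori: candidate k-itemsets are
joined from (k-1)-itemsets sharing a (k-1)-prefix under lexicographic
item order, pruned by downward closure, and counted by intersecting
per-item transaction-id sets. Downward closure of the output is
asserted on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._util import UserInputError, round_half_up
from .data import CaseReport

TE_ITEM = "thromboembolism"


@dataclass(frozen=True)
class Transaction:
    case_id: str
    items: FrozenSet[str]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for the miner (defaults match the replayed analysis)."""

    min_support: float = 0.00001
    min_confidence: float = 0.9
    maxlen: int = 3
    rhs_restriction: FrozenSet[str] = frozenset({TE_ITEM})
    include_age_item: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1 and 0 < self.min_confidence <= 1):
            raise UserInputError("thresholds must lie in (0, 1]")
        if self.maxlen < 2:
            raise UserInputError("maxlen must be at least 2")


@dataclass(frozen=True)
class AssociationRule:
    """A rule lhs -> rhs with exact counts and derived measures."""

    lhs: Tuple[str, ...]
    rhs: Tuple[str, ...]
    n_joint: int
    n_lhs: int
    n_rhs: int
    n_total: int

    def __post_init__(self) -> None:
        if set(self.lhs) & set(self.rhs):
            raise UserInputError("lhs and rhs must be disjoint")

    @property
    def support(self) -> float:
        return self.n_joint / self.n_total

    @property
    def confidence(self) -> float:
        return self.n_joint / self.n_lhs

    @property
    def lift(self) -> float:
        return (self.n_joint * self.n_total) / (self.n_lhs * self.n_rhs)

    def rounded(self) -> Tuple[float, float, float]:
        """(support, confidence, lift) at report-table precision
        (6, 2, 2 decimals, half-up)."""
        return (
            round_half_up(self.support, 6),
            round_half_up(self.confidence, 2),
            round_half_up(self.lift, 2),
        )


def rule_metrics(
    n_joint: int, n_lhs: int, n_rhs: int, n_total: int
) -> Tuple[Fraction, Fraction, Fraction]:
    """Exact rational (support, confidence, lift) from counts."""
    if not 0 <= n_joint <= min(n_lhs, n_rhs) <= n_total:
        raise UserInputError(
            f"inconsistent counts: joint={n_joint}, lhs={n_lhs}, "
            f"rhs={n_rhs}, total={n_total}"
        )
    if n_lhs == 0:
        raise UserInputError("confidence undefined for an empty antecedent count")
    support = Fraction(n_joint, n_total)
    confidence = Fraction(n_joint, n_lhs)
    lift = Fraction(n_joint * n_total, n_lhs * n_rhs)
    return support, confidence, lift


def build_transactions(
    reports: Mapping[str, CaseReport],
    include_age_item: bool = False,
    te_item: str = TE_ITEM,
) -> List[Transaction]:
    """One transaction per report: drugs of all roles, history terms, the
    event flag item for cases, and optionally an ``age:<band>`` item."""
    out = []
    for r in reports.values():
        items: Set[str] = {d.drug_name for d in r.drugs}
        items |= {h.term for h in r.history}
        if r.is_te:
            items.add(te_item)
        if include_age_item and r.age_category != "unknown":
            items.add(f"age:{r.age_category}")
        out.append(Transaction(r.case_id, frozenset(items)))
    return out


def _tidsets(transactions: Sequence[Transaction]) -> Dict[str, Set[int]]:
    tid: Dict[str, Set[int]] = {}
    for i, t in enumerate(transactions):
        for item in t.items:
            tid.setdefault(item, set()).add(i)
    return tid


def apriori_frequent(
    transactions: Sequence[Transaction],
    min_support: float = 0.00001,
    maxlen: int = 3,
) -> Dict[Tuple[str, ...], int]:
    """All itemsets of size <= maxlen with support >= min_support.

    Returns a mapping of lexicographically sorted item tuples to absolute
    transaction counts. Downward closure (every non-empty subset of a
    returned itemset is returned) holds by construction and is asserted.
    """
    if not transactions:
        raise UserInputError("no transactions")
    n = len(transactions)
    # count threshold: smallest integer c with c / n >= min_support
    # (tiny slack so 0.25 * 4 counts 1, not 2, despite float representation)
    min_count = max(1, math.ceil(min_support * n - 1e-9))

    tid = _tidsets(transactions)
    frequent: Dict[Tuple[str, ...], int] = {}
    level: Dict[Tuple[str, ...], Set[int]] = {
        (item,): s for item, s in sorted(tid.items()) if len(s) >= min_count
    }
    frequent.update({k: len(s) for k, s in level.items()})

    k = 1
    while level and k < maxlen:
        keys = sorted(level)
        next_level: Dict[Tuple[str, ...], Set[int]] = {}
        for i, left in enumerate(keys):
            for right in keys[i + 1 :]:
                if left[:-1] != right[:-1]:
                    break  # sorted keys: no further shared prefix
                candidate = left + (right[-1],)
                # downward-closure pruning on all k-subsets
                if any(
                    candidate[:j] + candidate[j + 1 :] not in level
                    for j in range(len(candidate))
                ):
                    continue
                s = level[left] & tid[right[-1]]
                if len(s) >= min_count:
                    next_level[candidate] = s
        frequent.update({k_: len(s) for k_, s in next_level.items()})
        level = next_level
        k += 1

    # self-check: downward closure of the reported collection
    for itemset in frequent:
        for r in range(1, len(itemset)):
            for sub in combinations(itemset, r):
                assert sub in frequent, f"downward closure violated at {itemset}"
    return frequent


def generate_rules(
    frequent: Mapping[Tuple[str, ...], int],
    n_transactions: int,
    config: MiningConfig = MiningConfig(),
) -> List[AssociationRule]:
    """Rules X -> rhs_restriction from the frequent itemsets, confidence
    filtered and sorted by support desc, confidence desc, then lhs."""
    rhs = tuple(sorted(config.rhs_restriction))
    n_rhs = frequent.get(rhs)
    if n_rhs is None:
        return []
    rules = []
    for itemset, n_joint in frequent.items():
        if not set(rhs) < set(itemset):
            continue
        lhs = tuple(x for x in itemset if x not in config.rhs_restriction)
        if not lhs:
            continue
        n_lhs = frequent[lhs]  # guaranteed by downward closure
        if n_joint / n_lhs >= config.min_confidence - 1e-12:
            rules.append(
                AssociationRule(
                    lhs=lhs,
                    rhs=rhs,
                    n_joint=n_joint,
                    n_lhs=n_lhs,
                    n_rhs=n_rhs,
                    n_total=n_transactions,
                )
            )
    rules.sort(key=lambda r: (-r.support, -r.confidence, r.lhs))
    return rules


class Apriori:
    """Association-rule miner in the model/results idiom.

    Construct from transactions (see :func:`build_transactions`), call
    :meth:`fit`, inspect the returned :class:`RuleMiningResults`.
    """

    def __init__(
        self,
        transactions: Sequence[Transaction],
        config: MiningConfig = MiningConfig(),
    ) -> None:
        if not transactions:
            raise UserInputError("no transactions")
        self.transactions = list(transactions)
        self.config = config

    @classmethod
    def from_reports(
        cls, reports: Mapping[str, CaseReport], config: MiningConfig = MiningConfig()
    ) -> "Apriori":
        return cls(
            build_transactions(reports, include_age_item=config.include_age_item),
            config,
        )

    def fit(self) -> "RuleMiningResults":
        frequent = apriori_frequent(
            self.transactions, self.config.min_support, self.config.maxlen
        )
        rules = generate_rules(frequent, len(self.transactions), self.config)
        return RuleMiningResults(self, frequent, rules)


@dataclass
class RuleMiningResults:
    model: Apriori
    frequent_itemsets: Dict[Tuple[str, ...], int] = field(default_factory=dict)
    rules: List[AssociationRule] = field(default_factory=list)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        for r in self.rules:
            support, confidence, lift = r.rounded() if rounded else (
                r.support,
                r.confidence,
                r.lift,
            )
            rows.append(
                {
                    "lhs": "; ".join(r.lhs),
                    "rhs": "; ".join(r.rhs),
                    "support": support,
                    "confidence": confidence,
                    "lift": lift,
                    "n_joint": r.n_joint,
                    "n_lhs": r.n_lhs,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["lhs", "rhs", "support", "confidence", "lift", "n_joint", "n_lhs"],
        )

    def edge_list(self) -> pd.DataFrame:
        """Rule graph as (source item, rule index, weight=lift) edges for
        external plotting."""
        rows = []
        for i, r in enumerate(self.rules):
            for item in r.lhs:
                rows.append({"node": item, "rule": i, "weight": r.lift})
            for item in r.rhs:
                rows.append({"node": item, "rule": i, "weight": r.lift})
        return pd.DataFrame(rows, columns=["node", "rule", "weight"])

    def summary(self) -> str:
        lines = [
            f"Apriori rule mining: {len(self.model.transactions)} transactions, "
            f"{len(self.frequent_itemsets)} frequent itemsets, {len(self.rules)} rules",
            "=" * 72,
            self.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)
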