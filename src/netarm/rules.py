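"""Rule selection, subgroup characterization, and rule-as-classifier
diagnostics.

Selection mirrors the reported workflow: threshold filtering (strict ">" for
support, "≥" for lift and confidence, matching the printed operators),
removal of redundant rules (same antecedent/consequent attribute sets in a
different order), ranking by lift then support, item-frequency summaries,
second-pass mining against a composite consequent (e.g. females with CgA >4
ULN) to characterize a subgroup, and evaluation of a rule antecedent as a
binary classifier (PPV/NPV/sensitivity/specificity) within an optional
stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .apriori import (AssociationRule, mine_rules_for_rhs, rule_metrics)
from .categorize import Transaction, TransactionDB


class RuleFilter(BaseModel):
    """Threshold predicate applied to every rule metric.

    Operators are configurable per threshold; the defaults follow the
    printed filters: support strictly ">", lift and confidence "≥".
    """

    model_config = ConfigDict(frozen=True)
    min_support_count: int = Field(ge=0)
    min_confidence: float = Field(ge=0.0, le=1.0)
    min_lift: float = Field(ge=0.0)
    support_strict: bool = True
    confidence_strict: bool = False
    lift_strict: bool = False

    def accepts(self, rule: AssociationRule) -> bool:
        m = rule.metrics
        ok_s = (m.support_count > self.min_support_count if self.support_strict
                else m.support_count >= self.min_support_count)
        ok_c = (m.confidence > self.min_confidence if self.confidence_strict
                else m.confidence >= self.min_confidence)
        ok_l = (m.lift > self.min_lift if self.lift_strict
                else m.lift >= self.min_lift)
        return ok_s and ok_c and ok_l


# Named filter presets.  "characterization" selects on support ≥8 and
# confidence ≥80% only; the very high lift (>4.7) of the resulting rules is
# a reported property of the subgroup, not a selection threshold.
PROFILES: dict[str, RuleFilter] = {
    "sinet_pd": RuleFilter(min_support_count=20, min_confidence=0.70, min_lift=1.2),
    "sinet_sd": RuleFilter(min_support_count=14, min_confidence=0.70, min_lift=1.2),
    "pnet_pd": RuleFilter(min_support_count=14, min_confidence=0.70, min_lift=1.25),
    "characterization": RuleFilter(min_support_count=8, support_strict=False,
                                   min_confidence=0.80, min_lift=0.0),
}


def filter_rules(rules: Iterable[AssociationRule],
                 rule_filter: RuleFilter) -> list[AssociationRule]:
    """Rules meeting all thresholds."""
    return [r for r in rules if rule_filter.accepts(r)]


def remove_redundant(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """One rule per unique (LHS-as-set, RHS-as-set) pair; the canonical
    (sorted-label) representative is retained."""
    seen: set[tuple[frozenset, frozenset]] = set()
    out: list[AssociationRule] = []
    for r in rules:
        key = (frozenset(r.lhs), frozenset(r.rhs))
        if key in seen:
            continue
        seen.add(key)
        canonical = AssociationRule(tuple(sorted(r.lhs)), tuple(sorted(r.rhs)),
                                    r.metrics)
        out.append(canonical)
    return out


def rank_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Sort by lift desc, then support desc, then canonical LHS label asc."""
    return sorted(rules, key=lambda r: (-r.metrics.lift, -r.metrics.support_count,
                                        r.lhs, r.rhs))


def item_frequency(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Per LHS item: number and fraction of rules whose LHS contains it."""
    counts: dict[str, int] = {}
    for r in rules:
        for item in r.lhs:
            counts[item] = counts.get(item, 0) + 1
    n = len(rules)
    rows = [
        {"item": item, "n_rules": c, "fraction": c / n}
        for item, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["item", "n_rules", "fraction"])


def select_rules(rules: Iterable[AssociationRule],
                 rule_filter: RuleFilter) -> list[AssociationRule]:
    """filter → dedupe → rank (the full selection pipeline)."""
    return rank_rules(remove_redundant(filter_rules(rules, rule_filter)))


def characterize_subgroup(db: TransactionDB, target_rhs: Iterable[str],
                          rule_filter: RuleFilter,
                          max_lhs: int = 3) -> list[AssociationRule]:
    """Second-pass mining with a fixed composite consequent.

    Mines all antecedents X with count(X ∪ target) at least the filter's
    support threshold, computes confidence and lift against the full
    database (lift baseline = count(target)/N), then filters, dedupes and
    ranks.
    """
    min_count = rule_filter.min_support_count + (1 if rule_filter.support_strict else 0)
    rules = mine_rules_for_rhs(db, target_rhs, max(min_count, 1), max_lhs=max_lhs)
    return select_rules(rules, rule_filter)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2×2 table of rule-positivity vs outcome within a stratum.

    Proportions are ``None`` when their denominator is zero (undefined, not
    zero).  ``as_percentages`` rounds half-away-from-zero to integers, as in
    clinical reporting.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    stratum: Optional[str] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def as_percentages(self) -> dict[str, Optional[int]]:
        return {
            name: round_half_away(100.0 * v) if v is not None else None
            for name, v in [("ppv", self.ppv), ("npv", self.npv),
                            ("sensitivity", self.sensitivity),
                            ("specificity", self.specificity)]
        }

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "stratum": self.stratum,
            "ppv": self.ppv, "npv": self.npv,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "percentages": self.as_percentages(),
        }


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 → 3, −2.5 → −3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def evaluate_rule_as_classifier(
    antecedent_items: Iterable[str],
    outcome: str,
    db: TransactionDB,
    stratum: Optional[str] = None,
) -> DiagnosticMetrics:
    """Treat rule-positivity (carrying all antecedent items) as a test for
    the outcome, within the stratum (or the whole cohort)."""
    antecedent = frozenset(antecedent_items)
    if not antecedent:
        raise ValueError("antecedent must be non-empty")
    if outcome not in ("SD", "PD"):
        raise ValueError("outcome must be 'SD' or 'PD'")
    transactions = db.transactions
    if stratum is not None:
        if stratum not in db.item_catalog:
            raise ValueError(f"stratum item {stratum!r} absent from the database")
        transactions = [t for t in transactions if stratum in t.items]
        if not transactions:
            raise ValueError(f"stratum {stratum!r} is empty")
    tp = fp = fn = tn = 0
    for t in transactions:
        positive = antecedent <= t.items
        diseased = t.outcome_item == outcome
        if positive and diseased:
            tp += 1
        elif positive:
            fp += 1
        elif diseased:
            fn += 1
        else:
            tn += 1
    return DiagnosticMetrics(tp, fp, fn, tn, stratum=stratum)
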