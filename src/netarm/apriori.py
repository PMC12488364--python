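"""Level-wise Apriori frequent-itemset mining and rule generation.

An association rule X → Y (X ∩ Y = ∅) is scored with
support (the absolute number of transactions containing X ∪ Y),
confidence = count(X ∪ Y) / count(X), and
lift = confidence / (count(Y) / N).

Counting uses one bitmask of transactions per item; an itemset's support is
the popcount of the AND of its members' masks, so all metrics are exact
integer ratios.  Candidate k-itemsets are generated by joining frequent
(k−1)-itemsets that share a (k−2)-prefix and pruning candidates with any
infrequent (k−1)-subset.  All orderings are canonical-lexicographic, so the
output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .categorize import TransactionDB

DISPLAY_SEP = " ∩ "
MACHINE_SEP = " & "


@dataclass(frozen=True)
class Itemset:
    """A sorted itemset with its absolute support count."""

    items: tuple[str, ...]
    support_count: int

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.items))) != self.items:
            raise ValueError("items must be sorted and unique")
        if self.support_count < 0:
            raise ValueError("support_count must be >= 0")


@dataclass(frozen=True)
class RuleMetrics:
    support_count: int
    support_fraction: float
    confidence: float
    lift: float


@dataclass(frozen=True)
class AssociationRule:
    """X → Y with X ∩ Y = ∅, both non-empty, plus its metrics."""

    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    metrics: RuleMetrics

    def __post_init__(self) -> None:
        if not self.lhs or not self.rhs:
            raise ValueError("both rule sides must be non-empty")
        if set(self.lhs) & set(self.rhs):
            raise ValueError("lhs and rhs must be disjoint")

    @property
    def support_count(self) -> int:
        return self.metrics.support_count

    @property
    def confidence(self) -> float:
        return self.metrics.confidence

    @property
    def lift(self) -> float:
        return self.metrics.lift

    def label(self, sep: str = DISPLAY_SEP) -> str:
        return f"{sep.join(self.lhs)} => {sep.join(self.rhs)}"


def item_masks(db: TransactionDB) -> dict[str, int]:
    """One transaction-bitmask integer per item (bit i = transaction i)."""
    masks: dict[str, int] = {}
    for i, t in enumerate(db.transactions):
        bit = 1 << i
        for item in t.items:
            masks[item] = masks.get(item, 0) | bit
    return masks


def _count(masks: dict[str, int], items: Iterable[str]) -> int:
    it = iter(items)
    try:
        acc = masks[next(it)]
    except StopIteration:
        raise ValueError("cannot count the empty itemset")
    except KeyError as exc:
        raise KeyError(f"item {exc.args[0]!r} absent from the database") from None
    for item in it:
        try:
            acc &= masks[item]
        except KeyError as exc:
            raise KeyError(f"item {exc.args[0]!r} absent from the database") from None
        if acc == 0:
            return 0
    return acc.bit_count()


def mine_frequent_itemsets(db: TransactionDB, min_support_count: int,
                           max_size: int = 4) -> list[Itemset]:
    """All itemsets of size ≤ max_size with support ≥ min_support_count."""
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if db.N == 0:
        return []
    masks = item_masks(db)
    out: list[Itemset] = []
    level: dict[tuple[str, ...], int] = {}
    for item in sorted(masks):
        c = masks[item].bit_count()
        if c >= min_support_count:
            level[(item,)] = c
    out.extend(Itemset(k, v) for k, v in sorted(level.items()))
    k = 1
    while level and k < max_size:
        keys = sorted(level)
        frequent_prev = set(keys)
        next_level: dict[tuple[str, ...], int] = {}
        # join step: two frequent k-sets sharing their (k-1)-prefix
        by_prefix: dict[tuple[str, ...], list[str]] = {}
        for key in keys:
            by_prefix.setdefault(key[:-1], []).append(key[-1])
        for prefix, lasts in by_prefix.items():
            for a, b in combinations(lasts, 2):
                cand = prefix + (a, b)  # lasts are sorted, so cand is sorted
                # prune: every k-subset must be frequent
                if k >= 2 and any(
                    cand[:i] + cand[i + 1:] not in frequent_prev
                    for i in range(len(cand) - 2)  # dropping a or b gives known-frequent sets
                ):
                    continue
                c = _count(masks, cand)
                if c >= min_support_count:
                    next_level[cand] = c
        out.extend(Itemset(key, v) for key, v in sorted(next_level.items()))
        level = next_level
        k += 1
    return out


def _normalize_rhs(rhs_constraint) -> list[tuple[str, ...]]:
    if isinstance(rhs_constraint, str):
        return [(rhs_constraint,)]
    out = []
    for y in rhs_constraint:
        if isinstance(y, str):
            out.append((y,))
        else:
            out.append(tuple(sorted(set(y))))
    return out


def generate_rules(frequent: Sequence[Itemset], db: TransactionDB,
                   rhs_constraint, max_lhs: int = 3) -> list[AssociationRule]:
    """Rules X → Y with Y in the constraint, |X| ≤ max_lhs, X ∪ Y frequent.

    ``frequent`` must have been mined on ``db`` with a max_size of at least
    max_lhs + |Y|, so every needed subset count is available.
    """
    if max_lhs < 1:
        raise ValueError("max_lhs must be >= 1")
    targets = _normalize_rhs(rhs_constraint)
    catalog = db.item_catalog
    for y in targets:
        for item in y:
            if item not in catalog:
                raise ValueError(f"consequent item {item!r} absent from the database")
    counts = {fs.items: fs.support_count for fs in frequent}
    N = db.N
    rules: list[AssociationRule] = []
    for y in targets:
        yset = set(y)
        c_y = counts.get(y)
        if c_y is None or c_y == 0:
            continue
        for fs in frequent:
            fset = set(fs.items)
            if not yset <= fset:
                continue
            xsize = len(fset) - len(y)
            if not 1 <= xsize <= max_lhs:
                continue
            x = tuple(sorted(fset - yset))
            c_x = counts[x]  # anti-monotonicity: X ⊆ frequent set => frequent
            conf = fs.support_count / c_x
            lift = conf * N / c_y
            rules.append(AssociationRule(
                lhs=x, rhs=y,
                metrics=RuleMetrics(fs.support_count, fs.support_count / N,
                                    conf, lift)))
    rules.sort(key=lambda r: (r.rhs, len(r.lhs), r.lhs))
    return rules


def rule_metrics(db: TransactionDB, lhs: Iterable[str],
                 rhs: Iterable[str]) -> RuleMetrics:
    """Exact metrics of a single rule by direct counting."""
    lhs = tuple(sorted(set(lhs)))
    rhs = tuple(sorted(set(rhs)))
    if set(lhs) & set(rhs):
        raise ValueError("lhs and rhs must be disjoint")
    masks = item_masks(db)
    c_union = _count(masks, lhs + rhs)
    c_x = _count(masks, lhs)
    c_y = _count(masks, rhs)
    if c_x == 0 or c_y == 0:
        raise ValueError("rule sides must occur in the database")
    conf = c_union / c_x
    return RuleMetrics(c_union, c_union / db.N, conf, conf * db.N / c_y)


def mine_rules_for_rhs(db: TransactionDB, rhs_items: Iterable[str],
                       min_support_count: int, max_lhs: int = 3,
                       exclude_items: Iterable[str] = ()) -> list[AssociationRule]:
    """All rules X → Y for one fixed (possibly composite) consequent Y.

    Mines frequent antecedents on the conditional database of transactions
    containing Y (exact: count(X ∪ Y) ≥ min_support_count is equivalent to X
    being frequent there), then computes confidence and lift against the full
    database.
    """
    y = tuple(sorted(set(rhs_items)))
    masks = item_masks(db)
    for item in y:
        if item not in masks:
            raise ValueError(f"consequent item {item!r} absent from the database")
    y_mask = masks[y[0]]
    for item in y[1:]:
        y_mask &= masks[item]
    c_y = y_mask.bit_count()
    if c_y == 0:
        raise ValueError(f"consequent {y} occurs in no transaction")
    drop = set(y) | set(exclude_items)
    from .categorize import Transaction  # local import to avoid cycle at module load
    cond = TransactionDB([
        Transaction(t.patient_id, t.items - drop, t.outcome_item)
        for i, t in enumerate(db.transactions) if (y_mask >> i) & 1
    ])
    frequent_x = mine_frequent_itemsets(cond, min_support_count, max_size=max_lhs)
    N = db.N
    rules = []
    for fs in frequent_x:
        c_x = _count(masks, fs.items)
        conf = fs.support_count / c_x
        lift = conf * N / c_y
        rules.append(AssociationRule(
            lhs=fs.items, rhs=y,
            metrics=RuleMetrics(fs.support_count, fs.support_count / N, conf, lift)))
    rules.sort(key=lambda r: (len(r.lhs), r.lhs))
    return rules


# --------------------------------------------------------------------------
# rules CSV (machine separator " & ", full precision + 2-decimal display)

def rules_to_frame(rules: Sequence[AssociationRule],
                   sep: str = MACHINE_SEP) -> pd.DataFrame:
    rows = [
        {
            "lhs": sep.join(r.lhs),
            "rhs": sep.join(r.rhs),
            "support_count": r.metrics.support_count,
            "support_fraction": r.metrics.support_fraction,
            "confidence": r.metrics.confidence,
            "lift": r.metrics.lift,
            "confidence_2dp": round(r.metrics.confidence, 2),
            "lift_2dp": round(r.metrics.lift, 2),
        }
        for r in rules
    ]
    return pd.DataFrame(rows, columns=[
        "lhs", "rhs", "support_count", "support_fraction", "confidence",
        "lift", "confidence_2dp", "lift_2dp"])


def write_rules(rules: Sequence[AssociationRule], path: str | Path,
                sep: str = MACHINE_SEP) -> None:
    rules_to_frame(rules, sep=sep).to_csv(path, index=False, encoding="utf-8")


def read_rules(path: str | Path, sep: str = MACHINE_SEP) -> list[AssociationRule]:
    df = pd.read_csv(path, encoding="utf-8")
    out = []
    for _, row in df.iterrows():
        out.append(AssociationRule(
            lhs=tuple(sorted(str(row["lhs"]).split(sep))),
            rhs=tuple(sorted(str(row["rhs"]).split(sep))),
            metrics=RuleMetrics(int(row["support_count"]),
                                float(row["support_fraction"]),
                                float(row["confidence"]), float(row["lift"]))))
    return out
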