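"""Independent brute-force oracles used to cross-check the miner.

Everything here counts by exhaustive enumeration and scanning; nothing is
shared with the production bitset implementation.
"""

from itertools import combinations

from netarm import TransactionDB


def brute_force_itemsets(db: TransactionDB, min_support_count: int,
                         max_size: int):
    """All frequent itemsets by enumerating every subset of the catalog."""
    catalog = sorted(db.item_catalog)
    sets = [t.items for t in db.transactions]
    out = {}
    for k in range(1, max_size + 1):
        for combo in combinations(catalog, k):
            c = sum(1 for s in sets if set(combo) <= s)
            if c >= min_support_count:
                out[combo] = c
    return out


def brute_force_rules(db: TransactionDB, frequent: dict, rhs_targets,
                      max_lhs: int):
    """All rules X -> Y from the frequent table, metrics by definition."""
    sets = [t.items for t in db.transactions]
    N = len(sets)

    def count(items):
        return sum(1 for s in sets if set(items) <= s)

    rules = {}
    targets = [tuple(sorted(y)) if not isinstance(y, str) else (y,)
               for y in rhs_targets]
    for y in targets:
        c_y = count(y)
        if c_y == 0:
            continue
        for f in frequent:
            if not set(y) <= set(f):
                continue
            x = tuple(sorted(set(f) - set(y)))
            if not 1 <= len(x) <= max_lhs:
                continue
            c_u = frequent[f]
            c_x = count(x)
            conf = c_u / c_x
            rules[(x, y)] = (c_u, c_u / N, conf, conf * N / c_y)
    return rules


def brute_force_2x2(transactions, antecedent, outcome):
    """2x2 table of antecedent-positivity vs outcome by direct recount."""
    tp = fp = fn = tn = 0
    for t in transactions:
        pos = set(antecedent) <= t.items
        dis = t.outcome_item == outcome
        tp += pos and dis
        fp += pos and not dis
        fn += (not pos) and dis
        tn += (not pos) and (not dis)
    return tp, fp, fn, tn
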