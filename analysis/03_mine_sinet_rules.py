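#!/usr/bin/env python
"""Mine and select siNET progression rules.

Apriori with up to three antecedent attributes and an SD/PD consequent;
selection at the study thresholds (PD: support >20, lift ≥1.2, confidence
≥70%; SD: support >14, same lift/confidence).  Writes the selected rules and
the antecedent item-frequency table; prints the top 5 of each outcome.
"""

from pathlib import Path

from netarm import PROFILES, generate_rules, mine_frequent_itemsets, select_rules
from netarm.apriori import write_rules
from netarm.categorize import read_basket
from netarm.rules import item_frequency

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    db = read_basket(ROOT / "sinet.basket")
    frequent = mine_frequent_itemsets(db, min_support_count=15, max_size=4)
    mined = generate_rules(frequent, db, ["PD", "SD"], max_lhs=3)
    print(f"{len(frequent)} frequent itemsets, {len(mined)} candidate rules")
    for outcome, profile in (("PD", "sinet_pd"), ("SD", "sinet_sd")):
        sel = select_rules([r for r in mined if r.rhs == (outcome,)],
                           PROFILES[profile])
        write_rules(sel, ROOT / f"sinet_{outcome.lower()}_rules.csv")
        print(f"\n{len(sel)} rules selected for {outcome} ({profile}); top 5 "
              "by lift and support:")
        for r in sel[:5]:
            print(f"  {r.label():70s} support={r.support_count:3d} "
                  f"conf={r.confidence:.2f} lift={r.lift:.2f}")
        if outcome == "PD":
            freq = item_frequency(sel)
            freq.to_csv(ROOT / "sinet_pd_item_frequency.csv", index=False)
            top = ", ".join(freq["item"].head(5))
            print(f"most frequent PD antecedents: {top}")


if __name__ == "__main__":
    main()
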