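#!/usr/bin/env python
"""Mine progression rules in the pNET cohort.

Small-cohort configuration (n=30): PD rules at support >14, lift ≥1.25,
confidence ≥70%.  SD rules are not reported (8 patients).
"""

from pathlib import Path

from netarm import PROFILES, generate_rules, mine_frequent_itemsets, select_rules
from netarm.apriori import write_rules
from netarm.categorize import read_basket
from netarm.rules import item_frequency

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    db = read_basket(ROOT / "pnet.basket")
    frequent = mine_frequent_itemsets(db, min_support_count=15, max_size=4)
    mined = generate_rules(frequent, db, ["PD"], max_lhs=3)
    sel = select_rules(mined, PROFILES["pnet_pd"])
    write_rules(sel, ROOT / "pnet_pd_rules.csv")
    print(f"{len(sel)} pNET PD rules selected; top 5 by lift and support:")
    for r in sel[:5]:
        print(f"  {r.label():70s} support={r.support_count:3d} "
              f"conf={r.confidence:.2f} lift={r.lift:.2f}")
    freq = item_frequency(sel)
    freq.to_csv(ROOT / "pnet_pd_item_frequency.csv", index=False)
    if not freq.empty:
        print("most frequent PD antecedents:", ", ".join(freq["item"].head(5)))


if __name__ == "__main__":
    main()
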