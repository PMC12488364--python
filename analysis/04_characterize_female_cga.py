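#!/usr/bin/env python
"""Characterize the female / CgA >4 ULN subgroup.

Second-pass mining with the composite consequent {female, CgA >4 ULN}
(support ≥8, confidence ≥80%), and evaluation of the CgA >4 ULN antecedent
as a progression classifier within the female and male strata (PPV/NPV).
"""

import json
from pathlib import Path

from netarm import PROFILES, characterize_subgroup, evaluate_rule_as_classifier
from netarm.apriori import write_rules
from netarm.categorize import read_basket

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    db = read_basket(ROOT / "sinet.basket")
    target = ("female", "CgA > 4 ULN")
    rules = characterize_subgroup(db, target, PROFILES["characterization"],
                                  max_lhs=3)
    write_rules(rules, ROOT / "female_cga_characterization.csv")
    baseline = sum(1 for t in db.transactions if set(target) <= t.items) / db.N
    print(f"{len(rules)} characterization rules for RHS {list(target)} "
          f"(baseline rate {baseline:.2f}); top 3:")
    for r in rules[:3]:
        print(f"  {r.label():70s} support={r.support_count:3d} "
              f"conf={r.confidence:.2f} lift={r.lift:.2f}")

    diagnostics = {}
    for stratum in ("female", "male"):
        dm = evaluate_rule_as_classifier(["CgA > 4 ULN"], "PD", db,
                                         stratum=stratum)
        diagnostics[stratum] = dm.as_dict()
        pct = dm.as_percentages()
        print(f"{stratum}: 2x2 = (tp={dm.tp}, fp={dm.fp}, fn={dm.fn}, "
              f"tn={dm.tn}); PPV={pct['ppv']}% NPV={pct['npv']}%")
    (ROOT / "female_cga_diagnostics.json").write_text(
        json.dumps(diagnostics, indent=2), encoding="utf-8")


if __name__ == "__main__":
    main()
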