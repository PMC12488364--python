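#!/usr/bin/env python
"""Derive control-CI cut-offs and encode both cohorts as transactions.

The control mean 95% CI of each of the 92 proteins defines the "<low" /
">high" items; fixed clinical thresholds add CgA >4 ULN, 5-HIAA >455 (%ULN),
Ki-67 >5% and >10 metastases.  Outputs: cutoffs.json and one basket file per
cohort under results/.
"""

from pathlib import Path

from netarm import derive_control_ci_cutoffs, encode_cohort
from netarm.categorize import cutoffs_to_json, write_basket
from netarm.simulate import read_cohort, read_controls

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    controls = read_controls(ROOT / "data" / "controls.csv")
    cutoffs = derive_control_ci_cutoffs(controls, ci_level=0.95)
    cutoffs_to_json(cutoffs, ROOT / "cutoffs.json")
    cpe = cutoffs.specs["CPE"]
    print(f"control-CI cut-offs for {len(cutoffs.biomarker_specs())} proteins; "
          f"e.g. CPE items: '{cpe.low_label}' / '{cpe.high_label}'")
    for name in ("sinet", "pnet"):
        patients = read_cohort(ROOT / "data" / f"{name}_cohort.csv")
        db = encode_cohort(patients, cutoffs)
        write_basket(db, ROOT / f"{name}.basket")
        sizes = [len(t.items) for t in db.transactions]
        print(f"{name}: {db.N} transactions, {len(db.item_catalog)} distinct "
              f"items, {sum(sizes)/len(sizes):.1f} items per patient")


if __name__ == "__main__":
    main()
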