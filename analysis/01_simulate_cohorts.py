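#!/usr/bin/env python
"""Generate the study-sized synthetic cohorts.

Writes the siNET cohort (n=115, 65 PD / 50 SD), the pNET cohort (n=30,
22 PD / 8 SD) and the shared control cohort (n=143) under results/data/,
together with the generating configurations.
"""

from collections import Counter
from pathlib import Path

from netarm import generate_controls, generate_patients, pnet_config, sinet_config
from netarm.simulate import write_cohort, write_config, write_controls

STUDY_SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, cfg in (("sinet", sinet_config(seed=STUDY_SEED)),
                      ("pnet", pnet_config(seed=STUDY_SEED + 1))):
        patients = generate_patients(cfg)
        write_cohort(patients, OUT / f"{name}_cohort.csv")
        write_config(cfg, OUT / f"{name}_config.json")
        counts = Counter(p.outcome for p in patients)
        females = sum(p.gender == "F" for p in patients)
        print(f"{name}: n={len(patients)} PD={counts['PD']} SD={counts['SD']} "
              f"female={females}")
    controls = generate_controls(sinet_config(seed=STUDY_SEED))
    write_controls(controls, OUT / "controls.csv")
    print(f"controls: n={len(controls)}")


if __name__ == "__main__":
    main()
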