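"""The 92-protein plasma biomarker panel and its default distribution parameters.

The cohorts carry 92 cancer-related plasma proteins measured on a relative
log-abundance (NPX-like) scale.  The panel below contains every protein that
appears in a reported rule or frequency table (CPE, WISP-1, VIM, CD160,
PVRL4, TRAIL, DLL1, ITGAV, ABL1, ADAM-8, TGF-alpha, MK, PPY, IFN-gamma-R1,
MIA, TFPI-2, 5'-NT, ICOSLG, VEGFR-2, TFF3, ...) padded with further oncology
panel symbols to 92 entries.

Default distribution parameters: proteins with a literature-supported
direction of effect get a group shift (in units of the control SD); all other
proteins are null (same distribution in stable and progressive disease).
Control-level means and SDs for proteins without printed summary statistics
are fixed, deterministically generated values on a plausible NPX range.
"""

from __future__ import annotations

import numpy as np

# Protein symbols used in reported rules / frequency tables, in panel order.
PANEL_92: tuple[str, ...] = (
    "CPE", "WISP-1", "VIM", "CD160", "PVRL4", "TRAIL", "DLL1", "ITGAV",
    "ABL1", "ADAM-8", "TGF-alpha", "MK", "PPY", "IFN-gamma-R1", "MIA",
    "TFPI-2", "5'-NT", "ICOSLG", "VEGFR-2", "TFF3", "DcR3", "CEA", "CAIX",
    "CXCL13", "ERBB2", "ERBB3", "ERBB4", "EGF", "AREG", "hK11", "hK14",
    "hK8", "PSA", "FR-alpha", "FR-gamma", "MSLN", "MUC-16", "WFDC2",
    "FASLG", "TNFSF13", "TNFRSF4", "TNFRSF6B", "TNFRSF19", "CD27", "CD48",
    "CD70", "GZMB", "GZMH", "ICOSLG-2", "LY9", "S100A4", "S100A11", "SCAMP3",
    "SDC1", "SEZ6L", "SPARC", "TCL1A", "TXLNA", "VIM-2", "XPNPEP2", "ADAM-TS15",
    "ANXA1", "CDKN1A", "CESC1", "CPVL", "CRNN", "CYR61", "DLL4", "EPHA2",
    "ESM-1", "FADD", "FCRLB", "GPC1", "GPNMB", "IGF1R", "ITGB5", "KLK13",
    "LYPD3", "MAD-homolog-5", "MetAP-2", "MIC-A/B", "NTRK3", "PODXL", "PVRL1",
    "RET", "RSPO3", "SCF", "TGF-BR2", "TLR3", "VEGFA", "WIF-1", "YES1",
)

assert len(PANEL_92) == 92
assert len(set(PANEL_92)) == 92

# Effects on the NPX scale, in units of the control SD, applied to the
# progressive-disease group (positive = higher in PD) or, when keyed "SD",
# to the stable-disease group.  Directions follow the reported associations:
# WISP-1/VIM/DLL1 high in PD, CD160/PVRL4 high in SD, TRAIL/ITGAV low in PD.
PD_SHIFTS_SD_UNITS: dict[str, float] = {
    "WISP-1": 0.55,
    "VIM": 0.45,
    "ABL1": 0.40,
    "TFPI-2": 0.40,
    "DLL1": 0.50,
    "5'-NT": 0.40,
    "TRAIL": -0.50,
    "ITGAV": -0.45,
    "ICOSLG": -0.35,
    "VEGFR-2": -0.30,
}
SD_SHIFTS_SD_UNITS: dict[str, float] = {
    "CD160": 0.50,
    "PVRL4": 0.45,
    "ADAM-8": 0.35,
    "TGF-alpha": 0.30,
    "MK": 0.30,
    "PPY": 0.35,
    "IFN-gamma-R1": 0.30,
    "MIA": 0.30,
}

# CPE has printed group summaries (control 3.09 (0.34), PD 3.32 (0.74),
# SD 2.96 (0.33)); it is parameterized explicitly in the cohort config.
CPE_CONTROL = (3.09, 0.34)
CPE_PD = (3.32, 0.74)
CPE_SD = (2.96, 0.33)

_PARAM_SEED = 92_143  # fixed: panel parameter catalog, independent of cohort seeds


def default_panel_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Default (mean, sd) per protein for control / SD / PD groups.

    Control means are fixed draws on a plausible NPX range (2-10) with SDs
    in 0.25-1.0; the same rng seed is always used, so the catalog is a
    constant of the package.  Group means are control mean plus the
    configured shift (in control-SD units).
    """
    rng = np.random.default_rng(_PARAM_SEED)
    means = rng.uniform(2.0, 10.0, size=92)
    sds = rng.uniform(0.25, 1.0, size=92)
    params: dict[str, dict[str, tuple[float, float]]] = {}
    for name, mu, sigma in zip(PANEL_92, means, sds):
        if name == "CPE":
            params[name] = {
                "control": CPE_CONTROL,
                "SD": CPE_SD,
                "PD": CPE_PD,
            }
            continue
        pd_shift = PD_SHIFTS_SD_UNITS.get(name, 0.0) * sigma
        sd_shift = SD_SHIFTS_SD_UNITS.get(name, 0.0) * sigma
        params[name] = {
            "control": (float(mu), float(sigma)),
            "SD": (float(mu + sd_shift), float(sigma)),
            "PD": (float(mu + pd_shift), float(sigma)),
        }
    return params
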