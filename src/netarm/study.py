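"""End-to-end study runner: simulate → categorize → mine → select →
characterize → evaluate → stats, with a checksum manifest and run log."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import apriori, categorize, group_stats, rules, simulate


class StudyConfig(BaseModel):
    """Configuration of a full analysis run over one synthetic cohort."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    cohort_config: simulate.CohortConfig
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    pd_profile: str = "sinet_pd"
    sd_profile: str = "sinet_sd"
    characterization_profile: str = "characterization"
    characterization_rhs: tuple[str, ...] = ("female", "CgA > 4 ULN")
    evaluate_antecedent: tuple[str, ...] = ("CgA > 4 ULN",)
    evaluate_strata: tuple[str, ...] = ("female", "male")
    evaluate_outcome: str = "PD"
    min_support_count: int = Field(default=20, ge=1)
    max_lhs: int = Field(default=3, ge=1)
    item_separator: str = apriori.MACHINE_SEP
    decimals: int = 2

    @model_validator(mode="after")
    def _profiles_exist(self) -> "StudyConfig":
        for name in (self.pd_profile, self.sd_profile, self.characterization_profile):
            if name not in rules.PROFILES:
                raise ValueError(f"unknown filter profile {name!r}")
        return self


@dataclass
class StageOutput:
    stage: str
    path: Path
    sha256: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Run every stage, write all outputs under ``outdir`` and return the
    manifest (also written as ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[StageOutput] = []
    log_lines: list[str] = [f"seed={config.cohort_config.seed}",
                            f"ci_level={config.ci_level}"]

    def record(stage: str, path: Path) -> None:
        outputs.append(StageOutput(stage, path, _sha256(path)))

    def stage_guard(stage: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        return _Ctx()

    # 1. simulate
    with stage_guard("simulate"):
        patients = simulate.generate_patients(config.cohort_config)
        controls = simulate.generate_controls(config.cohort_config)
        simulate.write_cohort(patients, outdir / "cohort.csv")
        simulate.write_controls(controls, outdir / "controls.csv")
        simulate.write_config(config.cohort_config, outdir / "cohort_config.json")
    record("simulate", outdir / "cohort.csv")
    record("simulate", outdir / "controls.csv")
    record("simulate", outdir / "cohort_config.json")
    log_lines.append(f"simulate: n={len(patients)} controls={len(controls)}")

    # 2. categorize
    with stage_guard("categorize"):
        cutoffs = categorize.derive_control_ci_cutoffs(controls, config.ci_level)
        db = categorize.encode_cohort(patients, cutoffs)
        categorize.cutoffs_to_json(cutoffs, outdir / "cutoffs.json")
        categorize.write_basket(db, outdir / "transactions.basket")
    record("categorize", outdir / "cutoffs.json")
    record("categorize", outdir / "transactions.basket")
    log_lines.append(f"categorize: N={db.N} items={len(db.item_catalog)}")

    # 3. mine
    with stage_guard("mine"):
        frequent = apriori.mine_frequent_itemsets(
            db, config.min_support_count, max_size=config.max_lhs + 1)
        mined = apriori.generate_rules(frequent, db, rhs_constraint=["PD", "SD"],
                                       max_lhs=config.max_lhs)
        apriori.write_rules(mined, outdir / "rules.csv", sep=config.item_separator)
    record("mine", outdir / "rules.csv")
    log_lines.append(f"mine: frequent={len(frequent)} rules={len(mined)} "
                     f"min_support_count={config.min_support_count} "
                     f"max_lhs={config.max_lhs}")

    # 4. select
    with stage_guard("select"):
        pd_rules = rules.select_rules(
            [r for r in mined if r.rhs == ("PD",)], rules.PROFILES[config.pd_profile])
        sd_rules = rules.select_rules(
            [r for r in mined if r.rhs == ("SD",)], rules.PROFILES[config.sd_profile])
        apriori.write_rules(pd_rules + sd_rules, outdir / "selected_rules.csv",
                            sep=config.item_separator)
        freq_table = rules.item_frequency(pd_rules)
        freq_table.to_csv(outdir / "item_frequency.csv", index=False)
    record("select", outdir / "selected_rules.csv")
    record("select", outdir / "item_frequency.csv")
    log_lines.append(
        f"select: pd_profile={config.pd_profile} -> {len(pd_rules)} rules; "
        f"sd_profile={config.sd_profile} -> {len(sd_rules)} rules")

    # 5. characterize
    with stage_guard("characterize"):
        catalog = db.item_catalog
        if all(i in catalog for i in config.characterization_rhs):
            char_rules = rules.characterize_subgroup(
                db, config.characterization_rhs,
                rules.PROFILES[config.characterization_profile],
                max_lhs=config.max_lhs)
        else:
            char_rules = []
        apriori.write_rules(char_rules, outdir / "characterization_rules.csv",
                            sep=config.item_separator)
    record("characterize", outdir / "characterization_rules.csv")
    log_lines.append(f"characterize: rhs={list(config.characterization_rhs)} "
                     f"-> {len(char_rules)} rules")

    # 6. evaluate
    with stage_guard("evaluate"):
        diagnostics = {}
        for stratum in config.evaluate_strata:
            if stratum not in db.item_catalog:
                continue
            dm = rules.evaluate_rule_as_classifier(
                config.evaluate_antecedent, config.evaluate_outcome, db,
                stratum=stratum)
            diagnostics[stratum] = dm.as_dict()
        (outdir / "diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2), encoding="utf-8")
    record("evaluate", outdir / "diagnostics.json")
    log_lines.append(f"evaluate: antecedent={list(config.evaluate_antecedent)} "
                     f"strata={list(diagnostics)}")

    # 7. stats
    with stage_guard("stats"):
        cpe_pd = [p.biomarkers["CPE"] for p in patients if p.outcome == "PD"]
        cpe_sd = [p.biomarkers["CPE"] for p in patients if p.outcome == "SD"]
        anova = group_stats.ls_means_anova(
            [p.biomarkers["CPE"] for p in patients],
            [p.outcome for p in patients],
            [p.treatment for p in patients])
        logit = group_stats.logistic_group_test(
            [p.outcome for p in patients], [p.treatment for p in patients])
        auc_cga = group_stats.roc_auc(
            [np.log(p.cga_uln) for p in patients],
            [p.outcome == "PD" for p in patients])
        stats_payload = {
            "cpe_summary": {
                "PD": group_stats.summarize_group(cpe_pd, config.ci_level, "PD").__dict__,
                "SD": group_stats.summarize_group(cpe_sd, config.ci_level, "SD").__dict__,
            },
            "cpe_anova": {
                "ls_means": anova.ls_means,
                "f_stat": anova.f_stat,
                "df": [anova.df_num, anova.df_den],
                "p_value": anova.p_value,
            },
            "treatment_logistic": {
                "p_value": logit.p_value, "lr_stat": logit.lr_stat,
                "df": logit.df, "separation": logit.separation,
            },
            "auc_log_cga": auc_cga,
        }
        (outdir / "group_stats.json").write_text(
            json.dumps(stats_payload, indent=2), encoding="utf-8")
    record("stats", outdir / "group_stats.json")
    log_lines.append(f"stats: anova_p={anova.p_value:.4g} logistic_p={logit.p_value:.4g}")

    manifest = {
        "stages": sorted({o.stage for o in outputs}),
        "outputs": [
            {"stage": o.stage, "file": o.path.name, "sha256": o.sha256}
            for o in outputs
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return manifest
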