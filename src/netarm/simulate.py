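"""Synthetic patient and control cohort generator.

Emulates the structure of a prospective neuroendocrine-tumor (NET) biomarker
study: a small-intestinal (siNET) or pancreatic (pNET) patient cohort with a
binary 3-year outcome (stable disease SD vs progressive disease PD), clinical
variables drawn per outcome group from configured category frequencies,
log-normal chromogranin A (CgA, in multiples of the upper limit of normal,
ULN) and 5-HIAA (% of ULN), 92 plasma proteins on an NPX-like scale, and a
separate outcome-free control cohort used downstream to derive biomarker
cut-offs from control-mean confidence intervals.

Ground-truth "planted rules" can be injected for recovery testing: a chosen
fraction of patients is made antecedent-positive (their raw values are pushed
past the relevant cut-offs), all remaining patients are made
antecedent-negative, and carriers' outcomes are resampled with a stated
penetrance, so the mined confidence of the planted rule is a binomial draw
around the penetrance.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .panel import PANEL_92, default_panel_params

Outcome = Literal["SD", "PD"]
OUTCOMES: tuple[Outcome, Outcome] = ("SD", "PD")
SYMPTOMS = ("diarrhea", "flushing", "bronchospasm")

_PROB_TOL = 1e-9


class GroupParams(BaseModel):
    """Mean/SD pair for one group's (log-)normal draw."""

    model_config = ConfigDict(frozen=True)
    mean: float
    sd: float = Field(gt=0.0)


def _check_dist(dist: dict[str, float], name: str) -> dict[str, float]:
    total = sum(dist.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} probabilities sum to {total!r}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probability")
    return dist


class OutcomeFrequencies(BaseModel):
    """Clinical category frequencies for one outcome group."""

    female: float = Field(ge=0.0, le=1.0)
    n_status: dict[str, float]
    m_status: dict[str, float]
    net_grade: dict[str, float]
    treatment: dict[str, float]
    liver_metastasis_given_m1: float = Field(ge=0.0, le=1.0)
    liver_metastasis_given_m0: float = Field(default=0.05, ge=0.0, le=1.0)
    symptom_rates: dict[str, float] = Field(
        default_factory=lambda: {"diarrhea": 0.45, "flushing": 0.35, "bronchospasm": 0.06}
    )
    mean_metastases_m1: float = Field(gt=0.0)
    age_mean: float = 66.0
    age_sd: float = Field(default=10.0, gt=0.0)

    @field_validator("n_status", "m_status", "net_grade", "treatment")
    @classmethod
    def _sum_to_one(cls, v: dict[str, float], info) -> dict[str, float]:
        return _check_dist(v, info.field_name)

    @field_validator("symptom_rates")
    @classmethod
    def _symptom_probs(cls, v: dict[str, float]) -> dict[str, float]:
        for s, p in v.items():
            if s not in SYMPTOMS:
                raise ValueError(f"unknown symptom {s!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"symptom rate {s}={p} outside [0,1]")
        return v


class PlantedRule(BaseModel):
    """Ground-truth association planted into a generated cohort.

    ``carrier_fraction`` of the cohort is made antecedent-positive; everyone
    else is made antecedent-negative (one antecedent item is relaxed,
    preferring a continuous item so categorical frequencies are disturbed as
    little as possible).  Carrier outcomes are Bernoulli(``penetrance``) for
    ``outcome`` vs the opposite label.
    """

    model_config = ConfigDict(frozen=True)
    antecedent_items: tuple[str, ...]
    outcome: Outcome
    penetrance: float = Field(ge=0.0, le=1.0)
    carrier_fraction: float = Field(gt=0.0, lt=1.0)

    @field_validator("antecedent_items")
    @classmethod
    def _nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("planted rule needs at least one antecedent item")
        return v


class CohortConfig(BaseModel):
    """Full parameterization of one synthetic patient + control cohort."""

    cohort: Literal["siNET", "pNET"] = "siNET"
    n_patients: int = Field(gt=0)
    pd_fraction: float = Field(ge=0.0, le=1.0)
    n_controls: int = Field(default=143, gt=0)
    # protein -> group ("control"/"SD"/"PD") -> GroupParams
    biomarker_params: dict[str, dict[str, GroupParams]]
    cga_log_params: dict[str, GroupParams]  # keys control, SD, PD (log scale)
    hiaa_log_params: dict[str, GroupParams]  # keys SD, PD (log %ULN scale)
    clinical_frequencies: dict[str, OutcomeFrequencies]  # keys SD, PD
    control_female_fraction: float = Field(default=0.41, ge=0.0, le=1.0)
    control_age: GroupParams = GroupParams(mean=64.0, sd=10.0)
    missing_grade_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    biomarker_equicorrelation: float = Field(default=0.0, ge=0.0, lt=1.0)
    planted_rules: list[PlantedRule] = Field(default_factory=list)
    seed: int = 0

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarker_params)

    @property
    def biomarker_names(self) -> tuple[str, ...]:
        return tuple(self.biomarker_params)

    @model_validator(mode="after")
    def _complete(self) -> "CohortConfig":
        for name, groups in self.biomarker_params.items():
            for g in ("control", "SD", "PD"):
                if g not in groups:
                    raise ValueError(f"biomarker {name!r} missing {g!r} parameters")
        for g in ("control", "SD", "PD"):
            if g not in self.cga_log_params:
                raise ValueError(f"cga_log_params missing group {g!r}")
        for g in OUTCOMES:
            if g not in self.hiaa_log_params:
                raise ValueError(f"hiaa_log_params missing group {g!r}")
            if g not in self.clinical_frequencies:
                raise ValueError(f"clinical_frequencies missing group {g!r}")
        for rule in self.planted_rules:
            for item in rule.antecedent_items:
                _parse_planted_item(item, self)  # raises on unknown variables
        return self


@dataclass
class PatientRecord:
    """One subject: clinical variables, biomarker values, 3-year outcome."""

    patient_id: str
    cohort: str
    gender: str  # "F" | "M"
    age: float
    net_grade: str  # "G1" | "G2" | "missing"
    ki67: float  # percent
    n_status: str  # "N0" | "N1" | "Nx"
    m_status: str  # "M0" | "M1"
    liver_metastasis: bool
    n_metastases: int
    cs_symptoms: frozenset[str]
    treatment: str
    cga_uln: float  # multiple of ULN, > 0
    hiaa_pct_uln: float  # percent of ULN
    biomarkers: dict[str, float]
    outcome: str  # "SD" | "PD"

    def __post_init__(self) -> None:
        if self.ki67 < 0:
            raise ValueError("ki67 must be >= 0")
        if self.cga_uln <= 0:
            raise ValueError("cga_uln must be > 0")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass
class ControlRecord:
    """One outcome-free control subject used for cut-off derivation."""

    control_id: str
    gender: str
    age: float
    biomarkers: dict[str, float]


# --------------------------------------------------------------------------
# default study-sized configurations

def _sinet_frequencies() -> dict[str, OutcomeFrequencies]:
    # Category counts for the siNET SD (n=50) and PD (n=65) groups; grade
    # missingness is folded out by default (complete-case analysis set).
    sd = OutcomeFrequencies(
        female=15 / 50,
        n_status={"N0": 10 / 50, "N1": 40 / 50, "Nx": 0.0},
        m_status={"M0": 16 / 50, "M1": 34 / 50},
        net_grade={"G1": 28 / 48, "G2": 20 / 48},
        treatment={"SSA": 21 / 50, "SSA+surgery": 18 / 50, "other": 11 / 50},
        liver_metastasis_given_m1=0.55,
        symptom_rates={"diarrhea": 0.40, "flushing": 0.30, "bronchospasm": 0.05},
        mean_metastases_m1=4.0,
    )
    pd_ = OutcomeFrequencies(
        female=32 / 65,
        n_status={"N0": 13 / 65, "N1": 51 / 65, "Nx": 1 / 65},
        m_status={"M0": 5 / 65, "M1": 60 / 65},
        net_grade={"G1": 18 / 61, "G2": 43 / 61},
        treatment={"SSA": 37 / 65, "SSA+surgery": 12 / 65, "other": 16 / 65},
        liver_metastasis_given_m1=0.80,
        symptom_rates={"diarrhea": 0.55, "flushing": 0.45, "bronchospasm": 0.08},
        mean_metastases_m1=9.0,
    )
    return {"SD": sd, "PD": pd_}


def _pnet_frequencies() -> dict[str, OutcomeFrequencies]:
    sd = OutcomeFrequencies(
        female=4 / 8,
        n_status={"N0": 5 / 8, "N1": 3 / 8, "Nx": 0.0},
        m_status={"M0": 2 / 8, "M1": 6 / 8},
        net_grade={"G1": 4 / 7, "G2": 3 / 7},
        treatment={"SSA": 4 / 7, "other": 3 / 7},
        liver_metastasis_given_m1=0.55,
        symptom_rates={"diarrhea": 0.2, "flushing": 0.15, "bronchospasm": 0.03},
        mean_metastases_m1=4.0,
    )
    pd_ = OutcomeFrequencies(
        female=11 / 22,
        n_status={"N0": 8 / 22, "N1": 14 / 22, "Nx": 0.0},
        m_status={"M0": 1 / 22, "M1": 21 / 22},
        net_grade={"G1": 5 / 18, "G2": 13 / 18},
        treatment={"SSA": 16 / 21, "other": 5 / 21},
        liver_metastasis_given_m1=0.80,
        symptom_rates={"diarrhea": 0.25, "flushing": 0.2, "bronchospasm": 0.04},
        mean_metastases_m1=8.0,
    )
    return {"SD": sd, "PD": pd_}


def _panel_as_group_params() -> dict[str, dict[str, GroupParams]]:
    return {
        name: {g: GroupParams(mean=m, sd=s) for g, (m, s) in groups.items()}
        for name, groups in default_panel_params().items()
    }


def sinet_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-sized siNET configuration: n=115 (65 PD / 50 SD), 143 controls.

    Log-CgA and CPE group parameters are the printed group summaries
    (control log-CgA 1.29 (0.48); PD 3.57 (1.37); SD 2.35 (1.01)).
    """
    base = dict(
        cohort="siNET",
        n_patients=115,
        pd_fraction=65 / 115,
        n_controls=143,
        biomarker_params=_panel_as_group_params(),
        cga_log_params={
            "control": GroupParams(mean=1.29, sd=0.48),
            "SD": GroupParams(mean=2.35, sd=1.01),
            "PD": GroupParams(mean=3.57, sd=1.37),
        },
        hiaa_log_params={
            "SD": GroupParams(mean=5.0, sd=1.0),
            "PD": GroupParams(mean=6.0, sd=1.0),
        },
        clinical_frequencies=_sinet_frequencies(),
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def pnet_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-sized pNET configuration: n=30 (22 PD / 8 SD)."""
    base = dict(
        cohort="pNET",
        n_patients=30,
        pd_fraction=22 / 30,
        n_controls=143,
        biomarker_params=_panel_as_group_params(),
        # CgA is less informative in pNET; group separation kept modest.
        cga_log_params={
            "control": GroupParams(mean=1.29, sd=0.48),
            "SD": GroupParams(mean=2.0, sd=1.0),
            "PD": GroupParams(mean=2.4, sd=1.1),
        },
        hiaa_log_params={
            "SD": GroupParams(mean=4.2, sd=1.0),
            "PD": GroupParams(mean=4.6, sd=1.0),
        },
        clinical_frequencies=_pnet_frequencies(),
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def null_config(seed: int = 0, n_patients: int = 115, **overrides) -> CohortConfig:
    """siNET-shaped configuration with all group effects removed.

    Both outcome groups share the SD-group parameters for every variable, so
    any biomarker is exchangeable between PD and SD patients.
    """
    cfg = sinet_config(seed=seed, n_patients=n_patients, **overrides)
    bp = {
        name: {
            "control": groups["control"],
            "SD": groups["SD"],
            "PD": groups["SD"],
        }
        for name, groups in cfg.biomarker_params.items()
    }
    freqs = {"SD": cfg.clinical_frequencies["SD"], "PD": cfg.clinical_frequencies["SD"]}
    return cfg.model_copy(
        update=dict(
            biomarker_params=bp,
            cga_log_params={
                "control": cfg.cga_log_params["control"],
                "SD": cfg.cga_log_params["SD"],
                "PD": cfg.cga_log_params["SD"],
            },
            hiaa_log_params={
                "SD": cfg.hiaa_log_params["SD"],
                "PD": cfg.hiaa_log_params["SD"],
            },
            clinical_frequencies=freqs,
        )
    )


# --------------------------------------------------------------------------
# planted-item parsing / enforcement

_CGA_RE = re.compile(r"^CgA > (\d+(?:\.\d+)?) ULN$")
_BIOMARKER_RE = re.compile(r"^(?P<var>.+?) (?P<dir>[<>]) (?P<val>-?\d+(?:\.\d+)?)$")


def _parse_planted_item(item: str, config: "CohortConfig") -> tuple[str, object]:
    """Classify a planted antecedent item; raise ValueError if unknown."""
    if item in ("female", "male"):
        return ("gender", item)
    m = _CGA_RE.match(item)
    if m:
        return ("cga", float(m.group(1)))
    if item == "Ki-67 > 5%":
        return ("ki67_high", 5.0)
    if item == "Ki-67 <= 5%":
        return ("ki67_low", 5.0)
    if item == "5-HIAA > 455 (%ULN)":
        return ("hiaa", 455.0)
    if item in ("NET grade 1", "NET grade 2"):
        return ("grade", item[-1])
    if item == "liver metastasis":
        return ("liver", True)
    if item == "> 10 metastases":
        return ("metastases", 10)
    if item in SYMPTOMS:
        return ("symptom", item)
    if item == "no CS symptoms":
        return ("no_symptoms", None)
    m = _BIOMARKER_RE.match(item)
    if m and m.group("var") in config.biomarker_params:
        return ("biomarker", (m.group("var"), m.group("dir")))
    raise ValueError(f"planted antecedent item {item!r} not recognized for this config")


# Relaxation preference: continuous items first, categorical flips last.
_RELAX_ORDER = (
    "cga", "hiaa", "biomarker", "ki67_high", "ki67_low",
    "metastases", "liver", "symptom", "no_symptoms", "grade", "gender",
)


class _CohortArrays:
    """Columnar view of a cohort under construction (mutated by planting)."""

    def __init__(self, n: int):
        self.gender = np.empty(n, dtype=object)
        self.age = np.empty(n)
        self.net_grade = np.empty(n, dtype=object)
        self.ki67 = np.empty(n)
        self.n_status = np.empty(n, dtype=object)
        self.m_status = np.empty(n, dtype=object)
        self.liver = np.zeros(n, dtype=bool)
        self.n_metastases = np.zeros(n, dtype=int)
        self.symptoms = [set() for _ in range(n)]
        self.treatment = np.empty(n, dtype=object)
        self.cga = np.empty(n)
        self.hiaa = np.empty(n)
        self.outcome = np.empty(n, dtype=object)
        self.biomarkers: dict[str, np.ndarray] = {}


def _enforce_item(arr: _CohortArrays, idx: np.ndarray, kind: str, payload,
                  config: CohortConfig, rng: np.random.Generator) -> None:
    """Force patients at ``idx`` to carry the item."""
    k = len(idx)
    if kind == "gender":
        arr.gender[idx] = "F" if payload == "female" else "M"
    elif kind == "cga":
        thr = payload
        arr.cga[idx] = np.maximum(arr.cga[idx], thr * rng.uniform(1.2, 3.0, size=k))
    elif kind == "ki67_high":
        arr.ki67[idx] = np.maximum(arr.ki67[idx], rng.uniform(5.5, 19.0, size=k))
        arr.net_grade[idx] = "G2"
    elif kind == "ki67_low":
        arr.ki67[idx] = np.minimum(arr.ki67[idx], rng.uniform(0.5, 4.5, size=k))
    elif kind == "hiaa":
        arr.hiaa[idx] = np.maximum(arr.hiaa[idx], 455.0 * rng.uniform(1.1, 2.5, size=k))
    elif kind == "grade":
        arr.net_grade[idx] = f"G{payload}"
        if payload == "1":
            arr.ki67[idx] = np.minimum(arr.ki67[idx], rng.uniform(0.5, 2.9, size=k))
        else:
            arr.ki67[idx] = np.maximum(arr.ki67[idx], rng.uniform(3.1, 19.0, size=k))
    elif kind == "liver":
        arr.liver[idx] = True
        arr.m_status[idx] = "M1"
    elif kind == "metastases":
        arr.n_metastases[idx] = np.maximum(arr.n_metastases[idx],
                                           rng.integers(11, 25, size=k))
        arr.m_status[idx] = "M1"
    elif kind == "symptom":
        for i in idx:
            arr.symptoms[i].add(payload)
    elif kind == "no_symptoms":
        for i in idx:
            arr.symptoms[i].clear()
    elif kind == "biomarker":
        var, direction = payload
        mu, sigma = (config.biomarker_params[var]["control"].mean,
                     config.biomarker_params[var]["control"].sd)
        shift = (1.5 + rng.uniform(0.0, 1.5, size=k)) * sigma
        arr.biomarkers[var][idx] = mu + shift if direction == ">" else mu - shift
    else:  # pragma: no cover
        raise AssertionError(kind)


def _relax_item(arr: _CohortArrays, idx: np.ndarray, kind: str, payload,
                config: CohortConfig, rng: np.random.Generator) -> None:
    """Force patients at ``idx`` to NOT carry the item."""
    k = len(idx)
    if kind == "gender":
        arr.gender[idx] = "M" if payload == "female" else "F"
    elif kind == "cga":
        thr = payload
        arr.cga[idx] = np.minimum(arr.cga[idx], thr * rng.uniform(0.3, 0.95, size=k))
    elif kind == "ki67_high":
        arr.ki67[idx] = np.minimum(arr.ki67[idx], rng.uniform(0.5, 4.9, size=k))
    elif kind == "ki67_low":
        arr.ki67[idx] = np.maximum(arr.ki67[idx], rng.uniform(5.1, 19.0, size=k))
    elif kind == "hiaa":
        arr.hiaa[idx] = np.minimum(arr.hiaa[idx], 455.0 * rng.uniform(0.3, 0.95, size=k))
    elif kind == "grade":
        other = "G2" if payload == "1" else "G1"
        arr.net_grade[idx] = other
    elif kind == "liver":
        arr.liver[idx] = False
    elif kind == "metastases":
        arr.n_metastases[idx] = np.minimum(arr.n_metastases[idx], 10)
    elif kind == "symptom":
        for i in idx:
            arr.symptoms[i].discard(payload)
    elif kind == "no_symptoms":
        for i in idx:
            arr.symptoms[i].add("diarrhea")
    elif kind == "biomarker":
        var, _ = payload
        mu = config.biomarker_params[var]["control"].mean
        arr.biomarkers[var][idx] = mu  # dead-center of the control CI: no item
    else:  # pragma: no cover
        raise AssertionError(kind)


def _apply_planted_rules(arr: _CohortArrays, config: CohortConfig,
                         rng: np.random.Generator) -> None:
    n = len(arr.cga)
    for rule in config.planted_rules:
        parsed = [_parse_planted_item(it, config) for it in rule.antecedent_items]
        n_carriers = int(round(rule.carrier_fraction * n))
        if n_carriers < 1 or n_carriers >= n:
            raise ValueError(
                f"carrier_fraction {rule.carrier_fraction} yields {n_carriers} "
                f"carriers in a cohort of {n}")
        perm = rng.permutation(n)
        carriers, rest = perm[:n_carriers], perm[n_carriers:]
        for kind, payload in parsed:
            _enforce_item(arr, carriers, kind, payload, config, rng)
        # make everyone else antecedent-negative by relaxing one item,
        # preferring a continuous one
        relax_kind, relax_payload = min(
            parsed, key=lambda kp: _RELAX_ORDER.index(kp[0]))
        _relax_item(arr, rest, relax_kind, relax_payload, config, rng)
        hit = rng.random(n_carriers) < rule.penetrance
        other = "SD" if rule.outcome == "PD" else "PD"
        arr.outcome[carriers[hit]] = rule.outcome
        arr.outcome[carriers[~hit]] = other


# --------------------------------------------------------------------------
# generation

def _rng_for(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_categorical(rng: np.random.Generator, dist: dict[str, float],
                      size: int) -> np.ndarray:
    cats = sorted(dist)
    p = np.array([dist[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(cats, dtype=object), size=size, p=p)


def generate_controls(config: CohortConfig) -> list[ControlRecord]:
    """Draw the outcome-free control cohort (biomarkers from the configured
    control distributions; reproducible under ``config.seed``)."""
    rng = _rng_for(config, 1)
    n = config.n_controls
    gender = np.where(rng.random(n) < config.control_female_fraction, "F", "M")
    age = rng.normal(config.control_age.mean, config.control_age.sd, size=n)
    values = {
        name: rng.normal(groups["control"].mean, groups["control"].sd, size=n)
        for name, groups in config.biomarker_params.items()
    }
    names = config.biomarker_names
    cols = np.column_stack([values[v] for v in names])
    return [
        ControlRecord(
            control_id=f"C{i + 1:04d}",
            gender=str(gender[i]),
            age=float(age[i]),
            biomarkers=dict(zip(names, cols[i].tolist())),
        )
        for i in range(n)
    ]


def generate_patients(config: CohortConfig) -> list[PatientRecord]:
    """Draw the patient cohort.

    The realized PD count equals ``round(n_patients * pd_fraction)`` before
    planted-rule overrides; clinical categories, log-CgA, log-5-HIAA and all
    proteins are drawn per outcome group; planted rules are applied last.
    """
    rng = _rng_for(config, 2)
    n = config.n_patients
    n_pd = int(round(n * config.pd_fraction))
    outcome = np.array(["PD"] * n_pd + ["SD"] * (n - n_pd), dtype=object)
    rng.shuffle(outcome)

    arr = _CohortArrays(n)
    arr.outcome = outcome
    for grp in OUTCOMES:
        mask = outcome == grp
        k = int(mask.sum())
        if k == 0:
            continue
        freq = config.clinical_frequencies[grp]
        arr.gender[mask] = np.where(rng.random(k) < freq.female, "F", "M")
        arr.age[mask] = np.clip(rng.normal(freq.age_mean, freq.age_sd, size=k), 30, 95)
        grade_dist = dict(freq.net_grade)
        if config.missing_grade_rate > 0:
            grade_dist = {c: p * (1 - config.missing_grade_rate)
                          for c, p in grade_dist.items()}
            grade_dist["missing"] = config.missing_grade_rate
        arr.net_grade[mask] = _draw_categorical(rng, grade_dist, k)
        arr.n_status[mask] = _draw_categorical(rng, freq.n_status, k)
        arr.m_status[mask] = _draw_categorical(rng, freq.m_status, k)
        arr.treatment[mask] = _draw_categorical(rng, freq.treatment, k)
        m1 = mask & (arr.m_status == "M1")
        m0 = mask & (arr.m_status == "M0")
        arr.liver[m1] = rng.random(int(m1.sum())) < freq.liver_metastasis_given_m1
        arr.liver[m0] = rng.random(int(m0.sum())) < freq.liver_metastasis_given_m0
        arr.n_metastases[m1] = 1 + rng.poisson(freq.mean_metastases_m1 - 1,
                                               size=int(m1.sum()))
        for s in SYMPTOMS:
            has = rng.random(k) < freq.symptom_rates.get(s, 0.0)
            for i, flag in zip(np.nonzero(mask)[0], has):
                if flag:
                    arr.symptoms[i].add(s)
        arr.cga[mask] = np.exp(rng.normal(config.cga_log_params[grp].mean,
                                          config.cga_log_params[grp].sd, size=k))
        arr.hiaa[mask] = np.exp(rng.normal(config.hiaa_log_params[grp].mean,
                                           config.hiaa_log_params[grp].sd, size=k))
    # Ki-67 conditional on grade (G1 < 3%, G2 in 3-20%)
    g1 = arr.net_grade == "G1"
    g2 = arr.net_grade == "G2"
    gmiss = ~(g1 | g2)
    arr.ki67[g1] = rng.uniform(0.3, 2.9, size=int(g1.sum()))
    arr.ki67[g2] = rng.uniform(3.1, 19.9, size=int(g2.sum()))
    arr.ki67[gmiss] = rng.uniform(0.5, 19.9, size=int(gmiss.sum()))

    # proteins, optionally with a shared equicorrelated factor
    rho = config.biomarker_equicorrelation
    shared = rng.normal(size=n) if rho > 0 else None
    for name, groups in config.biomarker_params.items():
        vals = np.empty(n)
        for grp in OUTCOMES:
            mask = outcome == grp
            k = int(mask.sum())
            gp = groups[grp]
            if rho > 0:
                z = math.sqrt(rho) * shared[mask] + math.sqrt(1 - rho) * rng.normal(size=k)
                vals[mask] = gp.mean + gp.sd * z
            else:
                vals[mask] = rng.normal(gp.mean, gp.sd, size=k)
        arr.biomarkers[name] = vals

    _apply_planted_rules(arr, config, rng)

    names = config.biomarker_names
    cols = np.column_stack([arr.biomarkers[v] for v in names])
    prefix = "S" if config.cohort == "siNET" else "P"
    return [
        PatientRecord(
            patient_id=f"{prefix}{i + 1:04d}",
            cohort=config.cohort,
            gender=str(arr.gender[i]),
            age=float(arr.age[i]),
            net_grade=str(arr.net_grade[i]),
            ki67=float(arr.ki67[i]),
            n_status=str(arr.n_status[i]),
            m_status=str(arr.m_status[i]),
            liver_metastasis=bool(arr.liver[i]),
            n_metastases=int(arr.n_metastases[i]),
            cs_symptoms=frozenset(arr.symptoms[i]),
            treatment=str(arr.treatment[i]),
            cga_uln=float(arr.cga[i]),
            hiaa_pct_uln=float(arr.hiaa[i]),
            biomarkers=dict(zip(names, cols[i].tolist())),
            outcome=str(arr.outcome[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# tabular IO (CSV round-trip, '.' decimal separator, UTF-8)

_CLINICAL_COLS = [
    "patient_id", "cohort", "gender", "age", "net_grade", "ki67", "n_status",
    "m_status", "liver_metastasis", "n_metastases", "cs_symptoms", "treatment",
    "cga_uln", "hiaa_pct_uln", "outcome",
]


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _CLINICAL_COLS if c != "cs_symptoms"}
        row["cs_symptoms"] = "|".join(sorted(r.cs_symptoms))
        row.update(r.biomarkers)
        rows.append(row)
    names = list(records[0].biomarkers) if records else []
    return pd.DataFrame(rows, columns=_CLINICAL_COLS + names)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    marker_cols = [c for c in df.columns if c not in _CLINICAL_COLS]
    records = []
    for _, row in df.iterrows():
        sym = row["cs_symptoms"]
        symptoms = frozenset() if (pd.isna(sym) or sym == "") else frozenset(str(sym).split("|"))
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            cohort=str(row["cohort"]),
            gender=str(row["gender"]),
            age=float(row["age"]),
            net_grade=str(row["net_grade"]),
            ki67=float(row["ki67"]),
            n_status=str(row["n_status"]),
            m_status=str(row["m_status"]),
            liver_metastasis=bool(row["liver_metastasis"]),
            n_metastases=int(row["n_metastases"]),
            cs_symptoms=symptoms,
            treatment=str(row["treatment"]),
            cga_uln=float(row["cga_uln"]),
            hiaa_pct_uln=float(row["hiaa_pct_uln"]),
            biomarkers={c: float(row[c]) for c in marker_cols},
            outcome=str(row["outcome"]),
        ))
    return records


def controls_to_frame(records: list[ControlRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"control_id": r.control_id, "gender": r.gender, "age": r.age}
        row.update(r.biomarkers)
        rows.append(row)
    names = list(records[0].biomarkers) if records else []
    return pd.DataFrame(rows, columns=["control_id", "gender", "age"] + names)


def frame_to_controls(df: pd.DataFrame) -> list[ControlRecord]:
    marker_cols = [c for c in df.columns if c not in ("control_id", "gender", "age")]
    return [
        ControlRecord(
            control_id=str(row["control_id"]),
            gender=str(row["gender"]),
            age=float(row["age"]),
            biomarkers={c: float(row[c]) for c in marker_cols},
        )
        for _, row in df.iterrows()
    ]


def write_cohort(records: list[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path, encoding="utf-8"))


def write_controls(records: list[ControlRecord], path: str | Path) -> None:
    controls_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_controls(path: str | Path) -> list[ControlRecord]:
    return frame_to_controls(pd.read_csv(path, encoding="utf-8"))


def write_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2), encoding="utf-8")


def read_config(path: str | Path) -> CohortConfig:
    return CohortConfig.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))
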