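"""Variable categorization: cut-off derivation and transaction encoding.

Continuous biomarkers are discretized against the 95% confidence interval of
the control-cohort mean: a patient value below the lower bound yields a
"VAR < low" item, above the upper bound a "VAR > high" item, and a value
inside the interval yields no item (absence coding).  Comparisons always use
the unrounded bounds; item labels carry the bounds rounded to a configurable
number of decimals.

Clinical variables are encoded with fixed thresholds (CgA as a multiple of
ULN, default >4; 5-HIAA above 455 % of ULN; Ki-67 above/below 5%; more than
10 metastases) or pass through as one item per observed category (gender,
NET grade, nodal/distant status, liver metastasis, carcinoid-syndrome
symptoms, with "no CS symptoms" for an empty symptom set).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .simulate import ControlRecord, PatientRecord

Source = Literal["control_ci", "uln_multiple", "fixed_threshold", "categorical_passthrough"]

OUTCOME_ITEMS = ("SD", "PD")


@dataclass(frozen=True)
class CutoffSpec:
    """Discretization bounds for one variable, with provenance."""

    variable: str
    low: Optional[float]
    high: Optional[float]
    source: Source
    label_precision: int = 2
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"{self.variable}: low {self.low} > high {self.high}")
        if self.source == "control_ci" and (self.low is None or self.high is None):
            raise ValueError(f"{self.variable}: control_ci spec requires both bounds")

    @property
    def low_label(self) -> str:
        return f"{self.variable} < {self.low:.{self.label_precision}f}"

    @property
    def high_label(self) -> str:
        return f"{self.variable} > {self.high:.{self.label_precision}f}"


@dataclass
class CutoffTable:
    """Per-variable cut-off specs plus control-cohort provenance."""

    specs: dict[str, CutoffSpec]
    provenance: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    ci_level: float = 0.95
    cga_multiples: tuple[float, ...] = (4.0,)
    hiaa_threshold: float = 455.0
    ki67_threshold: float = 5.0
    metastasis_threshold: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    def biomarker_specs(self) -> dict[str, CutoffSpec]:
        return {v: s for v, s in self.specs.items() if s.source == "control_ci"}


def ci_bounds(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """z-based confidence interval of the mean: mean ± z·sd/√n."""
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half


def derive_control_ci_cutoffs(
    controls: Sequence[ControlRecord],
    ci_level: float = 0.95,
    label_precision: int = 2,
    **table_options,
) -> CutoffTable:
    """Derive biomarker cut-offs from the control cohort's mean CIs.

    For each biomarker: low/high = control mean ∓ z·SD/√n (sample SD, n−1
    denominator).  Zero-variance markers get low == high and are flagged.
    Fixed clinical thresholds (CgA ULN multiples, 5-HIAA, Ki-67, metastasis
    count) are attached as additional specs.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 controls")
    names = list(controls[0].biomarkers)
    for c in controls:
        missing = set(names) - set(c.biomarkers)
        if missing:
            raise ValueError(f"control {c.control_id} missing biomarkers {sorted(missing)}")
    mat = np.array([[c.biomarkers[v] for v in names] for c in controls], dtype=float)
    n = mat.shape[0]
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    specs: dict[str, CutoffSpec] = {}
    provenance: dict[str, tuple[float, float, int]] = {}
    for j, v in enumerate(names):
        provenance[v] = (float(means[j]), float(sds[j]), n)
        if sds[j] == 0.0:
            specs[v] = CutoffSpec(v, float(means[j]), float(means[j]),
                                  "control_ci", label_precision, zero_variance=True)
        else:
            low, high = ci_bounds(float(means[j]), float(sds[j]), n, ci_level)
            specs[v] = CutoffSpec(v, low, high, "control_ci", label_precision)
    table = CutoffTable(specs=specs, provenance=provenance, ci_level=ci_level,
                        **table_options)
    _attach_fixed_specs(table)
    return table


def _attach_fixed_specs(table: CutoffTable) -> None:
    for k in table.cga_multiples:
        table.specs[f"CgA@{k:g}"] = CutoffSpec("CgA", None, float(k), "uln_multiple")
    table.specs["5-HIAA"] = CutoffSpec("5-HIAA", None, table.hiaa_threshold,
                                       "fixed_threshold")
    table.specs["Ki-67"] = CutoffSpec("Ki-67", None, table.ki67_threshold,
                                      "fixed_threshold")
    table.specs["n_metastases"] = CutoffSpec("n_metastases", None,
                                             float(table.metastasis_threshold),
                                             "fixed_threshold")


@dataclass(frozen=True)
class Transaction:
    """One patient as a set of categorical items (outcome item included)."""

    patient_id: str
    items: frozenset[str]
    outcome_item: str

    def __post_init__(self) -> None:
        if self.outcome_item not in OUTCOME_ITEMS:
            raise ValueError(f"outcome_item must be in {OUTCOME_ITEMS}")


@dataclass
class TransactionDB:
    """Ordered collection of transactions with the induced item universe."""

    transactions: list[Transaction]

    @property
    def N(self) -> int:
        return len(self.transactions)

    @property
    def item_catalog(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t.items
        return frozenset(out)

    def project(self, items: Iterable[str]) -> "TransactionDB":
        """Restrict every transaction to a subset of the item universe."""
        keep = frozenset(items)
        return TransactionDB([
            Transaction(t.patient_id, t.items & keep, t.outcome_item)
            for t in self.transactions
        ])


class MissingValueError(ValueError):
    pass


def _require(value, variable: str, patient_id: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingValueError(
            f"patient {patient_id}: missing value for {variable!r} "
            "(complete-case contract)")
    return value


def categorize_patient(record: PatientRecord, cutoffs: CutoffTable,
                       include_treatment: bool = False) -> Transaction:
    """Encode one patient as a transaction of categorical items."""
    pid = record.patient_id
    items: set[str] = set()

    for v, spec in cutoffs.biomarker_specs().items():
        value = _require(record.biomarkers.get(v), v, pid)
        if value < spec.low:
            items.add(spec.low_label)
        elif value > spec.high:
            items.add(spec.high_label)
        # inside [low, high]: no item (absence coding, strict inequalities)

    cga = _require(record.cga_uln, "cga_uln", pid)
    for k in cutoffs.cga_multiples:
        if cga > k:
            items.add(f"CgA > {k:g} ULN")
    hiaa = _require(record.hiaa_pct_uln, "hiaa_pct_uln", pid)
    if hiaa > cutoffs.hiaa_threshold:
        items.add(f"5-HIAA > {cutoffs.hiaa_threshold:g} (%ULN)")
    ki67 = _require(record.ki67, "ki67", pid)
    if ki67 > cutoffs.ki67_threshold:
        items.add(f"Ki-67 > {cutoffs.ki67_threshold:g}%")
    else:
        items.add(f"Ki-67 <= {cutoffs.ki67_threshold:g}%")

    gender = _require(record.gender, "gender", pid)
    items.add("female" if gender == "F" else "male")
    grade = _require(record.net_grade, "net_grade", pid)
    if grade in ("G1", "G2"):
        items.add(f"NET grade {grade[-1]}")
    items.add(_require(record.n_status, "n_status", pid))
    items.add(_require(record.m_status, "m_status", pid))
    if record.liver_metastasis:
        items.add("liver metastasis")
    else:
        items.add("no liver metastasis")
    if record.n_metastases > cutoffs.metastasis_threshold:
        items.add(f"> {cutoffs.metastasis_threshold} metastases")
    if record.cs_symptoms:
        items |= set(record.cs_symptoms)
    else:
        items.add("no CS symptoms")
    if include_treatment:
        items.add(f"treatment: {record.treatment}")

    outcome_item = _require(record.outcome, "outcome", pid)
    items.add(outcome_item)
    return Transaction(pid, frozenset(items), outcome_item)


def encode_cohort(records: Sequence[PatientRecord], cutoffs: CutoffTable,
                  items: Optional[Iterable[str]] = None,
                  include_treatment: bool = False) -> TransactionDB:
    """Encode a cohort in order; optionally restrict to an item whitelist
    (the outcome items are always kept)."""
    keep = None if items is None else frozenset(items) | set(OUTCOME_ITEMS)
    out: list[Transaction] = []
    for r in records:
        try:
            t = categorize_patient(r, cutoffs, include_treatment=include_treatment)
        except MissingValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context
            raise ValueError(f"while encoding patient {r.patient_id}: {exc}") from exc
        if keep is not None:
            t = Transaction(t.patient_id, t.items & keep, t.outcome_item)
        out.append(t)
    return TransactionDB(out)


# --------------------------------------------------------------------------
# item-label parsing (round-trip: label -> variable + direction)

_THRESH_RE = re.compile(
    r"^(?P<var>.+?) (?P<dir><|>|<=) (?P<val>-?\d+(?:\.\d+)?)(?P<suffix>%| ULN| \(%ULN\))?$"
)


def parse_item(label: str) -> tuple[str, str]:
    """Return (variable, direction) for an item label.

    Direction is "<" / ">" for threshold items, "=" for categorical
    pass-through items (including the outcome items).
    """
    if label.startswith("> ") and label.endswith(" metastases"):
        return "n_metastases", ">"
    m = _THRESH_RE.match(label)
    if m:
        d = m.group("dir")
        return m.group("var"), ("<" if d == "<=" else d)
    return label, "="


# --------------------------------------------------------------------------
# serialization

def cutoffs_to_json(table: CutoffTable, path: str | Path) -> None:
    payload = {
        "ci_level": table.ci_level,
        "cga_multiples": list(table.cga_multiples),
        "hiaa_threshold": table.hiaa_threshold,
        "ki67_threshold": table.ki67_threshold,
        "metastasis_threshold": table.metastasis_threshold,
        "provenance": {v: list(p) for v, p in table.provenance.items()},
        "specs": [
            {
                "variable": s.variable,
                "low": s.low,
                "high": s.high,
                "source": s.source,
                "label_precision": s.label_precision,
                "zero_variance": s.zero_variance,
                "key": key,
            }
            for key, s in table.specs.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def cutoffs_from_json(path: str | Path) -> CutoffTable:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    specs = {
        entry["key"]: CutoffSpec(
            entry["variable"], entry["low"], entry["high"], entry["source"],
            entry["label_precision"], entry["zero_variance"],
        )
        for entry in payload["specs"]
    }
    return CutoffTable(
        specs=specs,
        provenance={v: (p[0], p[1], int(p[2])) for v, p in payload["provenance"].items()},
        ci_level=payload["ci_level"],
        cga_multiples=tuple(payload["cga_multiples"]),
        hiaa_threshold=payload["hiaa_threshold"],
        ki67_threshold=payload["ki67_threshold"],
        metastasis_threshold=int(payload["metastasis_threshold"]),
    )


def write_basket(db: TransactionDB, path: str | Path) -> None:
    """Basket format: one line per patient, first field the patient id,
    then the item labels, comma-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in db.transactions:
            fields = [t.patient_id] + sorted(t.items)
            fh.write(",".join(fields) + "\n")


def read_basket(path: str | Path) -> TransactionDB:
    transactions: list[Transaction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: no items")
            pid, items = fields[0], frozenset(fields[1:])
            outcome = items & set(OUTCOME_ITEMS)
            if len(outcome) != 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected exactly one outcome item, "
                    f"got {sorted(outcome)}")
            transactions.append(Transaction(pid, items, next(iter(outcome))))
    return TransactionDB(transactions)
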