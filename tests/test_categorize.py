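"""Cut-off derivation and transaction encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netarm import (ci_bounds, derive_control_ci_cutoffs, categorize_patient,
                    encode_cohort, parse_item, generate_controls,
                    generate_patients)
from netarm.categorize import (MissingValueError, cutoffs_from_json,
                               cutoffs_to_json, read_basket, write_basket)
from netarm.simulate import ControlRecord

from conftest import tiny_config


def _controls_from_matrix(values: dict[str, list[float]]):
    n = len(next(iter(values.values())))
    return [
        ControlRecord(f"C{i}", "F", 60.0,
                      {v: values[v][i] for v in values})
        for i in range(n)
    ]


class TestCiBounds:
    def test_closed_form_standard_normal(self):
        low, high = ci_bounds(0.0, 1.0, 100, 0.95)
        assert low == pytest.approx(-0.1959964, abs=1e-6)
        assert high == pytest.approx(0.1959964, abs=1e-6)

    def test_printed_cpe_lower_bound(self):
        low, high = ci_bounds(3.09, 0.34, 143, 0.95)
        assert round(low, 3) == 3.034
        assert f"{low:.2f}" == "3.03"

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            ci_bounds(0.0, 1.0, 1)


class TestDeriveCutoffs:
    def test_zero_variance_collapses_and_flags(self):
        controls = _controls_from_matrix({"X": [5.0] * 10})
        table = derive_control_ci_cutoffs(controls)
        spec = table.specs["X"]
        assert spec.low == spec.high == 5.0
        assert spec.zero_variance

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(3.0, 0.4, size=50).tolist()
        c = 1.7
        t0 = derive_control_ci_cutoffs(_controls_from_matrix({"X": base}))
        t1 = derive_control_ci_cutoffs(
            _controls_from_matrix({"X": [v + c for v in base]}))
        assert t1.specs["X"].low == pytest.approx(t0.specs["X"].low + c, abs=1e-12)
        assert t1.specs["X"].high == pytest.approx(t0.specs["X"].high + c, abs=1e-12)

    def test_missing_biomarker_column_rejected(self):
        controls = _controls_from_matrix({"X": [1.0, 2.0]})
        controls[1].biomarkers.pop("X")
        with pytest.raises(ValueError, match="missing biomarkers"):
            derive_control_ci_cutoffs(controls)


class TestCategorizePatient:
    @pytest.fixture
    def setup(self):
        cfg = tiny_config(seed=2)
        controls = generate_controls(cfg)
        patients = generate_patients(cfg)
        cutoffs = derive_control_ci_cutoffs(controls)
        return cfg, patients, cutoffs

    def test_item_vocabulary_for_known_values(self, setup):
        _, patients, cutoffs = setup
        p = patients[0]
        p.gender = "F"
        p.cga_uln = 5.0
        p.ki67 = 7.0
        p.biomarkers["CPE"] = 3.32  # above the control CI of ~[3.03, 3.15]
        t = categorize_patient(p, cutoffs)
        assert {"CgA > 4 ULN", "Ki-67 > 5%", "female"} <= t.items
        assert cutoffs.specs["CPE"].high_label in t.items

    def test_boundary_value_emits_no_biomarker_item(self, setup):
        _, patients, cutoffs = setup
        p = patients[0]
        p.biomarkers["CPE"] = cutoffs.specs["CPE"].low  # exactly on the bound
        t = categorize_patient(p, cutoffs)
        assert not any(i.startswith("CPE ") for i in t.items)

    def test_at_most_one_item_per_continuous_variable(self, setup):
        _, patients, cutoffs = setup
        db = encode_cohort(patients, cutoffs)
        markers = list(cutoffs.biomarker_specs())
        for t in db.transactions:
            for v in markers:
                hits = [i for i in t.items if i.startswith(f"{v} ")]
                assert len(hits) <= 1

    def test_no_symptoms_item_and_per_symptom_items(self, setup):
        _, patients, cutoffs = setup
        p = patients[0]
        object.__setattr__(p, "cs_symptoms", frozenset())
        assert "no CS symptoms" in categorize_patient(p, cutoffs).items
        object.__setattr__(p, "cs_symptoms", frozenset({"diarrhea", "flushing"}))
        items = categorize_patient(p, cutoffs).items
        assert {"diarrhea", "flushing"} <= items
        assert "no CS symptoms" not in items

    def test_missing_value_error_names_variable(self, setup):
        _, patients, cutoffs = setup
        p = patients[4]
        p.biomarkers["WISP-1"] = float("nan")
        with pytest.raises(MissingValueError, match="WISP-1"):
            categorize_patient(p, cutoffs)


class TestEncodeCohort:
    def test_empty_cohort(self, tiny_cfg):
        cutoffs = derive_control_ci_cutoffs(generate_controls(tiny_cfg))
        db = encode_cohort([], cutoffs)
        assert db.N == 0
        assert db.item_catalog == frozenset()

    def test_order_count_and_outcome_items(self, tiny_cfg):
        patients = generate_patients(tiny_cfg)
        cutoffs = derive_control_ci_cutoffs(generate_controls(tiny_cfg))
        db = encode_cohort(patients, cutoffs)
        assert db.N == len(patients)
        assert [t.patient_id for t in db.transactions] == [p.patient_id for p in patients]
        assert all(t.outcome_item in ("SD", "PD") for t in db.transactions)
        assert all(t.outcome_item in t.items for t in db.transactions)

    def test_item_whitelist(self, tiny_cfg):
        patients = generate_patients(tiny_cfg)
        cutoffs = derive_control_ci_cutoffs(generate_controls(tiny_cfg))
        db = encode_cohort(patients, cutoffs, items=["female", "CgA > 4 ULN"])
        assert db.item_catalog <= {"female", "CgA > 4 ULN", "PD", "SD"}


@pytest.mark.parametrize("label,expected", [
    ("CPE < 3.03", ("CPE", "<")),
    ("CPE > 3.14", ("CPE", ">")),
    ("CgA > 4 ULN", ("CgA", ">")),
    ("5-HIAA > 455 (%ULN)", ("5-HIAA", ">")),
    ("Ki-67 > 5%", ("Ki-67", ">")),
    ("Ki-67 <= 5%", ("Ki-67", "<")),
    ("> 10 metastases", ("n_metastases", ">")),
    ("5'-NT > 9.56", ("5'-NT", ">")),
    ("NET grade 2", ("NET grade 2", "=")),
    ("liver metastasis", ("liver metastasis", "=")),
    ("female", ("female", "=")),
    ("PD", ("PD", "=")),
])
def test_item_label_round_trip(label, expected):
    assert parse_item(label) == expected


@given(shift=st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_ci_translation_property(shift):
    low0, high0 = ci_bounds(2.0, 0.7, 30)
    low1, high1 = ci_bounds(2.0 + shift, 0.7, 30)
    assert math.isclose(low1, low0 + shift, abs_tol=1e-9)
    assert math.isclose(high1, high0 + shift, abs_tol=1e-9)


def test_serialization_round_trips(tmp_path, tiny_cfg):
    patients = generate_patients(tiny_cfg)
    cutoffs = derive_control_ci_cutoffs(generate_controls(tiny_cfg))
    cutoffs_to_json(cutoffs, tmp_path / "cutoffs.json")
    back = cutoffs_from_json(tmp_path / "cutoffs.json")
    assert back.specs["CPE"].low == pytest.approx(cutoffs.specs["CPE"].low)
    assert back.cga_multiples == cutoffs.cga_multiples

    db = encode_cohort(patients, cutoffs)
    write_basket(db, tmp_path / "tx.basket")
    db2 = read_basket(tmp_path / "tx.basket")
    assert db2.N == db.N
    assert [t.items for t in db2.transactions] == [t.items for t in db.transactions]


def test_corrupt_basket_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.basket"
    path.write_text("P1,female,PD\nP2,female\n", encoding="utf-8")
    with pytest.raises(ValueError, match="line 2"):
        read_basket(path)
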