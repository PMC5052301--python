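"""Achievement engine: windows, denominators, exclusions, oracle recounts.

The oracle used here recomputes every cell with explicit per-patient
loops and pandas calendar arithmetic, independently of the engine's own
window logic.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from qibench.engine import (
    AchievementTable,
    Cell,
    MissingReason,
    Observation,
    PatientRecord,
    PracticeExtract,
    Prescription,
    PREVALENCE_ONLY,
    adjust_prevalence,
    apply_exclusions,
    build_achievement_table,
    compute_achievement,
    compute_prevalence,
    eligible_patients,
    months_before,
)
from qibench.registry import Disease, IndicatorKind

from conftest import REF, make_extract, make_patient


# --------------------------------------------------------------------------
# independent oracle
# --------------------------------------------------------------------------

def _in_window(date, ref, months):
    if date > ref:
        return False
    if months is None:
        return True
    start = (pd.Timestamp(ref) - pd.DateOffset(months=months)).date()
    return date > start


def _oracle_eligible(extract, disease):
    out = []
    for p in extract.patients:
        visited = any(
            _in_window(d, extract.reference_date, 15) for d in p.encounter_dates
        )
        diagnosed = any(
            dis == disease and rec <= extract.reference_date
            for dis, rec in p.diagnoses
        )
        if visited and diagnosed:
            out.append(p)
    return out


def _oracle_cell(extract, definition):
    """Loop-based recount of one achievement cell (valued cells only)."""
    ref = extract.reference_date
    if definition.kind is IndicatorKind.PREVALENCE:
        visitors = [
            p for p in extract.patients
            if any(_in_window(d, ref, 15) for d in p.encounter_dates)
        ]
        num = len(_oracle_eligible(extract, definition.disease))
        return num, len(visitors)

    def hba1c_vals(p):
        return [
            float(o.value) for o in p.observations
            if o.obs_type == "hba1c" and _in_window(o.date, ref, 9)
        ]

    denom = _oracle_eligible(extract, definition.disease)
    rule = definition.denominator_rule.value
    if rule == "diagnosed_measured":
        denom = [p for p in denom if hba1c_vals(p)]
    elif rule == "diagnosed_measured_above_target":
        denom = [p for p in denom if any(v >= 7.5 for v in hba1c_vals(p))]

    obs_map = {
        "bmi_recorded": "bmi", "bp_recorded": "blood_pressure",
        "smoking_recorded": "smoking_status", "creatinine_done": "creatinine",
        "hba1c_done": "hba1c", "spirometry_recorded": "spirometry",
    }
    rx_map = {
        "metformin_if_high": "metformin", "statin_rx": "statin",
        "beta_blocker_rx": "beta_blocker", "ace_arb_rx": "ace_arb",
        "antithrombotic_rx": "antithrombotic",
    }
    num = 0
    for p in denom:
        crit = definition.criterion
        if crit == "hba1c_below_target":
            ok = any(v < 7.5 for v in hba1c_vals(p))
        elif crit in obs_map:
            ok = any(
                o.obs_type == obs_map[crit]
                and _in_window(o.date, ref, definition.lookback_months)
                for o in p.observations
            )
        else:
            ok = any(
                rx.drug_class == rx_map[crit]
                and _in_window(rx.date, ref, definition.lookback_months)
                for rx in p.prescriptions
            )
        num += ok
    return num, len(denom)


def random_extract(seed, n_patients, gp_id="gpr"):
    """Randomized record-level fixture built directly, not via the generator."""
    rng = np.random.default_rng(seed)
    diseases = list(Disease)
    obs_types = ["bmi", "blood_pressure", "smoking_status", "creatinine",
                 "hba1c", "spirometry"]
    drug_classes = ["metformin", "statin", "beta_blocker", "ace_arb",
                    "antithrombotic"]
    patients = []
    for i in range(n_patients):
        encounters = frozenset(
            REF - dt.timedelta(days=int(rng.integers(0, 900)))
            for _ in range(rng.integers(1, 5))
        )
        dx = frozenset(
            (diseases[k], REF - dt.timedelta(days=int(rng.integers(100, 3000))))
            for k in rng.choice(8, size=rng.integers(0, 4), replace=False)
        )
        obs = tuple(
            Observation(
                obs_types[int(rng.integers(0, 6))],
                float(np.round(rng.uniform(4.0, 12.0), 1)),
                REF - dt.timedelta(days=int(rng.integers(0, 900))),
            )
            for _ in range(rng.integers(0, 8))
        )
        rx = tuple(
            Prescription(
                drug_classes[int(rng.integers(0, 5))],
                REF - dt.timedelta(days=int(rng.integers(0, 600))),
            )
            for _ in range(rng.integers(0, 5))
        )
        patients.append(
            PatientRecord(
                patient_id=f"p{i}", encounter_dates=encounters,
                diagnoses=dx, observations=obs, prescriptions=rx,
            )
        )
    return make_extract(gp_id, patients)


# --------------------------------------------------------------------------
# calendar arithmetic and eligibility
# --------------------------------------------------------------------------

class TestWindows:
    def test_month_subtraction_clips_day_overflow(self):
        assert months_before(dt.date(2024, 3, 31), 1) == dt.date(2024, 2, 29)
        assert months_before(dt.date(2023, 3, 31), 1) == dt.date(2023, 2, 28)
        assert months_before(dt.date(2012, 7, 1), 15) == dt.date(2011, 4, 1)

    def test_visit_window_boundaries(self, registry):
        recent = make_patient("a", visit_days_ago=(90,), diseases=("DM2",))
        # exactly on the window's lower edge -> excluded (half-open)
        edge_date = months_before(REF, 15)
        edge = PatientRecord(
            patient_id="b",
            encounter_dates=frozenset({edge_date}),
            diagnoses=frozenset({(Disease.DM2, REF - dt.timedelta(days=900))}),
        )
        old = make_patient("c", visit_days_ago=(16 * 30 + 20,), diseases=("DM2",))
        ext = make_extract("gp1", [recent, edge, old])
        assert [p.patient_id for p in eligible_patients(ext, "DM2")] == ["a"]

    def test_eligible_matches_hand_count(self):
        # 3 of 5 qualify: two lack either the diagnosis or a recent visit
        patients = [
            make_patient("p1", visit_days_ago=(10,), diseases=("DM2",)),
            make_patient("p2", visit_days_ago=(200,), diseases=("DM2", "HT")),
            make_patient("p3", visit_days_ago=(440,), diseases=("DM2",)),
            make_patient("p4", visit_days_ago=(10,), diseases=("HT",)),
            make_patient("p5", visit_days_ago=(600,), diseases=("DM2",)),
        ]
        ext = make_extract("gp1", patients)
        assert {p.patient_id for p in eligible_patients(ext, "DM2")} == {
            "p1", "p2", "p3",
        }

    def test_unknown_disease_rejected(self):
        ext = make_extract("gp1", [make_patient("p1")])
        with pytest.raises(ValueError):
            eligible_patients(ext, "NOPE")


class TestPrevalence:
    def test_hand_counted_fraction(self):
        patients = [
            make_patient(f"d{i}", visit_days_ago=(30,), diseases=("CHD",))
            for i in range(7)
        ] + [make_patient(f"h{i}", visit_days_ago=(30,)) for i in range(133)]
        ext = make_extract("gp1", patients)
        assert compute_prevalence(ext, "CHD") == pytest.approx(5.0)
        assert compute_prevalence(ext, "AF") == 0.0

    def test_empty_practice_rejected(self):
        ext = make_extract("gp1", [make_patient("p1", visit_days_ago=(800,))])
        with pytest.raises(ValueError, match="no patients"):
            compute_prevalence(ext, "DM2")

    @pytest.mark.parametrize(
        "raw,cov,expected", [(4.0, 1.0, 4.0), (4.0, 0.9, 3.6), (0.0, 0.5, 0.0)]
    )
    def test_adjustment(self, raw, cov, expected):
        assert adjust_prevalence(raw, cov) == pytest.approx(expected)

    def test_adjustment_never_inflates(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = float(rng.uniform(0, 100))
            cov = float(rng.uniform(0.01, 1.0))
            assert adjust_prevalence(raw, cov) <= raw

    @pytest.mark.parametrize("cov", [0.0, -0.1, 1.5])
    def test_bad_coverage_rejected(self, cov):
        with pytest.raises(ValueError):
            adjust_prevalence(4.0, cov)


# --------------------------------------------------------------------------
# achievement and the conditional chain
# --------------------------------------------------------------------------

def diabetes_fixture():
    """10 eligible DM2 patients: 8 measured, 6 below target, 1 of the 2
    above-target patients on metformin."""
    patients = []
    for i in range(10):
        obs = []
        rx = []
        if i < 8:  # measured within 9 months
            value = 6.8 if i < 6 else 8.9
            obs.append(("hba1c", value, 60))
            if i == 6:  # one above-target patient treated
                rx.append(("metformin", 30))
        patients.append(
            make_patient(f"p{i}", visit_days_ago=(20,), diseases=("DM2",),
                         obs=obs, rx=rx)
        )
    return make_extract("gp1", patients)


class TestAchievement:
    def test_conditional_chain_percentages(self, registry):
        ext = diabetes_fixture()
        done = compute_achievement(ext, registry["dm2_hba1c_done"])
        below = compute_achievement(ext, registry["dm2_hba1c_lt_7_5"])
        met = compute_achievement(ext, registry["dm2_metformin_if_high"])
        assert (done.numerator, done.denominator) == (8, 10)
        assert below.pct == pytest.approx(75.0)
        assert (below.numerator, below.denominator) == (6, 8)
        assert met.pct == pytest.approx(50.0)
        assert (met.numerator, met.denominator) == (1, 2)

    def test_empty_denominator_is_missing(self, registry):
        ext = make_extract("gp1", [make_patient("p1", visit_days_ago=(30,))])
        cell = compute_achievement(ext, registry["dm2_bmi"])
        assert cell.missing_reason is MissingReason.EMPTY_DENOMINATOR

    def test_capability_violation_is_missing_not_error(self, registry):
        ext = make_extract(
            "gp1",
            [make_patient("p1", visit_days_ago=(30,), diseases=("DM2",))],
            capability=PREVALENCE_ONLY,
        )
        assert (
            compute_achievement(ext, registry["dm2_bmi"]).missing_reason
            is MissingReason.CAPABILITY
        )
        assert not compute_achievement(ext, registry["dm2_prevalence"]).is_missing

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, registry, seed):
        ext = random_extract(seed, n_patients=120)
        for d in registry:
            cell = compute_achievement(ext, d)
            num, den = _oracle_cell(ext, d)
            if den == 0:
                assert cell.missing_reason is MissingReason.EMPTY_DENOMINATOR
            else:
                assert (cell.numerator, cell.denominator) == (num, den), d.indicator_id
                if d.kind is not IndicatorKind.PREVALENCE:
                    assert cell.pct == pytest.approx(100.0 * num / den)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_conditional_nesting(self, registry, seed):
        ext = random_extract(seed, n_patients=150)
        done = compute_achievement(ext, registry["dm2_hba1c_done"])
        below = compute_achievement(ext, registry["dm2_hba1c_lt_7_5"])
        met = compute_achievement(ext, registry["dm2_metformin_if_high"])
        if not below.is_missing:
            assert below.denominator == done.numerator
        if not met.is_missing:
            assert met.denominator <= below.denominator

    def test_shrinking_window_never_increases_numerator(self, registry):
        base = registry["dm2_bmi"]
        for seed in (7, 8):
            ext = random_extract(seed, n_patients=100)
            nums = []
            for months in (15, 9, 3):
                d = base.model_copy(update={"lookback_months": months})
                cell = compute_achievement(ext, d)
                nums.append(0 if cell.is_missing else cell.numerator)
            assert nums == sorted(nums, reverse=True)


# --------------------------------------------------------------------------
# table building and exclusions
# --------------------------------------------------------------------------

class TestAchievementTable:
    def test_shape(self, registry):
        extracts = [random_extract(s, 40, gp_id=f"gp{s}") for s in range(3)]
        table = build_achievement_table(extracts, registry)
        assert len(table.cells) == 3 * 43

    def test_prevalence_only_practice(self, registry):
        ext = make_extract(
            "gp1",
            [make_patient("p1", visit_days_ago=(30,), diseases=("DM2",))],
            capability=PREVALENCE_ONLY,
        )
        table = build_achievement_table([ext], registry)
        reasons = [
            table.cell("gp1", d.indicator_id).missing_reason for d in registry
        ]
        assert reasons.count(MissingReason.CAPABILITY) == 35
        assert sum(r is None for r in reasons) == 8

    def test_duplicate_gp_rejected(self, registry):
        ext = random_extract(0, 20)
        with pytest.raises(ValueError, match="duplicate gp_id"):
            build_achievement_table([ext, ext], registry)

    def test_empty_input_rejected(self, registry):
        with pytest.raises(ValueError):
            build_achievement_table([], registry)

    def test_roundtrip_through_frame(self, registry):
        table = build_achievement_table([random_extract(1, 60)], registry)
        again = AchievementTable.from_frame(table.to_frame())
        assert again.cells == table.cells
        assert again.gp_ids == table.gp_ids


class TestExclusions:
    def _chf_zero_table(self, registry):
        # one CHF-free practice: prevalence 0 must wipe the 4 dependent cells
        patients = [
            make_patient("p1", visit_days_ago=(20,), diseases=("DM2",),
                         obs=[("bmi", 27.0, 10)]),
            make_patient("p2", visit_days_ago=(25,)),
        ]
        return build_achievement_table([make_extract("gp1", patients)], registry)

    def test_prevalence_zero_wipes_dependent_cells(self, registry):
        table = self._chf_zero_table(registry)
        chf = [d for d in registry.for_disease("CHF")
               if d.kind is not IndicatorKind.PREVALENCE]
        assert len(chf) == 4
        for d in chf:
            assert (
                table.cell("gp1", d.indicator_id).missing_reason
                is MissingReason.PREVALENCE_ZERO
            )
        # the DM2 cells with data survive
        assert not table.cell("gp1", "dm2_bmi").is_missing

    def test_invalid_percentage_excluded(self, registry):
        table = self._chf_zero_table(registry)
        table.cells[("gp1", "dm2_bp")] = Cell(
            numerator=26, denominator=25, pct=104.2
        )
        out = apply_exclusions(table, registry)
        assert (
            out.cell("gp1", "dm2_bp").missing_reason is MissingReason.INVALID_VALUE
        )

    def test_idempotent_and_never_unmasks(self, registry):
        table = self._chf_zero_table(registry)
        once = apply_exclusions(table, registry)
        twice = apply_exclusions(once, registry)
        assert once.cells == twice.cells
        for key, cell in table.cells.items():
            if cell.is_missing:
                assert once.cells[key].is_missing

    def test_clean_table_unchanged(self, registry):
        ext = random_extract(9, 200)
        table = build_achievement_table([ext], registry)
        assert apply_exclusions(table, registry).cells == table.cells
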