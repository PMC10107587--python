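"""Screening, round validation, cascade and audit tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpvalidate.workflow import (
    DeviceReading,
    DeviceStatus,
    InputError,
    NurseReading,
    SubjectRecord,
    audit_sampling,
    classify_pregnant,
    percentage,
    read_rounds_csv,
    read_subjects_csv,
    run_cascade,
    screen_subject,
    validate_round,
)
from conftest import make_pair, make_round, pairs_to_rounds


def general_subject(**overrides):
    fields = dict(
        subject_id="G1", population="general", sex="male", age=40.0,
        arm_diff_sbp=5.0, arm_diff_dbp=3.0, resting_sbp=130.0, resting_dbp=80.0,
    )
    fields.update(overrides)
    return SubjectRecord(**fields)


def pregnant_subject(**overrides):
    fields = dict(
        subject_id="P1", population="pregnant", sex="female", age=28.0,
        arm_diff_sbp=5.0, arm_diff_dbp=3.0, resting_sbp=120.0, resting_dbp=75.0,
        proteinuria_flag=False, gestational_weeks=30.0,
    )
    fields.update(overrides)
    return SubjectRecord(**fields)


class TestScreening:
    def test_eligible_general_subject(self):
        assert screen_subject(general_subject()) is None

    def test_arm_difference_over_15_mmhg_excludes(self):
        assert screen_subject(general_subject(arm_diff_sbp=16.0)) == "arm_difference"
        assert screen_subject(general_subject(arm_diff_dbp=11.0)) == "arm_difference"
        assert screen_subject(general_subject(arm_diff_sbp=15.0)) is None

    def test_general_resting_cap_is_180_120(self):
        assert screen_subject(general_subject(resting_sbp=181.0)) == "resting_bp_cap"
        assert screen_subject(general_subject(resting_sbp=180.0, resting_dbp=120.0)) is None

    def test_pregnant_resting_cap_is_160_110(self):
        assert screen_subject(pregnant_subject(resting_sbp=158.0, resting_dbp=100.0)) is None
        assert screen_subject(pregnant_subject(resting_sbp=161.0)) == "resting_bp_cap"

    def test_age_limits_differ_by_population(self):
        assert screen_subject(general_subject(age=75.0)) is None
        assert screen_subject(general_subject(age=81.0)) == "age_range"
        assert screen_subject(pregnant_subject(age=51.0)) == "age_range"

    def test_rule_order_reports_first_failure(self):
        record = general_subject(age=17.0, arm_diff_sbp=20.0, resting_sbp=190.0)
        assert screen_subject(record) == "age_range"

    def test_incomplete_record_rejected(self):
        with pytest.raises(InputError, match="incomplete"):
            screen_subject(general_subject(resting_sbp=None))
        with pytest.raises(InputError, match="gestational"):
            screen_subject(pregnant_subject(gestational_weeks=None))


class TestClassifyPregnant:
    def test_boundary_139_89_is_normotensive(self):
        assert classify_pregnant(pregnant_subject(), (139.0, 89.0)) == "normotensive"

    def test_proteinuria_and_hypertension_is_pre_eclampsia(self):
        subject = pregnant_subject(proteinuria_flag=True)
        assert classify_pregnant(subject, (150.0, 95.0)) == "pre_eclampsia"

    def test_either_arm_over_threshold_is_hypertensive(self):
        assert (
            classify_pregnant(pregnant_subject(), (140.0, 85.0))
            == "hypertensive_no_proteinuria"
        )
        assert (
            classify_pregnant(pregnant_subject(), (130.0, 90.0))
            == "hypertensive_no_proteinuria"
        )

    def test_missing_inputs_rejected(self):
        with pytest.raises(InputError, match="proteinuria"):
            classify_pregnant(pregnant_subject(proteinuria_flag=None), (150.0, 95.0))
        with pytest.raises(InputError, match="BP"):
            classify_pregnant(pregnant_subject(), (float("nan"), 90.0))


class TestValidateRound:
    def test_valid_round_reference_is_nurse_mean(self):
        pair, reason = validate_round(
            make_round(n1=(120, 80), n2=(124, 82), device=(118, 79))
        )
        assert reason is None
        assert pair.reference_sbp == 122.0
        assert pair.reference_dbp == 81.0
        assert pair.device_sbp == 118.0

    def test_disagreement_over_4_mmhg_invalidates(self):
        pair, reason = validate_round(make_round(n1=(120, 80), n2=(125, 80)))
        assert pair is None and reason == "inter_nurse"
        # 4 mmHg exactly is still valid.
        pair, reason = validate_round(make_round(n1=(120, 80), n2=(124, 84)))
        assert reason is None

    def test_identical_readings_give_exact_reference(self):
        pair, _ = validate_round(make_round(n1=(118, 76), n2=(118, 76)))
        assert (pair.reference_sbp, pair.reference_dbp) == (118.0, 76.0)

    def test_device_failure_reported_before_disagreement(self):
        rnd = make_round(n1=(120, 80), n2=(130, 80), status=DeviceStatus.POOR_QUALITY)
        pair, reason = validate_round(rnd)
        assert pair is None and reason == "device_poor_quality"

    def test_symmetric_in_nurse_labels(self):
        a, _ = validate_round(make_round(n1=(120, 80), n2=(124, 82)))
        b, _ = validate_round(make_round(n1=(124, 82), n2=(120, 80)))
        assert (a.reference_sbp, a.reference_dbp) == (b.reference_sbp, b.reference_dbp)

    def test_reading_sanity_bounds_enforced(self):
        with pytest.raises(ValueError, match="implausible"):
            NurseReading(120.0, 121.0)
        with pytest.raises(ValueError, match="implausible"):
            NurseReading(310.0, 80.0)

    def test_device_reading_presence_matches_status(self):
        with pytest.raises(ValueError, match="status"):
            DeviceReading(status=DeviceStatus.OK)
        with pytest.raises(ValueError, match="status"):
            DeviceReading(status=DeviceStatus.MISSING, sbp=120.0, dbp=80.0)


class TestCascade:
    def test_subject_excluded_at_stage3_after_internurse_losses(self):
        rounds = [
            make_round("S1", 1, n1=(120, 80), n2=(130, 80)),   # inter-nurse
            make_round("S1", 2, n1=(120, 80), n2=(126, 80)),   # inter-nurse
            make_round("S1", 3),
            make_round("S1", 4),
        ]
        pairs, ledger = run_cascade(rounds)
        assert pairs == []
        assert ledger.measurement_exclusions["inter_nurse"] == 2
        assert ledger.measurement_exclusions["insufficient_pairs"] == 2
        assert ledger.subject_exclusions["insufficient_pairs"] == 1
        assert ledger.retained_subjects == 0
        assert ledger.conserves()

    def test_clean_subject_passes_with_zero_exclusions(self):
        rounds = [make_round("S1", i) for i in range(1, 5)]
        pairs, ledger = run_cascade(rounds)
        assert len(pairs) == 4
        assert sum(ledger.measurement_exclusions.values()) == 0
        assert ledger.retained_subjects == 1
        assert ledger.conserves()

    def test_stage4_variability_excludes_whole_subject(self):
        # Two rounds deviate from the median reference by > 12 mmHg SBP.
        rounds = [
            make_round("S1", 1, n1=(120, 80), n2=(120, 80)),
            make_round("S1", 2, n1=(122, 80), n2=(122, 80)),
            make_round("S1", 3, n1=(140, 80), n2=(140, 80)),
            make_round("S1", 4, n1=(100, 80), n2=(100, 80)),
        ]
        pairs, ledger = run_cascade(rounds)
        assert pairs == []
        assert ledger.subject_exclusions["excess_variability"] == 1
        assert ledger.measurement_exclusions["excess_variability"] == 4
        assert ledger.conserves()

    def test_single_deviant_round_is_tolerated(self):
        rounds = [
            make_round("S1", 1, n1=(120, 80), n2=(120, 80)),
            make_round("S1", 2, n1=(122, 80), n2=(122, 80)),
            make_round("S1", 3, n1=(124, 80), n2=(124, 80)),
            make_round("S1", 4, n1=(140, 80), n2=(140, 80)),
        ]
        pairs, ledger = run_cascade(rounds)
        assert len(pairs) == 4
        assert ledger.retained_subjects == 1

    def test_overlap_of_device_failure_and_disagreement_is_tallied(self):
        rounds = [
            make_round("S1", 1, n1=(120, 80), n2=(130, 80),
                       status=DeviceStatus.SIGNAL_NOT_CAPTURED),
            make_round("S1", 2),
            make_round("S1", 3),
            make_round("S1", 4),
        ]
        _, ledger = run_cascade(rounds)
        assert ledger.measurement_exclusions["device_failure"] == 1
        assert ledger.measurement_exclusions["inter_nurse"] == 0
        assert ledger.overlap_device_and_nurse == 1
        assert ledger.device_failure_breakdown == {"signal_not_captured": 1}

    def test_cascade_idempotent_on_own_output(self):
        rng = np.random.default_rng(11)
        rounds = []
        for s in range(12):
            for i in range(1, 5):
                sbp = float(rng.normal(125, 15))
                n2_off = float(rng.normal(0, 3))
                status = (
                    DeviceStatus.OK if rng.random() > 0.2
                    else DeviceStatus.SIGNAL_NOT_CAPTURED
                )
                rounds.append(
                    make_round(
                        f"S{s}", i, n1=(sbp, 80), n2=(sbp + n2_off, 80),
                        device=(sbp - 2, 78), status=status,
                    )
                )
        pairs, _ = run_cascade(rounds)
        pairs2, ledger2 = run_cascade(pairs_to_rounds(pairs))
        assert [
            (p.subject_id, p.reference_sbp, p.device_sbp) for p in pairs2
        ] == [(p.subject_id, p.reference_sbp, p.device_sbp) for p in pairs]
        assert sum(ledger2.measurement_exclusions.values()) == 0

    def test_round_order_within_subject_does_not_change_retention(self):
        rng = np.random.default_rng(5)
        rounds = []
        for s in range(8):
            for i in range(1, 6):
                sbp = float(rng.normal(125, 12))
                rounds.append(
                    make_round(f"S{s}", i, n1=(sbp, 80),
                               n2=(sbp + float(rng.normal(0, 3)), 80),
                               device=(sbp, 78))
                )
        pairs_fwd, _ = run_cascade(rounds)
        pairs_rev, _ = run_cascade(list(reversed(rounds)))
        assert {p.subject_id for p in pairs_fwd} == {p.subject_id for p in pairs_rev}

    def test_empty_survival_is_flagged_not_fatal(self):
        rounds = [
            make_round("S1", i, status=DeviceStatus.MISSING) for i in range(1, 5)
        ]
        pairs, ledger = run_cascade(rounds)
        assert pairs == []
        assert any("survived" in w for w in ledger.warnings)

    @given(st.integers(0, 2**30))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_conservation_and_min_pairs_guarantee(self, seed):
        rng = np.random.default_rng(seed)
        rounds = []
        for s in range(rng.integers(2, 8)):
            for i in range(1, rng.integers(4, 9)):
                sbp = float(np.clip(rng.normal(125, 20), 95, 250))
                status = (
                    DeviceStatus.OK if rng.random() > 0.3 else DeviceStatus.POOR_QUALITY
                )
                rounds.append(
                    make_round(
                        f"S{s}", i, n1=(sbp, 80),
                        n2=(sbp + float(rng.normal(0, 4)), 80),
                        device=(sbp + float(rng.normal(0, 6)), 78), status=status,
                    )
                )
        pairs, ledger = run_cascade(rounds)
        assert ledger.conserves()
        counts = {}
        for p in pairs:
            counts[p.subject_id] = counts.get(p.subject_id, 0) + 1
        assert all(c >= 3 for c in counts.values())


class TestLedgerArithmetic:
    def test_percentage_matches_reporting_convention(self):
        assert percentage(466, 1144) == 40.7
        assert percentage(125, 137) == 91.2
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_measurement_share_uses_excluded_total(self):
        rounds = [
            make_round("S1", 1, n1=(120, 80), n2=(130, 80)),
            make_round("S1", 2, status=DeviceStatus.MISSING),
            make_round("S1", 3),
            make_round("S1", 4),
            make_round("S1", 5),
        ]
        _, ledger = run_cascade(rounds)
        assert ledger.measurement_share("inter_nurse") == 50.0
        assert ledger.measurement_share("device_failure") == 50.0


class TestAuditSampling:
    @staticmethod
    def _general_dataset(sbp_values, dbp_values=None):
        dbp_values = dbp_values or [75.0] * len(sbp_values)
        pairs = [
            make_pair(f"S{i % 90}", 1 + i // 90, ref=(s, d), dev=(s, d))
            for i, (s, d) in enumerate(zip(sbp_values, dbp_values))
        ]
        subjects = [
            general_subject(subject_id=f"S{i}", sex="male" if i % 2 else "female")
            for i in range(90)
        ]
        return pairs, subjects

    def test_band_fractions_reported_as_printed(self):
        sbp = [95.0] * 59 + [120.0] * 298 + [150.0] * 55 + [165.0] * 12
        pairs, subjects = self._general_dataset(sbp)
        audit = audit_sampling(pairs, subjects)
        by_name = {c.name: c for c in audit.checks}
        assert by_name["sbp_le_100"].observed_percent == 13.9
        assert by_name["sbp_le_100"].passed
        # 140-159 plus >=160 counts pool into the >=140 requirement.
        assert by_name["sbp_ge_140"].observed_percent == 15.8

    def test_zero_severe_hypertension_band_fails(self):
        sbp = [120.0] * 400
        pairs, subjects = self._general_dataset(sbp)
        audit = audit_sampling(pairs, subjects)
        by_name = {c.name: c for c in audit.checks}
        assert not by_name["sbp_ge_160"].passed
        assert not audit.passed

    def test_pregnant_group_minimums(self):
        subjects = []
        for i in range(60):
            if i < 20:
                bp, flag = (120.0, 75.0), False
            elif i < 40:
                bp, flag = (150.0, 95.0), False
            else:
                bp, flag = (150.0, 98.0), True
            subjects.append(
                pregnant_subject(
                    subject_id=f"P{i}", resting_sbp=bp[0], resting_dbp=bp[1],
                    proteinuria_flag=flag,
                )
            )
        audit = audit_sampling([], subjects)
        group_checks = [c for c in audit.checks if c.name.startswith("group_")]
        assert len(group_checks) == 3
        assert all(c.passed for c in group_checks)
        assert all(c.observed == 20 for c in group_checks)

    def test_pregnant_audit_requires_proteinuria_flags(self):
        subjects = [pregnant_subject(proteinuria_flag=None)]
        with pytest.raises(InputError, match="proteinuria"):
            audit_sampling([], subjects)

    def test_mixed_populations_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            audit_sampling([], [general_subject(), pregnant_subject()])


class TestCsvContracts:
    def test_rounds_roundtrip_and_missing_device_fields(self, tmp_path):
        path = tmp_path / "rounds.csv"
        path.write_text(
            "subject_id,site,population,sex,age,round_index,"
            "n1_sbp,n1_dbp,n2_sbp,n2_dbp,dev_status,dev_sbp,dev_dbp\n"
            "S1,TZ,general,male,40,1,120,80,122,82,ok,118,79\n"
            "S1,TZ,general,male,40,2,120,80,122,82,signal_not_captured,,\n"
        )
        rounds = read_rounds_csv(path)
        assert len(rounds) == 2
        assert rounds[1].device.status is DeviceStatus.SIGNAL_NOT_CAPTURED
        assert rounds[1].device.sbp is None

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "rounds.csv"
        path.write_text(
            "subject_id,site,population,sex,age,round_index,"
            "n1_sbp,n1_dbp,n2_sbp,n2_dbp,dev_status,dev_sbp,dev_dbp\n"
            "S1,TZ,general,male,40,1,120,80,122,82,ok,,\n"  # ok but no values
            "S1,TZ,general,male,40,9,120,80,122,82,ok,118,79\n"  # round 9
        )
        with pytest.raises(InputError) as excinfo:
            read_rounds_csv(path)
        assert any("line 2" in e for e in excinfo.value.row_errors)
        assert any("line 3" in e for e in excinfo.value.row_errors)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "rounds.csv"
        path.write_text("subject_id,round_index\nS1,1\n")
        with pytest.raises(InputError, match="missing required columns"):
            read_rounds_csv(path)

    def test_subjects_csv_parses_flags(self, tmp_path):
        path = tmp_path / "subjects.csv"
        path.write_text(
            "subject_id,site,population,sex,age,arm_diff_sbp,arm_diff_dbp,"
            "resting_sbp,resting_dbp,proteinuria_flag,gestational_weeks\n"
            "P1,SA,pregnant,female,28,5,3,150,95,1,30\n"
            "G1,TZ,general,male,40,5,3,130,80,,\n"
        )
        subjects = read_subjects_csv(path)
        assert subjects[0].proteinuria_flag is True
        assert subjects[1].proteinuria_flag is None
        assert subjects[1].gestational_weeks is None
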