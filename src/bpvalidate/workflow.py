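"""Session workflow: screening, reference derivation, exclusion cascade, audits.

A validation session produces up to eight rounds per participant, each round
holding two blinded simultaneous nurse auscultatory readings and one test
device reading.  The reference for a round is the mean of the two nurse
readings, valid only when the nurses agree within 4 mmHg on both arms and
the device produced a reading.

The ordered exclusion cascade mirrors common practice in these studies:

1. device failure (signal not captured / poor quality / irregular heart
   rate / outlier / missing),
2. inter-nurse disagreement > 4 mmHg (SBP or DBP),
3. whole subjects left with fewer than three valid pairs,
4. whole subjects whose per-round reference varies excessively
   (> 12 mmHg SBP or > 8 mmHg DBP from the subject's median reference on
   two or more rounds).

A record carries exactly the first reason that removed it; the ledger
conserves counts at both the measurement and the subject level.
"""

from __future__ import annotations

import enum
import json
import math
import statistics
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "DeviceStatus",
    "NurseReading",
    "DeviceReading",
    "MeasurementRound",
    "PairedMeasurement",
    "SubjectRecord",
    "ScreeningCaps",
    "GENERAL_CAPS",
    "PREGNANT_CAPS",
    "ExclusionLedger",
    "SamplingRequirements",
    "RequirementCheck",
    "SamplingAudit",
    "InputError",
    "percentage",
    "screen_subject",
    "classify_pregnant",
    "validate_round",
    "run_cascade",
    "audit_sampling",
    "read_rounds_csv",
    "read_subjects_csv",
]

#: Maximum tolerated inter-nurse difference for a valid round, mmHg.
INTER_NURSE_LIMIT = 4.0
#: Stage-4 within-subject reference variability limits, mmHg.
SBP_VARIABILITY_LIMIT = 12.0
DBP_VARIABILITY_LIMIT = 8.0
#: Stage-3 minimum retained pairs per subject.
MIN_PAIRS_PER_SUBJECT = 3
#: Session design: minimum valid rounds sought, maximum attempts.
MIN_VALID_ROUNDS = 4
MAX_ROUNDS = 8


class InputError(ValueError):
    """Malformed input file; carries per-row diagnostics."""

    def __init__(self, message: str, row_errors: Sequence[str] = ()):
        super().__init__(message)
        self.row_errors = list(row_errors)


class DeviceStatus(str, enum.Enum):
    OK = "ok"
    SIGNAL_NOT_CAPTURED = "signal_not_captured"
    POOR_QUALITY = "poor_quality"
    IRREGULAR_HEART_RATE = "irregular_heart_rate"
    OUTLIER = "outlier"
    MISSING = "missing"


def percentage(numerator: float, denominator: float) -> float:
    """Share as a percentage rounded to 1 decimal, the reporting convention."""
    if denominator == 0:
        raise ValueError("percentage undefined for a zero denominator")
    return round(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class NurseReading:
    sbp: float
    dbp: float
    observer_id: str = "nurse1"

    def __post_init__(self) -> None:
        if not (40.0 <= self.dbp < self.sbp <= 300.0):
            raise ValueError(
                f"implausible reading {self.sbp}/{self.dbp} mmHg "
                "(need 40 <= DBP < SBP <= 300)"
            )


@dataclass(frozen=True)
class DeviceReading:
    status: DeviceStatus = DeviceStatus.OK
    sbp: Optional[float] = None
    dbp: Optional[float] = None

    def __post_init__(self) -> None:
        present = self.sbp is not None and self.dbp is not None
        if (self.status is DeviceStatus.OK) != present:
            raise ValueError(
                "device SBP/DBP must be present exactly when status is 'ok' "
                f"(status={self.status.value}, sbp={self.sbp}, dbp={self.dbp})"
            )


@dataclass(frozen=True)
class MeasurementRound:
    subject_id: str
    round_index: int
    nurse1: NurseReading
    nurse2: NurseReading
    device: DeviceReading

    def __post_init__(self) -> None:
        if not 1 <= self.round_index <= MAX_ROUNDS:
            raise ValueError(
                f"round_index must lie in 1..{MAX_ROUNDS}, got {self.round_index}"
            )


@dataclass(frozen=True)
class PairedMeasurement:
    """A validated (reference, device) pair surviving round validation."""

    subject_id: str
    round_index: int
    reference_sbp: float
    reference_dbp: float
    device_sbp: float
    device_dbp: float

    def error(self, arm: str) -> float:
        if arm == "SBP":
            return self.device_sbp - self.reference_sbp
        if arm == "DBP":
            return self.device_dbp - self.reference_dbp
        raise ValueError(f"arm must be 'SBP' or 'DBP', got {arm!r}")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    population: str = "general"  # 'general' | 'pregnant'
    sex: str = "female"
    age: Optional[float] = None
    country_site: str = ""
    arm_diff_sbp: Optional[float] = None
    arm_diff_dbp: Optional[float] = None
    resting_sbp: Optional[float] = None
    resting_dbp: Optional[float] = None
    proteinuria_flag: Optional[bool] = None
    gestational_weeks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.population not in ("general", "pregnant"):
            raise ValueError(f"unknown population {self.population!r}")


@dataclass(frozen=True)
class ScreeningCaps:
    """Eligibility caps; defaults differ between populations."""

    age_min: float
    age_max: float
    arm_diff_sbp_max: float = 15.0
    arm_diff_dbp_max: float = 10.0
    resting_sbp_max: float = 180.0
    resting_dbp_max: float = 120.0


GENERAL_CAPS = ScreeningCaps(age_min=18, age_max=80, resting_sbp_max=180, resting_dbp_max=120)
PREGNANT_CAPS = ScreeningCaps(age_min=18, age_max=50, resting_sbp_max=160, resting_dbp_max=110)


def screen_subject(
    record: SubjectRecord, caps: Optional[ScreeningCaps] = None
) -> Optional[str]:
    """Eligibility screen; returns the first failed rule, or None if eligible.

    Rule order: age range, between-arm difference, resting-BP cap.
    Exclusionary caps are exclusive (a difference of exactly 15 mmHg or a
    resting BP of exactly 180/120 remains eligible), matching '>' wording.
    """
    if caps is None:
        caps = PREGNANT_CAPS if record.population == "pregnant" else GENERAL_CAPS
    required = (
        record.age,
        record.arm_diff_sbp,
        record.arm_diff_dbp,
        record.resting_sbp,
        record.resting_dbp,
    )
    if any(v is None or not math.isfinite(float(v)) for v in required):
        raise InputError(
            f"subject {record.subject_id!r}: incomplete screening record "
            "(age, arm differences and resting BP are required)"
        )
    if record.population == "pregnant" and record.gestational_weeks is None:
        raise InputError(
            f"subject {record.subject_id!r}: pregnant record lacks gestational_weeks"
        )
    if not caps.age_min <= record.age <= caps.age_max:
        return "age_range"
    if (
        abs(record.arm_diff_sbp) > caps.arm_diff_sbp_max
        or abs(record.arm_diff_dbp) > caps.arm_diff_dbp_max
    ):
        return "arm_difference"
    if record.resting_sbp > caps.resting_sbp_max or record.resting_dbp > caps.resting_dbp_max:
        return "resting_bp_cap"
    return None


def classify_pregnant(
    subject: SubjectRecord, enrollment_bp: tuple[float, float]
) -> str:
    """Pregnancy BP group at enrollment.

    normotensive if SBP < 140 and DBP < 90; otherwise pre_eclampsia when the
    proteinuria flag is set, else hypertensive_no_proteinuria.
    """
    sbp, dbp = enrollment_bp
    if sbp is None or dbp is None or not (math.isfinite(sbp) and math.isfinite(dbp)):
        raise InputError(
            f"subject {subject.subject_id!r}: enrollment BP missing or non-finite"
        )
    if subject.proteinuria_flag is None:
        raise InputError(
            f"subject {subject.subject_id!r}: proteinuria flag required to classify"
        )
    if sbp < 140.0 and dbp < 90.0:
        return "normotensive"
    return "pre_eclampsia" if subject.proteinuria_flag else "hypertensive_no_proteinuria"


def _nurse_disagreement(rnd: MeasurementRound) -> bool:
    return (
        abs(rnd.nurse1.sbp - rnd.nurse2.sbp) > INTER_NURSE_LIMIT
        or abs(rnd.nurse1.dbp - rnd.nurse2.dbp) > INTER_NURSE_LIMIT
    )


def validate_round(
    rnd: MeasurementRound,
) -> tuple[Optional[PairedMeasurement], Optional[str]]:
    """Validate one round; returns ``(pair, None)`` or ``(None, reason)``.

    Device failure is reported before nurse disagreement, matching the
    cascade order.  The 4-mmHg rule applies jointly to SBP and DBP.
    """
    if rnd.device.status is not DeviceStatus.OK:
        return None, f"device_{rnd.device.status.value}"
    if _nurse_disagreement(rnd):
        return None, "inter_nurse"
    return (
        PairedMeasurement(
            subject_id=rnd.subject_id,
            round_index=rnd.round_index,
            reference_sbp=(rnd.nurse1.sbp + rnd.nurse2.sbp) / 2.0,
            reference_dbp=(rnd.nurse1.dbp + rnd.nurse2.dbp) / 2.0,
            device_sbp=float(rnd.device.sbp),
            device_dbp=float(rnd.device.dbp),
        ),
        None,
    )


_STAGES = ("device_failure", "inter_nurse", "insufficient_pairs", "excess_variability")


@dataclass
class ExclusionLedger:
    """Ordered tally of exclusions at measurement and subject level."""

    total_measurements: int = 0
    total_subjects: int = 0
    measurement_exclusions: "OrderedDict[str, int]" = field(
        default_factory=lambda: OrderedDict((s, 0) for s in _STAGES)
    )
    subject_exclusions: "OrderedDict[str, int]" = field(
        default_factory=lambda: OrderedDict(
            (s, 0) for s in ("insufficient_pairs", "excess_variability")
        )
    )
    device_failure_breakdown: "OrderedDict[str, int]" = field(default_factory=OrderedDict)
    retained_measurements: int = 0
    retained_subjects: int = 0
    overlap_device_and_nurse: int = 0
    records: list = field(default_factory=list)  # (subject_id, round_index, reason)
    warnings: list = field(default_factory=list)

    def measurement_share(self, reason: str) -> float:
        """Stage share among excluded measurements, as a 1-decimal percentage."""
        total_excluded = sum(self.measurement_exclusions.values())
        return percentage(self.measurement_exclusions[reason], total_excluded)

    def conserves(self) -> bool:
        m_ok = (
            self.retained_measurements + sum(self.measurement_exclusions.values())
            == self.total_measurements
        )
        s_ok = (
            self.retained_subjects + sum(self.subject_exclusions.values())
            == self.total_subjects
        )
        return m_ok and s_ok

    def to_dict(self) -> dict:
        return {
            "total_measurements": self.total_measurements,
            "total_subjects": self.total_subjects,
            "measurement_exclusions": dict(self.measurement_exclusions),
            "subject_exclusions": dict(self.subject_exclusions),
            "device_failure_breakdown": dict(self.device_failure_breakdown),
            "retained_measurements": self.retained_measurements,
            "retained_subjects": self.retained_subjects,
            "overlap_device_and_nurse": self.overlap_device_and_nurse,
            "records": [list(r) for r in self.records],
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExclusionLedger":
        ledger = cls(
            total_measurements=d["total_measurements"],
            total_subjects=d["total_subjects"],
            measurement_exclusions=OrderedDict(d["measurement_exclusions"]),
            subject_exclusions=OrderedDict(d["subject_exclusions"]),
            device_failure_breakdown=OrderedDict(d["device_failure_breakdown"]),
            retained_measurements=d["retained_measurements"],
            retained_subjects=d["retained_subjects"],
            overlap_device_and_nurse=d["overlap_device_and_nurse"],
            records=[tuple(r) for r in d["records"]],
            warnings=list(d["warnings"]),
        )
        return ledger

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def run_cascade(
    rounds: Sequence[MeasurementRound],
) -> tuple[list[PairedMeasurement], ExclusionLedger]:
    """Apply the four-stage exclusion cascade in order.

    Stages 1–2 act on measurements, stages 3–4 remove whole subjects (their
    surviving pairs are tallied at the measurement level under the subject's
    reason).  Rounds that fail both the device and the inter-nurse rule are
    excluded under stage 1 and counted in ``overlap_device_and_nurse``.
    An empty retained set is allowed and flagged with a warning.
    """
    ledger = ExclusionLedger(total_measurements=len(rounds))
    by_subject: "OrderedDict[str, list[PairedMeasurement]]" = OrderedDict()
    for rnd in rounds:
        by_subject.setdefault(rnd.subject_id, [])
    ledger.total_subjects = len(by_subject)

    # Stages 1-2: per-measurement removal, device failure checked first.
    for rnd in rounds:
        pair, reason = validate_round(rnd)
        if pair is not None:
            by_subject[rnd.subject_id].append(pair)
            continue
        if reason.startswith("device_"):
            ledger.measurement_exclusions["device_failure"] += 1
            status = reason.removeprefix("device_")
            ledger.device_failure_breakdown[status] = (
                ledger.device_failure_breakdown.get(status, 0) + 1
            )
            if _nurse_disagreement(rnd):
                ledger.overlap_device_and_nurse += 1
        else:
            ledger.measurement_exclusions["inter_nurse"] += 1
        ledger.records.append((rnd.subject_id, rnd.round_index, reason))

    # Stage 3: subjects with fewer than three surviving pairs.
    retained: "OrderedDict[str, list[PairedMeasurement]]" = OrderedDict()
    for subject_id, pairs in by_subject.items():
        if len(pairs) < MIN_PAIRS_PER_SUBJECT:
            ledger.subject_exclusions["insufficient_pairs"] += 1
            ledger.measurement_exclusions["insufficient_pairs"] += len(pairs)
            for p in pairs:
                ledger.records.append((subject_id, p.round_index, "insufficient_pairs"))
        else:
            retained[subject_id] = pairs

    # Stage 4: excessive within-subject reference variability.
    survivors: list[PairedMeasurement] = []
    for subject_id, pairs in retained.items():
        med_sbp = statistics.median(p.reference_sbp for p in pairs)
        med_dbp = statistics.median(p.reference_dbp for p in pairs)
        deviant = sum(
            1
            for p in pairs
            if abs(p.reference_sbp - med_sbp) > SBP_VARIABILITY_LIMIT
            or abs(p.reference_dbp - med_dbp) > DBP_VARIABILITY_LIMIT
        )
        if deviant >= 2:
            ledger.subject_exclusions["excess_variability"] += 1
            ledger.measurement_exclusions["excess_variability"] += len(pairs)
            for p in pairs:
                ledger.records.append((subject_id, p.round_index, "excess_variability"))
            continue
        if len(pairs) < MIN_VALID_ROUNDS:
            ledger.warnings.append(
                f"subject {subject_id!r} retained with only {len(pairs)} valid "
                f"pairs (protocol seeks {MIN_VALID_ROUNDS})"
            )
        ledger.retained_subjects += 1
        survivors.extend(pairs)

    ledger.retained_measurements = len(survivors)
    if not survivors:
        ledger.warnings.append("no measurements survived the exclusion cascade")
    return survivors, ledger


# --------------------------------------------------------------------------
# Sampling-distribution audits


@dataclass(frozen=True)
class RequirementCheck:
    name: str
    observed: float
    bound: float
    passed: bool
    unit: str = "fraction"  # 'fraction' | 'count'

    @property
    def observed_percent(self) -> float:
        """Observed fraction as a 1-decimal percentage (fraction checks only)."""
        if self.unit != "fraction":
            raise ValueError("observed_percent applies to fraction checks")
        return round(100.0 * self.observed, 1)


@dataclass(frozen=True)
class SamplingRequirements:
    """Population-specific recruitment bounds from the consensus protocol."""

    population: str = "general"
    min_n_subjects: int = 85
    min_sex_fraction: float = 0.30
    # General population: bounds on reference-BP band fractions (measurements).
    sbp_low_max: float = 100.0  # fraction with SBP <= 100 must be >= 5 %
    sbp_high_min: float = 140.0  # fraction with SBP >= 140 must be >= 20 %
    sbp_very_high_min: float = 160.0  # fraction with SBP >= 160 must be >= 5 %
    dbp_low_max: float = 60.0
    dbp_high_min: float = 85.0
    dbp_very_high_min: float = 100.0
    band_small_fraction: float = 0.05
    band_large_fraction: float = 0.20
    # Pregnant population: minimum subjects per BP group.
    min_group_n: int = 20


GENERAL_REQUIREMENTS = SamplingRequirements(population="general", min_n_subjects=85)
PREGNANT_REQUIREMENTS = SamplingRequirements(population="pregnant", min_n_subjects=45)


@dataclass(frozen=True)
class SamplingAudit:
    population: str
    checks: tuple[RequirementCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "passed": self.passed,
            "checks": [
                {
                    "name": c.name,
                    "observed": c.observed,
                    "bound": c.bound,
                    "passed": c.passed,
                    "unit": c.unit,
                }
                for c in self.checks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingAudit":
        return cls(
            population=d["population"],
            checks=tuple(
                RequirementCheck(
                    name=c["name"],
                    observed=c["observed"],
                    bound=c["bound"],
                    passed=c["passed"],
                    unit=c["unit"],
                )
                for c in d["checks"]
            ),
        )


def _fraction_check(name: str, values, predicate, bound: float) -> RequirementCheck:
    n = len(values)
    observed = sum(1 for v in values if predicate(v)) / n if n else 0.0
    return RequirementCheck(name, observed, bound, observed >= bound)


def audit_sampling(
    pairs: Sequence[PairedMeasurement],
    subjects: Sequence[SubjectRecord],
    requirements: Optional[SamplingRequirements] = None,
) -> SamplingAudit:
    """Audit the retained sample against the protocol's distribution bounds.

    General population: BP band fractions are computed over the reference
    values of retained measurements; subject count and sex fractions over
    retained subjects.  Pregnant population: subjects are classified at
    enrollment (resting BP + proteinuria flag) and each group must reach
    the minimum count.
    """
    if not subjects:
        raise ValueError("audit requires at least one subject record")
    populations = {s.population for s in subjects}
    if len(populations) > 1:
        raise ValueError(f"mixed populations in one audit: {sorted(populations)}")
    population = populations.pop()
    if requirements is None:
        requirements = (
            PREGNANT_REQUIREMENTS if population == "pregnant" else GENERAL_REQUIREMENTS
        )
    req = requirements
    checks: list[RequirementCheck] = [
        RequirementCheck(
            "n_subjects", len(subjects), req.min_n_subjects,
            len(subjects) >= req.min_n_subjects, unit="count",
        )
    ]

    if population == "general":
        sbp = [p.reference_sbp for p in pairs]
        dbp = [p.reference_dbp for p in pairs]
        small, large = req.band_small_fraction, req.band_large_fraction
        checks += [
            _fraction_check("sex_male", subjects, lambda s: s.sex == "male", req.min_sex_fraction),
            _fraction_check("sex_female", subjects, lambda s: s.sex == "female", req.min_sex_fraction),
            _fraction_check("sbp_le_100", sbp, lambda v: v <= req.sbp_low_max, small),
            _fraction_check("sbp_ge_160", sbp, lambda v: v >= req.sbp_very_high_min, small),
            _fraction_check("sbp_ge_140", sbp, lambda v: v >= req.sbp_high_min, large),
            _fraction_check("dbp_le_60", dbp, lambda v: v <= req.dbp_low_max, small),
            _fraction_check("dbp_ge_100", dbp, lambda v: v >= req.dbp_very_high_min, small),
            _fraction_check("dbp_ge_85", dbp, lambda v: v >= req.dbp_high_min, large),
        ]
    else:
        if any(s.proteinuria_flag is None for s in subjects):
            raise InputError(
                "pregnant audit requires a proteinuria flag on every subject"
            )
        groups = {"normotensive": 0, "hypertensive_no_proteinuria": 0, "pre_eclampsia": 0}
        for s in subjects:
            groups[classify_pregnant(s, (s.resting_sbp, s.resting_dbp))] += 1
        for name, count in groups.items():
            checks.append(
                RequirementCheck(
                    f"group_{name}", count, req.min_group_n,
                    count >= req.min_group_n, unit="count",
                )
            )
    return SamplingAudit(population=population, checks=tuple(checks))


# --------------------------------------------------------------------------
# CSV contracts

ROUNDS_COLUMNS = [
    "subject_id", "site", "population", "sex", "age", "round_index",
    "n1_sbp", "n1_dbp", "n2_sbp", "n2_dbp", "dev_status", "dev_sbp", "dev_dbp",
]
SUBJECTS_COLUMNS = [
    "subject_id", "site", "population", "sex", "age",
    "arm_diff_sbp", "arm_diff_dbp", "resting_sbp", "resting_dbp",
    "proteinuria_flag", "gestational_weeks",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")


def read_rounds_csv(path) -> list[MeasurementRound]:
    """Read round-level records; one row per round, header required.

    Device SBP/DBP may be empty only when ``dev_status`` is not ``ok``.
    Malformed rows are collected and reported with line numbers.
    """
    df = pd.read_csv(path)
    _require_columns(df, ROUNDS_COLUMNS, path)
    rounds: list[MeasurementRound] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            status = DeviceStatus(str(row["dev_status"]).strip())
            dev_sbp = None if pd.isna(row["dev_sbp"]) else float(row["dev_sbp"])
            dev_dbp = None if pd.isna(row["dev_dbp"]) else float(row["dev_dbp"])
            rounds.append(
                MeasurementRound(
                    subject_id=str(row["subject_id"]),
                    round_index=int(row["round_index"]),
                    nurse1=NurseReading(float(row["n1_sbp"]), float(row["n1_dbp"]), "nurse1"),
                    nurse2=NurseReading(float(row["n2_sbp"]), float(row["n2_dbp"]), "nurse2"),
                    device=DeviceReading(status=status, sbp=dev_sbp, dbp=dev_dbp),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise InputError(
            f"{path}: {len(errors)} malformed round record(s)", row_errors=errors
        )
    return rounds


def _opt_float(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_subjects_csv(path) -> list[SubjectRecord]:
    """Read subject-level screening records."""
    df = pd.read_csv(path)
    _require_columns(df, SUBJECTS_COLUMNS, path)
    subjects: list[SubjectRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            flag = row["proteinuria_flag"]
            proteinuria = None if pd.isna(flag) else bool(int(flag))
            subjects.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    population=str(row["population"]),
                    sex=str(row["sex"]),
                    age=_opt_float(row["age"]),
                    country_site=str(row["site"]),
                    arm_diff_sbp=_opt_float(row["arm_diff_sbp"]),
                    arm_diff_dbp=_opt_float(row["arm_diff_dbp"]),
                    resting_sbp=_opt_float(row["resting_sbp"]),
                    resting_dbp=_opt_float(row["resting_dbp"]),
                    proteinuria_flag=proteinuria,
                    gestational_weeks=_opt_float(row["gestational_weeks"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise InputError(
            f"{path}: {len(errors)} malformed subject record(s)", row_errors=errors
        )
    return subjects
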