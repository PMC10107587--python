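"""End-to-end study evaluation and report generation.

``evaluate`` runs the complete analysis for one site: subject screening,
the exclusion cascade, both accuracy criteria per arm, the sampling audit
and Bland-Altman agreement, and packages everything into a
:class:`StudyReport` that serializes losslessly to JSON.  Reported tables
follow the field's rounding conventions (means/SDs to 1 decimal,
permissible-SD thresholds to 2 decimals, percentages to 1 decimal).
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import agreement, criteria, workflow
from .agreement import BlandAltmanResult
from .criteria import Criterion1Result, Criterion2Constants, Criterion2Result
from .workflow import (
    ExclusionLedger,
    InputError,
    MeasurementRound,
    PairedMeasurement,
    SamplingAudit,
    SubjectRecord,
)

__all__ = ["StudyReport", "evaluate", "NotEvaluableError"]

ARMS = ("SBP", "DBP")


class NotEvaluableError(RuntimeError):
    """The retained dataset is too small to evaluate the criteria."""


@dataclass
class StudyReport:
    site: str
    population: str
    n_subjects: int
    n_measurements: int
    status: str  # 'ok' | 'not_evaluable'
    criterion1: "OrderedDict[str, Optional[Criterion1Result]]"
    criterion2: "OrderedDict[str, Optional[Criterion2Result]]"
    bland_altman: "OrderedDict[str, Optional[BlandAltmanResult]]"
    ledger: ExclusionLedger
    audit: Optional[SamplingAudit]
    screening_exclusions: "OrderedDict[str, int]" = field(default_factory=OrderedDict)

    def to_dict(self) -> dict:
        def c1(r):
            return None if r is None else {
                "mean_error": r.mean_error, "sd_error": r.sd_error,
                "n_measurements": r.n_measurements, "passed": r.passed,
            }

        def c2(r):
            return None if r is None else {
                "per_subject_mean_errors": list(r.per_subject_mean_errors),
                "sd_between_subjects": r.sd_between_subjects,
                "permissible_sd": r.permissible_sd,
                "mean_error_used": r.mean_error_used,
                "passed": r.passed,
            }

        def ba(r):
            return None if r is None else {
                "arm": r.arm,
                "pair_means": list(r.pair_means),
                "pair_diffs": list(r.pair_diffs),
                "subject_ids": list(r.subject_ids),
                "bias": r.bias, "sd_diff": r.sd_diff,
                "loa_low": r.loa_low, "loa_high": r.loa_high,
            }

        return {
            "site": self.site,
            "population": self.population,
            "n_subjects": self.n_subjects,
            "n_measurements": self.n_measurements,
            "status": self.status,
            "criterion1": {arm: c1(self.criterion1[arm]) for arm in ARMS},
            "criterion2": {arm: c2(self.criterion2[arm]) for arm in ARMS},
            "bland_altman": {arm: ba(self.bland_altman[arm]) for arm in ARMS},
            "ledger": self.ledger.to_dict(),
            "audit": None if self.audit is None else self.audit.to_dict(),
            "screening_exclusions": dict(self.screening_exclusions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        def c1(r):
            return None if r is None else Criterion1Result(**r)

        def c2(r):
            return None if r is None else Criterion2Result(
                per_subject_mean_errors=tuple(r["per_subject_mean_errors"]),
                sd_between_subjects=r["sd_between_subjects"],
                permissible_sd=r["permissible_sd"],
                mean_error_used=r["mean_error_used"],
                passed=r["passed"],
            )

        def ba(r):
            return None if r is None else BlandAltmanResult(
                arm=r["arm"],
                pair_means=tuple(r["pair_means"]),
                pair_diffs=tuple(r["pair_diffs"]),
                subject_ids=tuple(r["subject_ids"]),
                bias=r["bias"], sd_diff=r["sd_diff"],
                loa_low=r["loa_low"], loa_high=r["loa_high"],
            )

        return cls(
            site=d["site"],
            population=d["population"],
            n_subjects=d["n_subjects"],
            n_measurements=d["n_measurements"],
            status=d["status"],
            criterion1=OrderedDict((arm, c1(d["criterion1"][arm])) for arm in ARMS),
            criterion2=OrderedDict((arm, c2(d["criterion2"][arm])) for arm in ARMS),
            bland_altman=OrderedDict((arm, ba(d["bland_altman"][arm])) for arm in ARMS),
            ledger=ExclusionLedger.from_dict(d["ledger"]),
            audit=None if d["audit"] is None else SamplingAudit.from_dict(d["audit"]),
            screening_exclusions=OrderedDict(d["screening_exclusions"]),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls.from_dict(json.loads(text))

    def render_tables(self) -> str:
        """Human-readable criterion-1/2 tables in the conventional layout."""
        lines = [
            f"Site {self.site} — {self.population} population "
            f"(N = {self.n_subjects}, M = {self.n_measurements})",
            "",
            "Criterion 1 (pooled measurement errors, device − reference)",
            f"{'':14}{'requirement':>22}{'observed':>12}{'verdict':>14}",
        ]
        for arm in ARMS:
            r = self.criterion1[arm]
            if r is None:
                lines.append(f"  {arm:<12}{'—':>22}{'—':>12}{'not evaluable':>14}")
                continue
            verdict = "passed" if r.passed else "did not pass"
            lines.append(
                f"  {arm} mean{'':<4}{'−5 ≤ mean ≤ 5':>22}{r.mean_error:>12.1f}{verdict:>14}"
            )
            lines.append(f"  {arm} SD{'':<6}{'SD ≤ 8':>22}{r.sd_error:>12.1f}{verdict:>14}")
        lines += ["", "Criterion 2 (SD of per-subject mean errors)"]
        for arm in ARMS:
            r = self.criterion2[arm]
            if r is None:
                lines.append(f"  {arm:<12}not evaluable")
                continue
            verdict = "passed" if r.passed else "did not pass"
            lines.append(
                f"  {arm}: observed {r.sd_between_subjects:.1f} "
                f"≤ permissible {r.permissible_sd:.2f} "
                f"(mean error used {r.mean_error_used:.1f}) → {verdict}"
            )
        return "\n".join(lines)


def _screen(
    subjects: Sequence[SubjectRecord],
) -> tuple[list[SubjectRecord], "OrderedDict[str, int]"]:
    eligible: list[SubjectRecord] = []
    tally: "OrderedDict[str, int]" = OrderedDict()
    for s in subjects:
        reason = workflow.screen_subject(s)
        if reason is None:
            eligible.append(s)
        else:
            tally[reason] = tally.get(reason, 0) + 1
    return eligible, tally


def evaluate(
    rounds: Union[str, Path, Sequence[MeasurementRound]],
    subjects: Union[str, Path, Sequence[SubjectRecord]],
    *,
    constants: Criterion2Constants = criteria.DEFAULT_CONSTANTS,
    table_mode: bool = False,
    site: Optional[str] = None,
) -> StudyReport:
    """Run the full pipeline: screening → cascade → criteria → audit → Bland-Altman.

    ``rounds`` and ``subjects`` may be CSV paths (the documented contracts)
    or already-parsed record sequences.  Raises :class:`InputError` on
    malformed or empty inputs; a structurally valid dataset whose retained
    set is too small for the criteria yields a report with status
    ``not_evaluable`` rather than an exception.
    """
    if isinstance(rounds, (str, Path)):
        rounds = workflow.read_rounds_csv(rounds)
    else:
        rounds = list(rounds)
    if isinstance(subjects, (str, Path)):
        subjects = workflow.read_subjects_csv(subjects)
    else:
        subjects = list(subjects)
    if not rounds or not subjects:
        raise InputError("empty input: at least one round and one subject required")

    populations = {s.population for s in subjects}
    if len(populations) != 1:
        raise InputError(f"mixed populations in one evaluation: {sorted(populations)}")
    population = populations.pop()
    if site is None:
        site = subjects[0].country_site or "unknown"

    eligible, screening_tally = _screen(subjects)
    eligible_ids = {s.subject_id for s in eligible}
    usable_rounds = [r for r in rounds if r.subject_id in eligible_ids]

    pairs, ledger = workflow.run_cascade(usable_rounds)
    retained_ids = {p.subject_id for p in pairs}
    retained_subjects = [s for s in eligible if s.subject_id in retained_ids]

    criterion1: "OrderedDict[str, Optional[Criterion1Result]]" = OrderedDict()
    criterion2: "OrderedDict[str, Optional[Criterion2Result]]" = OrderedDict()
    bland: "OrderedDict[str, Optional[BlandAltmanResult]]" = OrderedDict()
    evaluable = len(pairs) >= 2 and len(retained_ids) >= 2
    for arm in ARMS:
        if not evaluable:
            criterion1[arm] = criterion2[arm] = bland[arm] = None
            continue
        errors = [p.error(arm) for p in pairs]
        criterion1[arm] = criteria.criterion1(errors)
        grouped: "OrderedDict[str, list[float]]" = OrderedDict()
        for p in pairs:
            grouped.setdefault(p.subject_id, []).append(p.error(arm))
        criterion2[arm] = criteria.criterion2(
            grouped, constants, table_mode=table_mode
        )
        bland[arm] = agreement.bland_altman(pairs, arm)

    audit = (
        workflow.audit_sampling(pairs, retained_subjects) if retained_subjects else None
    )
    return StudyReport(
        site=site,
        population=population,
        n_subjects=len(retained_ids),
        n_measurements=len(pairs),
        status="ok" if evaluable else "not_evaluable",
        criterion1=criterion1,
        criterion2=criterion2,
        bland_altman=bland,
        ledger=ledger,
        audit=audit,
        screening_exclusions=screening_tally,
    )
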