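"""Accuracy criteria for non-invasive blood-pressure device validation.

Implements the two pass/fail criteria of ISO 81060-2:2018 (and the
AAMI/ESH/ISO universal consensus protocol) for cuff-reference validation
studies:

* **Criterion 1** pools every retained (device − reference) difference and
  requires ``−5 ≤ mean ≤ 5`` mmHg and a sample standard deviation ``≤ 8``
  mmHg.

* **Criterion 2** averages the differences within each subject and bounds
  the between-subject standard deviation of those per-subject means by a
  ceiling that shrinks as the pooled mean error grows.  The ceiling is the
  unique ``s > 0`` at which a normal error distribution with mean ``|μ|``
  and standard deviation ``s`` places 85 % of its probability inside the
  ±10 mmHg envelope:

      Φ((10 − |μ|)/s) − Φ((−10 − |μ|)/s) = 0.85

  The envelope (10 mmHg) and coverage level (0.85) come from the standard
  and are exposed as configuration (:class:`Criterion2Constants`) rather
  than hard-coded.

All standard deviations use the n−1 denominator.  Pass comparisons are
inclusive.  The error sign convention is device − reference: a positive
mean error means the device overestimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "MEAN_ERROR_LIMIT",
    "SD_LIMIT",
    "Criterion2Constants",
    "DEFAULT_CONSTANTS",
    "ErrorSample",
    "Criterion1Result",
    "Criterion2Result",
    "criterion1",
    "criterion2",
    "criterion2_from_summary",
    "max_permissible_sd",
    "table6_grid",
]

#: Criterion-1 bound on the absolute pooled mean error, mmHg (inclusive).
MEAN_ERROR_LIMIT = 5.0
#: Criterion-1 bound on the pooled SD of the errors, mmHg (inclusive).
SD_LIMIT = 8.0

_ARMS = ("SBP", "DBP")


@dataclass(frozen=True)
class Criterion2Constants:
    """Constants defining the criterion-2 permissible-SD function.

    Parameters
    ----------
    tolerance
        Half-width of the acceptable error envelope, mmHg (default 10).
    probability
        Required probability mass inside ``±tolerance`` (default 0.85).
    """

    tolerance: float = 10.0
    probability: float = 0.85

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if not 0.0 < self.probability < 1.0:
            raise ValueError(
                f"probability must lie strictly between 0 and 1, got {self.probability}"
            )


DEFAULT_CONSTANTS = Criterion2Constants()


@dataclass(frozen=True)
class ErrorSample:
    """Signed device − reference differences for one arm (SBP or DBP)."""

    values: tuple[float, ...]
    arm: str = "SBP"

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"arm must be one of {_ARMS}, got {self.arm!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) == 0:
            raise ValueError("an ErrorSample must contain at least one difference")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("all error values must be finite")


@dataclass(frozen=True)
class Criterion1Result:
    mean_error: float
    sd_error: float
    n_measurements: int
    passed: bool


@dataclass(frozen=True)
class Criterion2Result:
    per_subject_mean_errors: tuple[float, ...]
    sd_between_subjects: float
    permissible_sd: float
    mean_error_used: float
    passed: bool

    @property
    def n_subjects(self) -> int:
        return len(self.per_subject_mean_errors)


def _as_values(errors: ErrorSample | Sequence[float] | Iterable[float]) -> np.ndarray:
    if isinstance(errors, ErrorSample):
        values = np.asarray(errors.values, dtype=float)
    else:
        values = np.asarray(list(errors), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("all error values must be finite")
    return values


def criterion1(errors: ErrorSample | Sequence[float]) -> Criterion1Result:
    """Evaluate ISO criterion 1 on pooled device − reference differences.

    Requires at least two values so the sample SD is defined.
    """
    values = _as_values(errors)
    if values.size < 2:
        raise ValueError(
            "criterion 1 needs at least two device-reference differences; "
            f"got {values.size}"
        )
    mean_error = float(values.mean())
    sd_error = float(values.std(ddof=1))
    passed = (-MEAN_ERROR_LIMIT <= mean_error <= MEAN_ERROR_LIMIT) and (
        sd_error <= SD_LIMIT
    )
    return Criterion1Result(mean_error, sd_error, int(values.size), passed)


def max_permissible_sd(
    mean_error: float, constants: Criterion2Constants = DEFAULT_CONSTANTS
) -> float:
    """Maximum permissible between-subject SD for a given pooled mean error.

    Solves ``Φ((Δ−|μ|)/s) − Φ((−Δ−|μ|)/s) = p`` for ``s`` by bracketed
    root-finding (Δ = ``constants.tolerance``, p = ``constants.probability``).
    The root is found to well below 1e−6 mmHg.  Symmetric in the sign of
    ``mean_error`` and strictly decreasing in ``|mean_error|``.
    """
    mu = abs(float(mean_error))
    if not math.isfinite(mu):
        raise ValueError("mean_error must be finite")
    delta, p = constants.tolerance, constants.probability
    if mu >= delta:
        raise ValueError(
            f"|mean_error| = {mu} mmHg is at or beyond the ±{delta} mmHg "
            "tolerance envelope; the permissible SD is undefined there"
        )

    def coverage_gap(s: float) -> float:
        return (norm.cdf((delta - mu) / s) - norm.cdf((-delta - mu) / s)) - p

    # Coverage → 1 as s → 0 (since |μ| < Δ) and → 0 as s → ∞, monotonically.
    return float(brentq(coverage_gap, 1e-9, 100.0 * delta, xtol=1e-9))


def criterion2(
    per_subject_errors: Mapping[object, Sequence[float]],
    constants: Criterion2Constants = DEFAULT_CONSTANTS,
    *,
    table_mode: bool = False,
    min_pairs_per_subject: int = 3,
) -> Criterion2Result:
    """Evaluate ISO criterion 2 on per-subject grouped differences.

    Parameters
    ----------
    per_subject_errors
        Mapping of subject id to that subject's device − reference
        differences for one arm.  Each subject must contribute at least
        ``min_pairs_per_subject`` differences (the exclusion cascade
        guarantees three) and at least two subjects are required.
    table_mode
        When true, reproduce the printed-table workflow: round the pooled
        mean error to the nearest 0.1 mmHg before solving, and round the
        resulting ceiling to 2 decimals before comparison.
    """
    if len(per_subject_errors) < 2:
        raise ValueError("criterion 2 needs at least two subjects")
    means: list[float] = []
    pooled: list[float] = []
    for subject_id, values in per_subject_errors.items():
        arr = _as_values(values)
        if arr.size < min_pairs_per_subject:
            raise ValueError(
                f"subject {subject_id!r} has {arr.size} paired measurements; "
                f"criterion 2 requires at least {min_pairs_per_subject} "
                "(exclusion-cascade violation)"
            )
        means.append(float(arr.mean()))
        pooled.extend(arr.tolist())
    mean_error_used = float(np.mean(pooled))
    sd_between = float(np.std(means, ddof=1))
    if table_mode:
        permissible = round(max_permissible_sd(round(mean_error_used, 1), constants), 2)
    else:
        permissible = max_permissible_sd(mean_error_used, constants)
    return Criterion2Result(
        per_subject_mean_errors=tuple(means),
        sd_between_subjects=sd_between,
        permissible_sd=permissible,
        mean_error_used=mean_error_used,
        passed=sd_between <= permissible,
    )


def criterion2_from_summary(
    mean_error: float,
    sd_between_subjects: float,
    constants: Criterion2Constants = DEFAULT_CONSTANTS,
    *,
    table_mode: bool = False,
) -> tuple[float, bool]:
    """Criterion-2 verdict from published summary statistics.

    Returns ``(permissible_sd, passed)`` for a reported pooled mean error
    and between-subject SD, for checking printed tables without raw data.
    """
    if sd_between_subjects < 0:
        raise ValueError("sd_between_subjects must be non-negative")
    if table_mode:
        permissible = round(max_permissible_sd(round(mean_error, 1), constants), 2)
    else:
        permissible = max_permissible_sd(mean_error, constants)
    return permissible, sd_between_subjects <= permissible


def table6_grid(constants: Criterion2Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Permissible-SD grid for mean errors 0.0–5.0 mmHg in steps of 0.1.

    Returns a DataFrame with rows ``±0 … ±5`` (integer part of the mean
    error) and columns ``0.0 … 0.9`` (fractional part); 51 cells rounded to
    2 decimals, NaN where the mean error would exceed 5.0 mmHg.
    """
    rows = [f"±{d}" for d in range(6)]
    cols = [round(c / 10, 1) for c in range(10)]
    grid = pd.DataFrame(np.nan, index=rows, columns=cols)
    for d in range(6):
        for c in range(10):
            mu = d + c / 10
            if mu > 5.0:
                break
            grid.iloc[d, c] = round(max_permissible_sd(mu, constants), 2)
    return grid
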