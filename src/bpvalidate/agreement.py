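"""Bland-Altman agreement analysis and observer-qualification checks.

Bland-Altman analysis plots each pair's difference (device − reference)
against the pair mean; the bias is the mean difference and the 95 % limits
of agreement are bias ± 1.96·SD of the differences (sample SD, n−1).  The
bias is by construction identical to the criterion-1 mean error computed on
the same pairs.

Observer qualification mirrors the dual-observer training requirement:
over exactly 50 practice measurements, both SBP and DBP inter-observer
differences must be within 5 mmHg on at least 45 and within 10 mmHg on at
least 48 (inclusive tolerances).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .workflow import NurseReading, PairedMeasurement

__all__ = [
    "BlandAltmanResult",
    "ObserverQualification",
    "bland_altman",
    "qualify_observers",
]

#: Normal 97.5 % quantile as conventionally used for limits of agreement.
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    arm: str
    pair_means: tuple[float, ...]
    pair_diffs: tuple[float, ...]
    subject_ids: tuple[str, ...]
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    @property
    def n(self) -> int:
        return len(self.pair_diffs)

    def to_frame(self) -> pd.DataFrame:
        """Point export for plotting: one row per pair."""
        return pd.DataFrame(
            {
                "pair_mean": self.pair_means,
                "pair_diff": self.pair_diffs,
                "subject_id": self.subject_ids,
                "arm": self.arm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None):
        """Render the scatter with bias and limit-of-agreement lines."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(self.pair_means, self.pair_diffs, s=12, alpha=0.6)
        ax.axhline(self.bias, color="black", label=f"bias {self.bias:.1f}")
        for y in (self.loa_low, self.loa_high):
            ax.axhline(y, color="red", linestyle=":")
        ax.set_xlabel(f"mean of device and reference {self.arm} (mmHg)")
        ax.set_ylabel("device − reference (mmHg)")
        ax.legend(loc="upper right")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def bland_altman(
    pairs: Sequence[PairedMeasurement], arm: str = "SBP", *, per_subject: bool = False
) -> BlandAltmanResult:
    """Bland-Altman summary of device vs reference for one arm.

    ``per_subject=True`` first averages each subject's device and reference
    values, yielding subject-level agreement instead of the default
    measurement-level pooling.
    """
    if arm not in ("SBP", "DBP"):
        raise ValueError(f"arm must be 'SBP' or 'DBP', got {arm!r}")
    if per_subject:
        grouped: "OrderedDict[str, list[PairedMeasurement]]" = OrderedDict()
        for p in pairs:
            grouped.setdefault(p.subject_id, []).append(p)
        ids = list(grouped)
        dev = np.array(
            [np.mean([_device(p, arm) for p in g]) for g in grouped.values()]
        )
        ref = np.array(
            [np.mean([_reference(p, arm) for p in g]) for g in grouped.values()]
        )
    else:
        ids = [p.subject_id for p in pairs]
        dev = np.array([_device(p, arm) for p in pairs])
        ref = np.array([_reference(p, arm) for p in pairs])
    if dev.size < 2:
        raise ValueError("Bland-Altman analysis needs at least two pairs")
    diffs = dev - ref
    means = (dev + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        arm=arm,
        pair_means=tuple(float(m) for m in means),
        pair_diffs=tuple(float(d) for d in diffs),
        subject_ids=tuple(ids),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_FACTOR * sd,
        loa_high=bias + LOA_FACTOR * sd,
    )


def _device(p: PairedMeasurement, arm: str) -> float:
    return p.device_sbp if arm == "SBP" else p.device_dbp


def _reference(p: PairedMeasurement, arm: str) -> float:
    return p.reference_sbp if arm == "SBP" else p.reference_dbp


@dataclass(frozen=True)
class ObserverQualification:
    n_practice: int
    n_within_5: int
    n_within_10: int
    passed: bool


def qualify_observers(
    practice: Sequence[tuple[NurseReading, NurseReading]]
    | Sequence[tuple[float, float, float, float]],
) -> ObserverQualification:
    """Inter-rater qualification over exactly 50 practice measurements.

    Accepts either ``(NurseReading, NurseReading)`` pairs or flat
    ``(n1_sbp, n1_dbp, n2_sbp, n2_dbp)`` tuples.  A practice measurement
    counts toward a tolerance only when both the SBP and the DBP
    differences are within it.
    """
    if len(practice) != 50:
        raise ValueError(
            f"observer qualification requires exactly 50 practice measurements, "
            f"got {len(practice)}"
        )
    n5 = n10 = 0
    for entry in practice:
        if len(entry) == 2 and isinstance(entry[0], NurseReading):
            d_sbp = abs(entry[0].sbp - entry[1].sbp)
            d_dbp = abs(entry[0].dbp - entry[1].dbp)
        else:
            n1_sbp, n1_dbp, n2_sbp, n2_dbp = entry
            d_sbp = abs(n1_sbp - n2_sbp)
            d_dbp = abs(n1_dbp - n2_dbp)
        if d_sbp <= 5 and d_dbp <= 5:
            n5 += 1
        if d_sbp <= 10 and d_dbp <= 10:
            n10 += 1
    return ObserverQualification(
        n_practice=50,
        n_within_5=n5,
        n_within_10=n10,
        passed=(n5 >= 45 and n10 >= 48),
    )
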