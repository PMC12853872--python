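"""Anatomical cutoff derivation by the group-mean scan procedure.

The rubric's length cutoffs were derived from cohort data by scanning every
integer candidate value of a metric, splitting the cohort into patients
below (< c) and at-or-above (>= c) the candidate, and computing each group's
mean resection weight and mean ptosis grade. A cutoff is selected where the
scan shows a transition across a landmark resection weight (500 g by
default) together with the at-or-above group sitting in the
moderate-to-severe -> severe ptosis band (~2.5 -> ~3).

For the sternal notch-to-nipple distance a deliberately more lenient rule is
available: because severe ptosis already carries its own rubric point and
SN-N is a ptosis surrogate, the weight landmark for the at-or-above group is
reduced (350 g by default) so the cutoff is not dragged upward by nipple
descent alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import MissingMeasurementError, PatientRecord, select_index_breast

SCAN_METRICS = ("sn_n", "n_imf", "base_width")


@dataclass(frozen=True)
class CutoffScanRow:
    """Group statistics at one integer candidate cutoff.

    Groups partition the cohort as {metric < candidate} vs
    {metric >= candidate}. Means of empty groups are NaN.
    """

    metric: str
    candidate: int
    n_below: int
    n_above: int
    mean_weight_below: float
    mean_weight_above: float
    mean_ptosis_below: float
    mean_ptosis_above: float

    @property
    def both_groups_nonempty(self) -> bool:
        return self.n_below > 0 and self.n_above > 0


@dataclass(frozen=True)
class CutoffSelection:
    metric: str
    selected_cutoff: Optional[int]
    rule_applied: str  # weight_ptosis_transition | lenient_sn_n | no_transition
    scan: tuple[CutoffScanRow, ...]
    rationale: str


def _index_values(
    cohort: Sequence[PatientRecord], metric: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if metric not in SCAN_METRICS:
        raise ValueError(f"metric must be one of {SCAN_METRICS}, got {metric!r}")
    vals, weights, ptosis, offenders = [], [], [], []
    for p in cohort:
        b = select_index_breast(p)
        if (
            getattr(b, metric) is None
            or b.ptosis_grade is None
            or b.resection_weight is None
        ):
            offenders.append(p.patient_id)
            continue
        vals.append(getattr(b, metric))
        weights.append(b.resection_weight)
        ptosis.append(b.ptosis_grade)
    if offenders:
        raise MissingMeasurementError(
            f"cutoff scan on {metric}: records missing {metric}, ptosis grade "
            f"or resection weight: {', '.join(offenders)}"
        )
    return np.asarray(vals), np.asarray(weights), np.asarray(ptosis)


def cutoff_scan(
    cohort: Sequence[PatientRecord], metric: str
) -> list[CutoffScanRow]:
    """Scan integer candidate cutoffs for one metric over a cohort.

    Candidates run over all integers in ``[floor(min)+1, ceil(max)]`` of the
    observed index-breast metric, so both partitions are nonempty somewhere
    in the grid. Group statistics are exact arithmetic means.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    vals, weights, ptosis = _index_values(cohort, metric)

    def gmean(x: np.ndarray) -> float:
        return float(np.mean(x)) if len(x) else math.nan

    rows = []
    for c in range(int(math.floor(vals.min())) + 1, int(math.ceil(vals.max())) + 1):
        below = vals < c
        above = ~below
        rows.append(
            CutoffScanRow(
                metric=metric,
                candidate=c,
                n_below=int(below.sum()),
                n_above=int(above.sum()),
                mean_weight_below=gmean(weights[below]),
                mean_weight_above=gmean(weights[above]),
                mean_ptosis_below=gmean(ptosis[below]),
                mean_ptosis_above=gmean(ptosis[above]),
            )
        )
    return rows


def select_cutoff(
    scan: Sequence[CutoffScanRow],
    *,
    weight_landmark: float = 500.0,
    ptosis_low: float = 2.5,
    ptosis_high: float = 3.0,
    sn_n_leniency: bool = False,
    lenient_landmark: float = 350.0,
) -> CutoffSelection:
    """Select a cutoff from a scan by the weight/ptosis transition rule.

    Default rule: the smallest candidate with both groups nonempty whose
    below-group mean weight is under ``weight_landmark`` and whose
    at-or-above group mean weight reaches it, with the at-or-above group's
    mean ptosis inside the moderate-to-severe -> severe transition band
    ``[ptosis_low, ptosis_high]``. With ``sn_n_leniency`` the at-or-above
    group only needs to reach ``lenient_landmark``.

    When several candidates qualify (a plateau), the smallest wins — the
    lenient reading. If none qualifies, a structured ``no_transition``
    result is returned rather than a silent default.
    """
    scan = list(scan)
    if sum(r.both_groups_nonempty for r in scan) < 2:
        raise ValueError("scan needs >= 2 candidates with both groups nonempty")
    metric = scan[0].metric
    above_landmark = lenient_landmark if sn_n_leniency else weight_landmark
    rule = "lenient_sn_n" if sn_n_leniency else "weight_ptosis_transition"

    for row in scan:
        if not row.both_groups_nonempty:
            continue
        weight_ok = (
            row.mean_weight_below < weight_landmark
            and row.mean_weight_above >= above_landmark
        )
        ptosis_ok = ptosis_low <= row.mean_ptosis_above <= ptosis_high
        if weight_ok and ptosis_ok:
            return CutoffSelection(
                metric=metric,
                selected_cutoff=row.candidate,
                rule_applied=rule,
                scan=tuple(scan),
                rationale=(
                    f"{metric} >= {row.candidate}: mean weight "
                    f"{row.mean_weight_below:.0f} g -> {row.mean_weight_above:.0f} g "
                    f"(landmark {above_landmark:.0f} g), mean ptosis "
                    f"{row.mean_ptosis_below:.2f} -> {row.mean_ptosis_above:.2f} "
                    f"(band {ptosis_low}-{ptosis_high}); smallest qualifying candidate"
                ),
            )
    return CutoffSelection(
        metric=metric,
        selected_cutoff=None,
        rule_applied="no_transition",
        scan=tuple(scan),
        rationale=(
            f"no candidate satisfied the {rule} rule "
            f"(weight landmark {above_landmark:.0f} g, ptosis band "
            f"{ptosis_low}-{ptosis_high})"
        ),
    )


def derive_all_cutoffs(
    cohort: Sequence[PatientRecord],
    *,
    weight_landmark: float = 500.0,
    ptosis_low: float = 2.5,
    ptosis_high: float = 3.0,
    lenient_landmark: float = 350.0,
) -> dict[str, CutoffSelection]:
    """Run the scan+selection for all three length metrics.

    SN-N uses the lenient rule; N-IMF and base width use the default rule.
    """
    out = {}
    for metric in SCAN_METRICS:
        scan = cutoff_scan(cohort, metric)
        out[metric] = select_cutoff(
            scan,
            weight_landmark=weight_landmark,
            ptosis_low=ptosis_low,
            ptosis_high=ptosis_high,
            sn_n_leniency=(metric == "sn_n"),
            lenient_landmark=lenient_landmark,
        )
    return out
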