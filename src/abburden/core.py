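"""Domain types and the anatomical breast burden (ABB) scoring rubric.

The ABB score is a 0-6 point clinical scoring rule for quantifying the
functional burden of breast hypertrophy. Four binary anatomical criteria
(sternal notch-to-nipple distance, nipple-to-inframammary-fold distance,
base width, and Regnault ptosis grade) contribute one point each; a
patient-reported symptom and a physical examination finding contribute one
point each. Scores of 0-2 are categorized as mild burden, 3-6 as
moderate-to-severe burden.

Scoring is per patient, not per breast: for bilateral cases the breast with
the heavier resection weight (the "index breast") carries the anatomical
assessment, on the rationale that averaging the two breasts underestimates
the burden experienced by an asymmetric patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNSPECIFIED = "unspecified"


class BurdenCategory(str, Enum):
    MILD = "mild"                              # ABB 0-2
    MODERATE_TO_SEVERE = "moderate_to_severe"  # ABB 3-6


#: Valid Regnault ptosis grades. 2.5 encodes a documented "Grade 2-3",
#: interpolated for analysis; it is not part of the formal Regnault system.
PTOSIS_GRADES = (0.0, 1.0, 2.0, 2.5, 3.0)

#: Plausibility ranges (cm) used for soft validation warnings only.
PLAUSIBLE_RANGES = {
    "sn_n": (22.5, 40.0),
    "n_imf": (9.0, 22.0),
    "base_width": (12.0, 24.0),
}

ANATOMICAL_FIELDS = ("sn_n", "n_imf", "base_width", "ptosis_grade")


class MissingMeasurementError(ValueError):
    """A required anatomical metric or resection weight is absent."""


class ScoringError(ValueError):
    """A patient cannot be scored under the requested assumptions."""


class ImplausibleValueWarning(UserWarning):
    """A measurement falls outside the plausible clinical range."""


@dataclass(frozen=True)
class BreastMeasurement:
    """One breast's anatomical metrics, ptosis grade, and resection weight.

    Lengths are centimetres; resection weight is grams. Any metric may be
    ``None`` (e.g. undocumented in a chart), but scoring operations raise
    :class:`MissingMeasurementError` when they need an absent value.
    """

    side: Side = Side.UNSPECIFIED
    sn_n: Optional[float] = None
    n_imf: Optional[float] = None
    base_width: Optional[float] = None
    ptosis_grade: Optional[float] = None
    resection_weight: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", Side(self.side))
        for name in ("sn_n", "n_imf", "base_width"):
            v = getattr(self, name)
            if v is None:
                continue
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
            lo, hi = PLAUSIBLE_RANGES[name]
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v} cm outside plausible range [{lo}, {hi}]",
                    ImplausibleValueWarning,
                    stacklevel=2,
                )
        if self.ptosis_grade is not None and self.ptosis_grade not in PTOSIS_GRADES:
            raise ValueError(
                f"ptosis_grade must be one of {PTOSIS_GRADES}, got {self.ptosis_grade}"
            )
        if self.resection_weight is not None and not self.resection_weight > 0:
            raise ValueError(
                f"resection_weight must be positive, got {self.resection_weight}"
            )

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingMeasurementError(
                f"breast ({self.side.value}) is missing: {', '.join(missing)}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus one or two breasts and symptom/finding flags.

    Height is metres, weight kilograms. ``has_symptom`` / ``has_finding`` are
    three-valued: True, False, or ``None`` (unknown — e.g. not documented in
    a retrospective chart).
    """

    patient_id: str
    age: float
    height: float
    weight: float
    breasts: tuple[BreastMeasurement, ...]
    has_symptom: Optional[bool] = None
    has_finding: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        breasts = tuple(self.breasts)
        object.__setattr__(self, "breasts", breasts)
        if not 1 <= len(breasts) <= 2:
            raise ValueError(f"expected 1 or 2 breasts, got {len(breasts)}")
        sides = [b.side for b in breasts if b.side is not Side.UNSPECIFIED]
        if len(sides) != len(set(sides)):
            raise ValueError("at most one breast per side")

    @property
    def bmi(self) -> float:
        """Body-mass index kg/m^2, always derived from height and weight."""
        return self.weight / self.height**2


@dataclass(frozen=True)
class ABBCutoffs:
    """Rubric thresholds and point weights.

    Anatomical criteria use inclusive ">=" comparisons ("16 cm or greater");
    the ptosis criterion is strict equality with the qualifying grade, so a
    documented "Grade 2-3" (2.5) scores zero under the default grade 3.
    """

    sn_n_min: float = 26.0
    n_imf_min: float = 14.0
    bw_min: float = 16.0
    ptosis_qualifying_grade: float = 3.0
    symptom_points: int = 1
    finding_points: int = 1

    def __post_init__(self) -> None:
        for name in ("sn_n_min", "n_imf_min", "bw_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.symptom_points < 0 or self.finding_points < 0:
            raise ValueError("point weights must be >= 0")

    @property
    def max_score(self) -> int:
        return 4 + self.symptom_points + self.finding_points


@dataclass(frozen=True)
class AnatomicalBreakdown:
    """Per-criterion indicator points for one breast."""

    sn_n: int
    n_imf: int
    base_width: int
    ptosis: int

    @property
    def total(self) -> int:
        return self.sn_n + self.n_imf + self.base_width + self.ptosis


@dataclass(frozen=True)
class ABBResult:
    patient_id: str
    index_side: Side
    breakdown: AnatomicalBreakdown
    symptom_point: int
    finding_point: int

    @property
    def anatomical_points(self) -> int:
        return self.breakdown.total

    @property
    def abb_score(self) -> int:
        return self.anatomical_points + self.symptom_point + self.finding_point

    @property
    def category(self) -> BurdenCategory:
        return (
            BurdenCategory.MILD
            if self.abb_score <= 2
            else BurdenCategory.MODERATE_TO_SEVERE
        )


def anatomical_points(
    b: BreastMeasurement, cutoffs: ABBCutoffs = ABBCutoffs()
) -> AnatomicalBreakdown:
    """Score one breast on the four binary anatomical criteria.

    Each length criterion awards a point when the measurement meets or
    exceeds its cutoff; the ptosis criterion awards a point only at the
    qualifying grade (severe, grade 3, by default).

    Raises
    ------
    MissingMeasurementError
        If any of the four metrics is absent, naming the missing field(s).
    """
    b.require(*ANATOMICAL_FIELDS)
    return AnatomicalBreakdown(
        sn_n=int(b.sn_n >= cutoffs.sn_n_min),
        n_imf=int(b.n_imf >= cutoffs.n_imf_min),
        base_width=int(b.base_width >= cutoffs.bw_min),
        ptosis=int(b.ptosis_grade == cutoffs.ptosis_qualifying_grade),
    )


def select_index_breast(p: PatientRecord) -> BreastMeasurement:
    """Return the breast carrying the patient's burden assessment.

    Unilateral patients contribute their single breast. Bilateral patients
    contribute the breast with the heavier resection weight; both weights
    must be documented. Exactly equal weights (never observed in the source
    cohort) break ties deterministically: left, then right, then input order.
    """
    if len(p.breasts) == 1:
        return p.breasts[0]
    missing = [b.side.value for b in p.breasts if b.resection_weight is None]
    if missing:
        raise MissingMeasurementError(
            f"patient {p.patient_id}: bilateral record missing resection "
            f"weight on side(s): {', '.join(missing)}"
        )
    side_rank = {Side.LEFT: 0, Side.RIGHT: 1, Side.UNSPECIFIED: 2}
    best = min(
        enumerate(p.breasts),
        key=lambda ib: (-ib[1].resection_weight, side_rank[ib[1].side], ib[0]),
    )
    return best[1]


def _domain_point(
    flag: Optional[bool], assume: bool, weight: int, label: str, patient_id: str
) -> int:
    if flag is True:
        return weight
    if flag is False:
        return 0
    if assume:
        return weight
    raise ScoringError(
        f"patient {patient_id}: {label} status unknown and assumption disabled"
    )


def abb_score(
    p: PatientRecord,
    cutoffs: ABBCutoffs = ABBCutoffs(),
    *,
    assume_symptom: bool = True,
    assume_finding: bool = True,
) -> ABBResult:
    """Compute a patient's ABB score (0-6 at default weights).

    The symptom and finding domains each award their point when the flag is
    True, or when it is unknown and the corresponding ``assume_*`` flag is
    enabled — the default, mirroring a cohort restricted to functional
    reductions where at least one symptom and one finding are presumed.
    An explicit False always overrides the assumption.
    """
    index = select_index_breast(p)
    breakdown = anatomical_points(index, cutoffs)
    return ABBResult(
        patient_id=p.patient_id,
        index_side=index.side,
        breakdown=breakdown,
        symptom_point=_domain_point(
            p.has_symptom, assume_symptom, cutoffs.symptom_points, "symptom", p.patient_id
        ),
        finding_point=_domain_point(
            p.has_finding, assume_finding, cutoffs.finding_points, "physical finding", p.patient_id
        ),
    )
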