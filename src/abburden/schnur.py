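"""DuBois body-surface area, Schnur sliding-scale lookup, and eligibility.

The Schnur sliding scale maps a patient's body surface area (BSA) to a
minimum per-breast resection weight; many US insurers treat meeting that
threshold as the eligibility criterion for covered reduction mammaplasty.
This module computes BSA from height and weight with the DuBois formula,
resolves a BSA to a threshold on the scale's regular 0.05 m^2 grid, and
reports the "mismatch weight" (actual resection minus threshold) whose sign
determines eligibility.

The sliding-scale entries ship as package data (``data/schnur_table.csv``)
rather than constants, because the scale is an external published table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import MissingMeasurementError, PatientRecord, select_index_breast

logger = logging.getLogger(__name__)


def dubois_bsa(height_m: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois formula.

    BSA = 0.007184 * height_cm^0.725 * weight_kg^0.425; strictly increasing
    in both arguments.
    """
    if not height_m > 0 or not weight_kg > 0:
        raise ValueError(
            f"height and weight must be positive, got {height_m} m, {weight_kg} kg"
        )
    return 0.007184 * (height_m * 100.0) ** 0.725 * weight_kg**0.425


class GridPolicy(str, Enum):
    """How a non-grid BSA resolves to a sliding-scale row."""

    NEAREST = "nearest"  # half rounds up
    FLOOR = "floor"
    CEIL = "ceil"
    LINEAR = "linear_interpolation"


@dataclass(frozen=True)
class SchnurTable:
    """Monotone BSA -> per-breast threshold-weight lookup on a regular grid."""

    bsa: np.ndarray
    threshold: np.ndarray
    policy: GridPolicy = GridPolicy.NEAREST

    def __post_init__(self) -> None:
        bsa = np.asarray(self.bsa, dtype=float)
        thr = np.asarray(self.threshold, dtype=float)
        object.__setattr__(self, "bsa", bsa)
        object.__setattr__(self, "threshold", thr)
        object.__setattr__(self, "policy", GridPolicy(self.policy))
        if bsa.ndim != 1 or bsa.shape != thr.shape or len(bsa) < 2:
            raise ValueError("table needs matching 1-D bsa/threshold arrays, >= 2 rows")
        if not np.all(np.diff(bsa) > 0):
            raise ValueError("BSA grid must be strictly increasing")
        steps = np.diff(bsa)
        if not np.allclose(steps, steps[0], atol=1e-9):
            raise ValueError("BSA grid must be regularly spaced")
        if not np.all(np.diff(thr) > 0):
            raise ValueError("thresholds must be strictly increasing with BSA")

    @property
    def spacing(self) -> float:
        return float(self.bsa[1] - self.bsa[0])

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], policy: GridPolicy = GridPolicy.NEAREST
    ) -> "SchnurTable":
        """Load a two-column ``bsa_m2,threshold_g`` CSV with strict schema."""
        import pandas as pd

        df = pd.read_csv(path)
        expected = ["bsa_m2", "threshold_g"]
        if list(df.columns) != expected:
            raise ValueError(
                f"Schnur table schema mismatch: expected columns {expected}, "
                f"got {list(df.columns)}"
            )
        if df.isna().any().any():
            raise ValueError("Schnur table contains missing values")
        return cls(df["bsa_m2"].to_numpy(), df["threshold_g"].to_numpy(), policy)

    @classmethod
    def default(cls, policy: GridPolicy = GridPolicy.NEAREST) -> "SchnurTable":
        """The packaged sliding-scale table (BSA 1.35-2.55 m^2, 0.05 grid)."""
        with resources.as_file(
            resources.files("abburden.data").joinpath("schnur_table.csv")
        ) as p:
            return cls.from_csv(p, policy)


def schnur_threshold(
    bsa: float, table: SchnurTable, policy: Optional[GridPolicy] = None
) -> tuple[float, float]:
    """Resolve a BSA to ``(matched_grid_bsa, threshold_g)``.

    The grid policy (nearest with half-up rounding by default, or
    floor/ceil/linear interpolation) is configurable because the matching
    convention used in practice is not standardized. The mapping is monotone
    non-decreasing in BSA under every policy.
    """
    policy = table.policy if policy is None else GridPolicy(policy)
    grid, thr, sp = table.bsa, table.threshold, table.spacing
    lo, hi = float(grid[0]), float(grid[-1])

    def _range_error() -> ValueError:
        return ValueError(
            f"BSA {bsa:.3f} m^2 outside the resolvable range "
            f"[{lo:.2f}, {hi:.2f}] (policy={policy.value})"
        )

    if policy is GridPolicy.NEAREST:
        if not (lo - sp / 2 <= bsa <= hi):
            raise _range_error()
        idx = int(np.floor((bsa - lo) / sp + 0.5 + 1e-9))  # half rounds up
        idx = min(idx, len(grid) - 1)
        return float(grid[idx]), float(thr[idx])
    if policy is GridPolicy.FLOOR:
        if not (lo <= bsa <= hi):
            raise _range_error()
        idx = min(int(np.floor((bsa - lo) / sp + 1e-12)), len(grid) - 1)
        return float(grid[idx]), float(thr[idx])
    if policy is GridPolicy.CEIL:
        if not (lo <= bsa <= hi):
            raise _range_error()
        idx = max(int(np.ceil((bsa - lo) / sp - 1e-12)), 0)
        return float(grid[idx]), float(thr[idx])
    # linear interpolation between bracketing rows
    if not (lo <= bsa <= hi):
        raise _range_error()
    return float(bsa), float(np.interp(bsa, grid, thr))


@dataclass(frozen=True)
class SchnurAssessment:
    """Per-patient Schnur eligibility result.

    ``mismatch = actual_resection - threshold``; a non-negative mismatch
    means the patient met the threshold (eligible). The exact-zero boundary
    counts as eligible, since the threshold is framed as a minimum.
    """

    patient_id: str
    bsa: float
    matched_grid_bsa: float
    threshold: float
    actual_resection: float
    policy: GridPolicy

    @property
    def mismatch(self) -> float:
        return self.actual_resection - self.threshold

    @property
    def eligible(self) -> bool:
        return self.mismatch >= 0


def assess_schnur(
    p: PatientRecord,
    table: SchnurTable,
    *,
    resection: str = "index",
) -> SchnurAssessment:
    """Assess one patient's Schnur eligibility.

    ``resection`` selects which weight faces the threshold: ``"index"``
    (the heavier breast, consistent with ABB scoring — the default) or
    ``"average"`` (mean over breasts, provided for sensitivity analysis;
    averaging understates the burden of asymmetric patients).
    """
    if resection == "index":
        breast = select_index_breast(p)
        if breast.resection_weight is None:
            raise MissingMeasurementError(
                f"patient {p.patient_id}: index breast has no resection weight"
            )
        actual = float(breast.resection_weight)
    elif resection == "average":
        weights = [b.resection_weight for b in p.breasts]
        if any(w is None for w in weights):
            raise MissingMeasurementError(
                f"patient {p.patient_id}: resection weight missing for averaging"
            )
        actual = float(np.mean(weights))
    else:
        raise ValueError(f"resection must be 'index' or 'average', got {resection!r}")

    bsa = dubois_bsa(p.height, p.weight)
    matched, threshold = schnur_threshold(bsa, table)
    if actual == threshold:
        logger.info(
            "patient %s: resection exactly equals the Schnur threshold "
            "(%.0f g); counted as eligible",
            p.patient_id,
            threshold,
        )
    return SchnurAssessment(
        patient_id=p.patient_id,
        bsa=bsa,
        matched_grid_bsa=matched,
        threshold=threshold,
        actual_resection=actual,
        policy=table.policy,
    )
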