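"""Cohort-level comparison of ABB categorization and Schnur eligibility.

The comparison treats moderate-to-severe ABB (score 3-6) as the reference
condition ("true burden") and Schnur eligibility as the test under
evaluation, yielding a fourfold table with sensitivity (fraction of
high-burden patients the sliding scale covers) and specificity (fraction of
mild-burden patients it correctly denies). Spearman rank correlations relate
each model's output to the anatomical measurements, resection weight, BSA,
BMI, and mismatch weight; stratified summaries break the cohort down by
individual ABB score or by the category x eligibility fourfold cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ABBCutoffs,
    ABBResult,
    BurdenCategory,
    PatientRecord,
    abb_score,
    select_index_breast,
)
from .schnur import SchnurAssessment, SchnurTable, assess_schnur

#: Variables correlated against each target, in reporting order.
PANEL_VARIABLES = (
    "ptosis_grade",
    "base_width",
    "sn_n",
    "n_imf",
    "resection_weight",
    "bsa",
    "bmi",
    "mismatch",
)

#: Variables summarized per stratum, in reporting order.
STRATUM_VARIABLES = ("bsa", "bmi", "resection_weight", "mismatch", "schnur_threshold")


def evaluate_cohort(
    cohort: Sequence[PatientRecord],
    cutoffs: ABBCutoffs = ABBCutoffs(),
    table: Optional[SchnurTable] = None,
    *,
    assume_symptom: bool = True,
    assume_finding: bool = True,
) -> pd.DataFrame:
    """Score every patient under both models into one tidy DataFrame.

    One row per patient: demographics (age, bmi, bsa), index-breast metrics,
    ABB score/category, Schnur threshold, actual resection, mismatch and
    eligibility. This frame is the input to :func:`concordance`,
    :func:`spearman_panel` and :func:`stratify`.
    """
    if table is None:
        table = SchnurTable.default()
    rows = []
    for p in cohort:
        res = abb_score(
            p, cutoffs, assume_symptom=assume_symptom, assume_finding=assume_finding
        )
        sa = assess_schnur(p, table)
        b = select_index_breast(p)
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "bmi": p.bmi,
                "bsa": sa.bsa,
                "sn_n": b.sn_n,
                "n_imf": b.n_imf,
                "base_width": b.base_width,
                "ptosis_grade": b.ptosis_grade,
                "resection_weight": sa.actual_resection,
                "abb_score": res.abb_score,
                "anatomical_points": res.anatomical_points,
                "category": res.category.value,
                "schnur_threshold": sa.threshold,
                "mismatch": sa.mismatch,
                "eligible": sa.eligible,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceTable:
    """Fourfold counts: condition = moderate-to-severe ABB, test = eligible.

    Sensitivity and specificity are exact fractions; NaN flags a degenerate
    margin (no positives or no negatives).
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else math.nan

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else math.nan

    def as_dict(self, *, ndigits: int = 1) -> dict:
        """Counts plus percentages rounded for display (exact values kept)."""

        def pct(x: float) -> Optional[float]:
            return None if math.isnan(x) else round(100 * x, ndigits)

        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "n": self.n,
            "sensitivity": None if math.isnan(self.sensitivity) else self.sensitivity,
            "specificity": None if math.isnan(self.specificity) else self.specificity,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
        }


def concordance(scored: pd.DataFrame) -> ConcordanceTable:
    """Fourfold table from an evaluated cohort frame."""
    required = {"category", "eligible"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored cohort missing columns: {sorted(missing)}")
    if scored[["category", "eligible"]].isna().any().any():
        bad = scored.loc[
            scored[["category", "eligible"]].isna().any(axis=1), "patient_id"
        ].tolist()
        raise ValueError(f"unscored patients: {bad}")
    pos = scored["category"] == BurdenCategory.MODERATE_TO_SEVERE.value
    elig = scored["eligible"].astype(bool)
    return ConcordanceTable(
        tp=int((pos & elig).sum()),
        fn=int((pos & ~elig).sum()),
        fp=int((~pos & elig).sum()),
        tn=int((~pos & ~elig).sum()),
    )


def spearman_panel(scored: pd.DataFrame, target: str) -> pd.DataFrame:
    """Spearman correlations of ``target`` with the standard variable panel.

    ``target`` is ``"abb_score"`` or ``"schnur_threshold"``. Ties get
    average ranks; p-values are two-tailed via the t approximation on n-2
    degrees of freedom (scipy's default). A constant variable yields NaN
    rho, flagged in the ``defined`` column.
    """
    if target not in ("abb_score", "schnur_threshold"):
        raise ValueError(f"target must be abb_score or schnur_threshold, got {target!r}")
    rows = []
    for var in PANEL_VARIABLES:
        pair = scored[[target, var]].dropna()
        n = len(pair)
        if n < 4:
            raise ValueError(f"need >= 4 complete pairs for {var}, got {n}")
        x, y = pair[target].to_numpy(float), pair[var].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = math.nan, math.nan
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append(
            {
                "target": target,
                "variable": var,
                "spearman_rho": rho,
                "p_value": p,
                "n": n,
                "defined": not math.isnan(rho),
            }
        )
    return pd.DataFrame(rows)


def _summarize(group: pd.DataFrame) -> dict:
    out: dict = {"n": len(group)}
    for var in STRATUM_VARIABLES:
        x = group[var].dropna()
        out[f"{var}_mean"] = float(x.mean()) if len(x) else math.nan
        out[f"{var}_min"] = float(x.min()) if len(x) else math.nan
        out[f"{var}_max"] = float(x.max()) if len(x) else math.nan
        # sample (n-1) SD; undefined for n < 2
        out[f"{var}_sd"] = float(x.std(ddof=1)) if len(x) > 1 else math.nan
    met = int(group["eligible"].astype(bool).sum()) if len(group) else 0
    out["met_schnur_n"] = met
    out["not_met_schnur_n"] = len(group) - met
    out["met_schnur_pct"] = 100 * met / len(group) if len(group) else math.nan
    out["not_met_schnur_pct"] = (
        100 * (len(group) - met) / len(group) if len(group) else math.nan
    )
    return out


def stratify(scored: pd.DataFrame, scheme: str = "by_score") -> pd.DataFrame:
    """Stratified summary of BSA, BMI, weights and eligibility.

    ``scheme="by_score"`` yields one row per observed ABB score (0-6);
    ``scheme="by_category_x_eligibility"`` yields the four fourfold cells
    (true/false positives/negatives). Empty strata are omitted for scores
    never observed but the four fourfold cells always appear, with n=0 and
    NaN statistics where empty.
    """
    if scheme == "by_score":
        rows = []
        for score, grp in scored.groupby("abb_score", sort=True):
            rows.append({"stratum": f"abb_{int(score)}", **_summarize(grp)})
        return pd.DataFrame(rows)
    if scheme == "by_category_x_eligibility":
        pos = scored["category"] == BurdenCategory.MODERATE_TO_SEVERE.value
        elig = scored["eligible"].astype(bool)
        cells = {
            "true_positive": pos & elig,
            "false_negative": pos & ~elig,
            "false_positive": ~pos & elig,
            "true_negative": ~pos & ~elig,
        }
        return pd.DataFrame(
            [{"stratum": name, **_summarize(scored[mask])} for name, mask in cells.items()]
        )
    raise ValueError(
        f"scheme must be by_score or by_category_x_eligibility, got {scheme!r}"
    )
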