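"""Concordance fourfold, Spearman panels, and stratified summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abburden import (
    ConcordanceTable,
    concordance,
    evaluate_cohort,
    spearman_panel,
    stratify,
)
from abburden.analysis import PANEL_VARIABLES


def spearman_oracle(x, y):
    """Brute-force oracle: average ranks, then Pearson on the ranks."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def scored_frame(cells):
    """Synthesize an evaluated-cohort frame with given fourfold cell sizes.

    cells = (tp, fn, fp, tn); filler values keep all panel columns present.
    """
    tp, fn, fp, tn = cells
    rows = []
    for i, (cat, elig, n) in enumerate(
        [
            ("moderate_to_severe", True, tp),
            ("moderate_to_severe", False, fn),
            ("mild", True, fp),
            ("mild", False, tn),
        ]
    ):
        for j in range(n):
            rows.append(
                {
                    "patient_id": f"c{i}_{j}",
                    "age": 40.0,
                    "bmi": 28.0,
                    "bsa": 1.8,
                    "sn_n": 30.0,
                    "n_imf": 14.0,
                    "base_width": 16.0,
                    "ptosis_grade": 3.0,
                    "resection_weight": 450.0,
                    "abb_score": 4 if cat == "moderate_to_severe" else 2,
                    "category": cat,
                    "schnur_threshold": 441.0,
                    "mismatch": 9.0 if elig else -9.0,
                    "eligible": elig,
                }
            )
    return pd.DataFrame(rows)


class TestConcordance:
    def test_reported_fourfold_reproduces_sensitivity_and_specificity(self):
        ct = ConcordanceTable(tp=29, fn=32, fp=8, tn=16)
        assert ct.n == 85
        assert ct.sensitivity == pytest.approx(29 / 61)
        assert ct.specificity == pytest.approx(16 / 24)
        d = ct.as_dict()
        assert d["sensitivity_pct"] == 47.5
        assert d["specificity_pct"] == 66.7

    def test_counts_extracted_from_scored_frame(self):
        ct = concordance(scored_frame((29, 32, 8, 16)))
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (29, 32, 8, 16)

    def test_degenerate_margin_flags_undefined(self):
        ct = concordance(scored_frame((10, 0, 0, 0)))
        assert ct.sensitivity == 1.0
        assert math.isnan(ct.specificity)
        assert ct.as_dict()["specificity_pct"] is None

    def test_matches_per_patient_enumeration_on_random_cohorts(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cells = tuple(int(x) for x in rng.integers(0, 15, size=4))
            if sum(cells) == 0:
                continue
            frame = scored_frame(cells).sample(frac=1, random_state=1)
            ct = concordance(frame)
            # oracle: enumerate each patient into its cell
            counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
            for _, r in frame.iterrows():
                pos = r["category"] == "moderate_to_severe"
                counts[
                    ("tp" if r["eligible"] else "fn") if pos
                    else ("fp" if r["eligible"] else "tn")
                ] += 1
            assert (ct.tp, ct.fn, ct.fp, ct.tn) == (
                counts["tp"], counts["fn"], counts["fp"], counts["tn"]
            )

    def test_unscored_patient_is_a_hard_error(self):
        frame = scored_frame((2, 2, 2, 2))
        frame["eligible"] = frame["eligible"].astype(object)
        frame.loc[0, "eligible"] = None
        with pytest.raises(ValueError, match="unscored"):
            concordance(frame)


class TestSpearmanPanel:
    def test_perfect_monotone_sequences(self):
        frame = scored_frame((4, 0, 0, 4))
        frame["abb_score"] = np.arange(8)
        frame["bsa"] = np.linspace(1.5, 2.3, 8)       # increasing
        frame["bmi"] = np.linspace(40, 20, 8)          # decreasing
        panel = spearman_panel(frame, "abb_score").set_index("variable")
        assert panel.loc["bsa", "spearman_rho"] == pytest.approx(1.0)
        assert panel.loc["bmi", "spearman_rho"] == pytest.approx(-1.0)

    def test_tied_sample_matches_brute_force_oracle(self):
        frame = scored_frame((8, 0, 0, 0))
        frame["abb_score"] = [3, 3, 4, 4, 5, 5, 6, 6]       # planted ties
        frame["resection_weight"] = [200, 300, 300, 400, 500, 500, 700, 900]
        panel = spearman_panel(frame, "abb_score").set_index("variable")
        expected = spearman_oracle(frame["abb_score"], frame["resection_weight"])
        assert panel.loc["resection_weight", "spearman_rho"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_variable_flagged_undefined(self):
        frame = scored_frame((5, 0, 0, 3))
        frame["abb_score"] = np.arange(8)
        # ptosis_grade is constant in the synthesized frame
        panel = spearman_panel(frame, "abb_score").set_index("variable")
        assert math.isnan(panel.loc["ptosis_grade", "spearman_rho"])
        assert not panel.loc["ptosis_grade", "defined"]

    def test_panel_covers_all_variables_with_two_tailed_t_pvalues(self, default_cohort):
        scored = evaluate_cohort(default_cohort)
        panel = spearman_panel(scored, "schnur_threshold")
        assert list(panel["variable"]) == list(PANEL_VARIABLES)
        # independent p-value check via the t approximation on n-2 dof
        row = panel.set_index("variable").loc["bsa"]
        n, rho = row["n"], row["spearman_rho"]
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert row["p_value"] == pytest.approx(p, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman_panel(scored_frame((2, 1, 0, 0)), "abb_score")


class TestStratify:
    def test_by_score_percentages_from_counts(self):
        # 16 patients at score 6, 7 of them ineligible -> 43.75% "did not meet"
        frame = scored_frame((9, 7, 0, 0))
        frame["abb_score"] = 6
        strata = stratify(frame, "by_score").set_index("stratum")
        row = strata.loc["abb_6"]
        assert row["n"] == 16
        assert row["not_met_schnur_n"] == 7
        assert row["not_met_schnur_pct"] == pytest.approx(100 * 7 / 16)
        assert round(row["not_met_schnur_pct"]) == 44

    def test_single_patient_stratum_sd_undefined(self):
        frame = scored_frame((1, 0, 0, 0))
        strata = stratify(frame, "by_score").set_index("stratum")
        row = strata.loc["abb_4"]
        assert row["bsa_mean"] == row["bsa_min"] == row["bsa_max"]
        assert math.isnan(row["bsa_sd"])

    def test_fourfold_cells_always_emitted_even_when_empty(self):
        frame = scored_frame((3, 0, 0, 2))
        strata = stratify(frame, "by_category_x_eligibility").set_index("stratum")
        assert set(strata.index) == {
            "true_positive", "false_negative", "false_positive", "true_negative"
        }
        assert strata.loc["false_negative", "n"] == 0
        assert math.isnan(strata.loc["false_negative", "bsa_mean"])

    def test_mismatch_mean_linearity_within_each_stratum(self, default_cohort):
        scored = evaluate_cohort(default_cohort)
        strata = stratify(scored, "by_score")
        for _, row in strata.iterrows():
            if row["n"] == 0:
                continue
            assert row["mismatch_mean"] == pytest.approx(
                row["resection_weight_mean"] - row["schnur_threshold_mean"], abs=1e-9
            )
        assert strata["n"].sum() == len(scored)

    def test_stratum_internal_order_min_mean_max(self, default_cohort):
        scored = evaluate_cohort(default_cohort)
        for scheme in ("by_score", "by_category_x_eligibility"):
            for _, row in stratify(scored, scheme).iterrows():
                if row["n"] == 0:
                    continue
                for var in ("bsa", "bmi", "resection_weight"):
                    assert row[f"{var}_min"] <= row[f"{var}_mean"] <= row[f"{var}_max"]
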