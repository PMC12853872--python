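"""Cohort CSV reading/writing, run configuration, and the report bundle.

Cohort interchange format: one CSV row per patient with fixed units
(lengths cm, resection weights g, height m, body weight kg):

    patient_id, age, height_m, weight_kg,
    l_sn_n, l_n_imf, l_bw, l_ptosis, l_resection_g,
    r_sn_n, r_n_imf, r_bw, r_ptosis, r_resection_g,
    has_symptom, has_finding

Any side may be entirely blank (unilateral patients). Ptosis accepts the
numeric grades 0/1/2/2.5/3 and the textual chart form ``2-3``, which maps
to the interpolated 2.5. Blank symptom/finding cells mean "unknown" and are
resolved by the scoring assumptions, not here.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .analysis import concordance, evaluate_cohort, spearman_panel, stratify
from .core import ABBCutoffs, BreastMeasurement, PatientRecord, Side
from .cutoffs import derive_all_cutoffs
from .schnur import GridPolicy, SchnurTable

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "height_m",
    "weight_kg",
    "l_sn_n",
    "l_n_imf",
    "l_bw",
    "l_ptosis",
    "l_resection_g",
    "r_sn_n",
    "r_n_imf",
    "r_bw",
    "r_ptosis",
    "r_resection_g",
    "has_symptom",
    "has_finding",
]

_SIDE_PREFIX = {"l": Side.LEFT, "r": Side.RIGHT}


class CohortSchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


@dataclass
class ValidationReport:
    """Row-level accounting: accepted + rejected = input rows."""

    n_input: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row no., reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def parse_ptosis(text: str) -> Optional[float]:
    """Parse a ptosis cell; chart-style ``2-3`` becomes the interpolated 2.5."""
    text = text.strip()
    if not text:
        return None
    if text == "2-3":
        return 2.5
    return float(text)


def _parse_flag(text: str) -> Optional[bool]:
    text = text.strip().lower()
    if not text:
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean flag {text!r}")


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    return float(text) if text else None


def _row_to_record(row: dict[str, str]) -> PatientRecord:
    height = float(row["height_m"])
    if height > 3.0:
        warnings.warn(
            f"patient {row['patient_id']}: height {height} m is implausible "
            "(centimetres entered as metres?)",
            UserWarning,
            stacklevel=3,
        )
    breasts = []
    for prefix, side in _SIDE_PREFIX.items():
        fields = {
            "sn_n": _opt_float(row[f"{prefix}_sn_n"]),
            "n_imf": _opt_float(row[f"{prefix}_n_imf"]),
            "base_width": _opt_float(row[f"{prefix}_bw"]),
            "ptosis_grade": parse_ptosis(row[f"{prefix}_ptosis"]),
            "resection_weight": _opt_float(row[f"{prefix}_resection_g"]),
        }
        if any(v is not None for v in fields.values()):
            breasts.append(BreastMeasurement(side=side, **fields))
    return PatientRecord(
        patient_id=row["patient_id"],
        age=float(row["age"]),
        height=height,
        weight=float(row["weight_kg"]),
        breasts=tuple(breasts),
        has_symptom=_parse_flag(row["has_symptom"]),
        has_finding=_parse_flag(row["has_finding"]),
    )


def read_cohort(
    path: Union[str, Path]
) -> tuple[list[PatientRecord], ValidationReport]:
    """Read a cohort CSV into typed records plus a validation report.

    The header must match the documented schema exactly (hard error with a
    column diff otherwise). Rows failing type or invariant validation are
    rejected and itemized in the report — never silently dropped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file")
        if list(reader.fieldnames) != COHORT_COLUMNS:
            missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
            extra = [c for c in reader.fieldnames if c not in COHORT_COLUMNS]
            raise CohortSchemaError(
                f"{path}: cohort schema mismatch; missing columns {missing}, "
                f"unexpected columns {extra}"
            )
        records: list[PatientRecord] = []
        report = ValidationReport()
        for lineno, row in enumerate(reader, start=2):
            report.n_input += 1
            try:
                records.append(_row_to_record(row))
                report.n_accepted += 1
            except (ValueError, KeyError) as exc:
                report.rejected.append((lineno, str(exc)))
    if report.n_input == 0:
        raise CohortSchemaError(f"{path}: no data rows")
    if report.rejected:
        logger.warning(
            "%s: rejected %d of %d rows", path, report.n_rejected, report.n_input
        )
    return records, report


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact decimal -> lossless round-trip
    return str(value)


def write_cohort(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write records in the cohort CSV schema (lossless float round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for p in records:
            by_side = {b.side: b for b in p.breasts}
            row = [_fmt(p.patient_id), _fmt(p.age), _fmt(p.height), _fmt(p.weight)]
            for side in (Side.LEFT, Side.RIGHT):
                b = by_side.get(side)
                if b is None:
                    row += [""] * 5
                else:
                    row += [
                        _fmt(b.sn_n),
                        _fmt(b.n_imf),
                        _fmt(b.base_width),
                        _fmt(b.ptosis_grade),
                        _fmt(b.resection_weight),
                    ]
            row += [_fmt(p.has_symptom), _fmt(p.has_finding)]
            writer.writerow(row)


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages."""

    cutoffs: ABBCutoffs = field(default_factory=ABBCutoffs)
    schnur_table_path: Optional[str] = None  # None -> packaged table
    grid_policy: str = GridPolicy.NEAREST.value
    weight_landmark: float = 500.0
    ptosis_low: float = 2.5
    ptosis_high: float = 3.0
    lenient_landmark: float = 350.0
    assume_symptom: bool = True
    assume_finding: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        rubric = raw.pop("rubric", {})
        known = {f for f in cls.__dataclass_fields__ if f != "cutoffs"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(cutoffs=ABBCutoffs(**rubric), **raw)

    def schnur_table(self) -> SchnurTable:
        policy = GridPolicy(self.grid_policy)
        if self.schnur_table_path is None:
            return SchnurTable.default(policy)
        return SchnurTable.from_csv(self.schnur_table_path, policy)

    def digest(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "cutoffs"
        }
        payload["rubric"] = self.cutoffs.__dict__
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def run_report(
    cohort: Sequence[PatientRecord],
    config: RunConfig,
    outdir: Union[str, Path],
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Emits six artifacts into ``outdir``: scored cohort CSV, Schnur
    assessment CSV, concordance JSON, correlation panel CSV, two stratified
    tables CSV, and a plain-text summary. Every artifact records the config
    digest and seed. A stage failure leaves earlier artifacts in place and
    is recorded in the summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.digest()} seed={config.seed}"
    table = config.schnur_table()
    paths: dict[str, Path] = {}
    failures: list[str] = []

    scored = evaluate_cohort(
        cohort,
        config.cutoffs,
        table,
        assume_symptom=config.assume_symptom,
        assume_finding=config.assume_finding,
    )

    def stage(name: str, fn) -> None:
        try:
            paths[name] = fn()
        except Exception as exc:  # keep earlier artifacts, mark the stage
            failures.append(f"{name}: {exc}")
            logger.exception("report stage %s failed", name)

    def _scored() -> Path:
        p = outdir / "scored_cohort.csv"
        scored.to_csv(p, index=False)
        return p

    def _schnur() -> Path:
        p = outdir / "schnur_assessments.csv"
        cols = [
            "patient_id", "bsa", "schnur_threshold", "resection_weight",
            "mismatch", "eligible",
        ]
        scored[cols].to_csv(p, index=False)
        return p

    def _concordance() -> Path:
        p = outdir / "concordance.json"
        payload = concordance(scored).as_dict()
        payload["stamp"] = stamp
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return p

    def _correlations() -> Path:
        p = outdir / "correlations.csv"
        import pandas as pd

        pd.concat(
            [spearman_panel(scored, t) for t in ("abb_score", "schnur_threshold")],
            ignore_index=True,
        ).to_csv(p, index=False)
        return p

    def _strata() -> Path:
        p = outdir / "strata_by_score.csv"
        stratify(scored, "by_score").to_csv(p, index=False)
        q = outdir / "strata_fourfold.csv"
        stratify(scored, "by_category_x_eligibility").to_csv(q, index=False)
        paths["strata_fourfold"] = q
        return p

    def _summary() -> Path:
        p = outdir / "summary.txt"
        ct = concordance(scored)
        lines = [
            f"ABB vs Schnur report  [{stamp}]",
            f"patients: {len(scored)}",
            "",
            "fourfold (condition = moderate-to-severe ABB, test = Schnur eligible):",
            f"  TP={ct.tp} FN={ct.fn} FP={ct.fp} TN={ct.tn}",
            f"  sensitivity={100 * ct.sensitivity:.1f}%  "
            f"specificity={100 * ct.specificity:.1f}%"
            if ct.n
            else "  (empty cohort)",
            "",
            "mean resection weight: "
            f"{scored['resection_weight'].mean():.0f} g; "
            f"mean Schnur threshold: {scored['schnur_threshold'].mean():.0f} g; "
            f"mean mismatch: {scored['mismatch'].mean():.0f} g",
            "note: symptom/finding points "
            f"assumed={config.assume_symptom}/{config.assume_finding} "
            "(adds up to 2 points per patient when flags are unknown)",
        ]
        if failures:
            lines += ["", "FAILED STAGES:"] + [f"  {f}" for f in failures]
        p.write_text("\n".join(lines) + "\n")
        return p

    stage("scored_cohort", _scored)
    stage("schnur_assessments", _schnur)
    stage("concordance", _concordance)
    stage("correlations", _correlations)
    stage("strata_by_score", _strata)
    stage("summary", _summary)
    return paths
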