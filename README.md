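# abburden

Anatomical breast burden (ABB) scoring and Schnur sliding-scale comparison
for reduction-mammaplasty cohorts.

## The problem

Most US insurers adjudicate coverage for breast reduction with the Schnur
sliding scale: a patient qualifies only if the resected tissue weight per
breast reaches a minimum that grows with body surface area (BSA). Because
the threshold depends only on height and weight, it penalizes patients with
larger body habitus and ignores the anatomy and symptoms that actually
constitute the burden of breast hypertrophy.

The ABB model is a 0–6 clinical score built from measurements surgeons
already record. Its anatomical domain awards one point per criterion met:

| criterion | cutoff |
|---|---|
| sternal notch–to–nipple distance (SN-N) | ≥ 26 cm |
| nipple–to–inframammary-fold distance (N-IMF) | ≥ 14 cm |
| base width (BW) | ≥ 16 cm |
| Regnault ptosis grade | = 3 (severe) |

plus one point for at least one patient-reported symptom and one for at
least one physical examination finding:

```
ABB = 1[SN-N ≥ 26] + 1[N-IMF ≥ 14] + 1[BW ≥ 16] + 1[ptosis = 3]
      + 1[symptom] + 1[finding]            ∈ {0, …, 6}
```

Scores 0–2 are categorized as mild burden, 3–6 as moderate-to-severe.
Scoring is per patient: bilateral cases use the breast with the heavier
resection weight (the *index breast*), never the average.

The package implements, as tested library code:

- **`abburden.core`** — domain types and the rubric (anatomical points,
  index-breast rule, total score and category);
- **`abburden.schnur`** — DuBois BSA
  (`0.007184 · h_cm^0.725 · w_kg^0.425`), the sliding-scale lookup on its
  0.05 m² grid (nearest/floor/ceil/linear policies), and the mismatch
  weight `actual − threshold` whose sign decides eligibility;
- **`abburden.cutoffs`** — the cutoff-derivation procedure: scan every
  integer candidate, compare mean resection weight and mean ptosis below vs
  at-or-above it, and select where the groups transition across a 500 g
  landmark inside the severe-ptosis band (a lenient 350 g variant for SN-N);
- **`abburden.analysis`** — fourfold concordance of ABB category vs Schnur
  eligibility (sensitivity/specificity), Spearman correlation panels, and
  stratified summary tables;
- **`abburden.synthetic`** — a seeded Gaussian-copula cohort generator with
  truncated-normal marginals matched to the emulated cohort's summary
  statistics, a severity-linked ptosis categorical, and a linear
  resection-weight model (plus planted-cutoff variants for recovery
  studies);
- **`abburden.io` / `abburden.cli`** — cohort CSV schema with validation
  accounting, YAML run configuration, and the `abb` command
  (`simulate | score | schnur | derive-cutoffs | compare | report`).

## Worked example

```python
import abburden as ab

patient = ab.PatientRecord(
    patient_id="example", age=46, height=1.65, weight=86.0,
    breasts=(ab.BreastMeasurement(
        side="left", sn_n=29, n_imf=12, base_width=20,
        ptosis_grade=3.0, resection_weight=607.0),),
    has_symptom=True, has_finding=True,
)

res = ab.abb_score(patient)
print(res.abb_score, res.category.value, res.breakdown)
# 5 moderate_to_severe AnatomicalBreakdown(sn_n=1, n_imf=0, base_width=1, ptosis=1)

a = ab.assess_schnur(patient, ab.SchnurTable.default())
print(f"BSA {a.bsa:.3f} -> threshold {a.threshold:.0f} g, "
      f"mismatch {a.mismatch:+.0f} g, eligible={a.eligible}")
# BSA 1.933 -> threshold 575 g, mismatch +32 g, eligible=True
```

The patient meets three of four anatomical criteria (N-IMF misses the
14 cm cutoff) and carries the symptom and finding points, scoring 5 of 6 —
severe burden. Under the sliding scale their 607 g resection clears the
575 g threshold for a 1.93 m² BSA by 32 g; had their BSA resolved one grid
row higher (628 g threshold) the same resection would have missed coverage
by 21 g, which is exactly the kind of near-miss the ABB score is designed
to surface.

Cohort-level, end to end on a synthetic cohort:

```python
cohort = ab.generate_cohort(ab.CohortSpec(n=84, seed=1))
scored = ab.evaluate_cohort(cohort)
ct = ab.concordance(scored)
print(ct.tp, ct.fn, ct.fp, ct.tn)   # 36 43 0 5
```

or from the shell:

```bash
abb simulate --n 84 --seed 1 --out cohort.csv
abb report cohort.csv --outdir results/
abb derive-cutoffs cohort.csv
```

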