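# Methods

## The scoring rule

The ABB score is a sum of six binary indicators: four anatomical criteria
evaluated on the index breast (SN-N ≥ 26 cm, N-IMF ≥ 14 cm, BW ≥ 16 cm,
Regnault ptosis grade exactly 3) and one point each for the presence of at
least one qualifying symptom and one physical finding. All length cutoffs
are inclusive ("or greater"). The ptosis criterion is strict equality with
the qualifying grade: grades 0–2 score zero, as does the interpolated 2.5
used when a chart documents "Grade 2-3". The qualifying grade is
configurable (`ABBCutoffs.ptosis_qualifying_grade`) for sensitivity
analyses, but 3 is the rubric.

**Index breast.** Bilateral patients are scored on the breast with the
heavier resection weight; averaging the two breasts would understate the
burden of asymmetric patients. Exactly equal weights never occur in
practice with continuous masses; the tie-break (left, then right, then
input order) exists only so the rule is total and deterministic.

**Symptom/finding assumption.** In retrospective cohorts restricted to
functional reductions, symptom and finding documentation is unreliable, so
the default scoring assumes both points when a flag is unknown
(`assume_symptom=True, assume_finding=True`). An explicit `False` always
overrides the assumption, and disabling an assumption makes an unknown flag
a hard scoring error rather than a silent zero. Note that in
assumption mode every patient starts at 2 points, so the observed score
range is 2–6 and the mild/moderate boundary (2 vs 3) is decided entirely
by anatomy.

## Schnur eligibility

BSA is always computed from height and weight with the DuBois formula,
never ingested, so its provenance is single-sourced (BMI likewise). The
sliding scale ships as data (`data/schnur_table.csv`: BSA 1.35–2.55 m² on a
0.05 grid, thresholds 199–1662 g) because it is an external published
table; the test suite pins the eleven threshold values that any correct
transcription must contain, so drift fails loudly.

Non-grid BSAs resolve to a row by a configurable policy. The default is
nearest-with-half-up; floor, ceil, and linear interpolation are available
because the matching convention used by adjudicators is not standardized.
Every policy is monotone non-decreasing in BSA and returns the exact table
entry at grid points. `mismatch = actual − threshold`; `mismatch ≥ 0`
counts as eligible (the threshold is a minimum; the exact-zero case is
logged when it occurs).

## Cutoff derivation

For each metric the scan evaluates every integer candidate `c` in
`[floor(min)+1, ceil(max)]`, partitioning patients into `{metric < c}` vs
`{metric ≥ c}` and recording each group's size, mean resection weight, and
mean ptosis grade. Empty-group means are NaN-flagged, never imputed.

Selection formalizes a narrative procedure as an explicit rule: the
*smallest* candidate whose below-group mean weight is under the 500 g
landmark, whose at-or-above-group mean reaches it, and whose
at-or-above-group mean ptosis lies in the moderate-to-severe → severe band
[2.5, 3.0]. The band is tested on the above group only: it is the group
whose severity justifies the cutoff, and a below-group condition would
spuriously veto homogeneous severe cohorts. For SN-N a lenient variant
lowers the above-group weight landmark to 350 g, because severe ptosis
already contributes its own rubric point and SN-N is partly a ptosis
surrogate; without the reduction the rule would over-shoot the cutoff to
chase the 500 g crossing. All four constants (500 g, 350 g, 2.5, 3.0) are
parameters, so the judgment calls are auditable and movable. When no
candidate qualifies the result is a structured `no_transition`, not a
default. Plateaus resolve to the smallest candidate, consistent with the
lenient reading.

## Concordance and correlations

The fourfold table takes moderate-to-severe ABB as the condition and
Schnur eligibility as the test: sensitivity is the fraction of high-burden
patients the scale covers, specificity the fraction of mild-burden patients
it denies. Degenerate margins yield NaN (JSON `null`), never 0/0 silently.
Percentages are displayed to one decimal; exact fractions are retained.

Spearman correlations use average-rank tie handling; two-tailed p-values
come from the t approximation on n−2 degrees of freedom, adequate at
cohort sizes in the dozens and above (no multiple-testing correction is
applied; each test stands at α = .05). Stratified summaries report sample
(n−1) standard deviations, the conventional choice for cohort description;
single-patient strata have NaN SD.

## Synthetic cohorts

The generator emulates a single-site reduction-mammaplasty cohort (n = 84)
whose per-patient data are not public. What it reproduces:

- **Marginals.** Age 48.8 ± 15.9 y on [16, 86]; height 1.63 ± 0.07 m on
  [1.47, 1.78]; weight 75.1 ± 11.4 kg on [53.3, 118.8]; SN-N 30.5 ± 4.04 cm
  on [22.5, 40]; N-IMF 13.8 ± 2.58 cm on [9, 22]; BW 15.7 ± 2.32 cm on
  [12, 24]. Each is a truncated normal whose parent location/scale are
  solved numerically so the *truncated* mean and SD equal the targets.
- **Dependence.** A Gaussian copula over the six variables plus a latent
  severity axis. The latent correlations (~0.4–0.55 among breast metrics,
  weight, and severity) are calibration choices — no pairwise measurement
  correlations are published — set so the resulting correlation panel is
  qualitatively ordered like the reference cohort's (metrics and resection
  weight correlate strongly with ABB, BSA/BMI moderately).
- **Ptosis.** Grades {1, 2, 2.5, 3} with probabilities {.02, .31, .10, .57},
  cut from the severity latent's quantiles, so the marginal frequencies are
  exact in expectation and ptosis co-varies positively with the metrics —
  which is what lets synthetic cutoff scans show the severity transition.
- **Resection weight.** Linear in the breast's SN-N, N-IMF, BW (15, 25,
  30 g/cm) and ptosis grade (80 g/grade) plus N(0, 100 g) noise, floored at
  50 g. The intercept (−1088 g) is set analytically so the *index-breast*
  mean lands near 452 g: picking the heavier of two noisy breasts adds
  E|Δ|/2 ≈ 58 g over the per-breast mean, which the intercept absorbs.
  Index-breast SD comes out ≈ 200 g against the 211 g target.
- **Breasts.** Patient-level metrics ± N(0, 0.4 cm) asymmetry per breast,
  clipped to the marginal support; all patients bilateral by default
  (configurable), flags set to `True` mirroring the assumption mode.

**Planted cutoffs.** `planted_cutoff_spec` swaps in a step model:
E[weight] = 300 g below the planted value `k`, 540 g at or above it
(gap 240 g, noise SD 80 g). The noise is drawn once per patient and shared
across breasts: with independent per-breast noise, heavier-breast selection
would lift both scan groups by ≈ noise_sd/√π ≈ 45 g and the above-group
mean would cross 500 g several centimetres below `k`, defeating the
construction. Margins follow from the truncated-normal tail fractions: at
candidate `k` the above-group mean is 540 g (+40 g margin), at `k−1`
roughly 300 + 240·P(X ≥ k | X ≥ k−1) ≈ 480 g (−20 g), with group-mean
standard errors of 12–18 g at n = 84 — so the smallest-candidate rule
recovers `k` or `k−1` in nearly all seeds, and the recovery test demands
±1 cm in ≥ 90% of 100 seeds.

**What passing synthetic tests does not show.** The generator is a
truncated-Gaussian idealization: it has no measurement rounding (real
charts record half-centimetres), no surgeon-level clustering (the
reference cohort spans 10 surgeons), no unilateral cases by default, no
missingness, and its weight model is linear where reality need not be.
Synthetic concordance numbers therefore exercise the *machinery*, not the
published cohort-dependent values, which are documentation anchors only.

## Numerical conventions and problem sizes

- Exact comparisons use the raw floats; oracle-equivalence tests allow
  1e−13 relative slack for summation order and 1e−12 absolute for rank
  correlations.
- Seeds: every stochastic routine takes an explicit seed through
  `CohortSpec`; generation draws all randomness up front in a fixed order,
  so cohorts and their CSV serializations are byte-reproducible.
- Default test problem sizes — 5 000 patients for marginal-fidelity checks
  (3 standard-error bands), 100 seeds × 84 patients for cutoff recovery,
  200 random cohorts/samples for oracle equivalence — keep the full suite
  in the low seconds while leaving the Monte-Carlo bands narrow.
- CSV floats serialize via `repr` (shortest round-trip form), making
  write→read the identity on records.

## Known limitations

- The grid-matching convention actually used with the sliding scale in
  adjudication practice is unknown; results can shift by one grid row near
  boundaries (hence the policy is recorded in every assessment).
- The selection rule is one faithful formalization of a narrative
  procedure; when the weight and ptosis transitions conflict, the
  conjunction rule abstains (`no_transition`) rather than rank them.
- Whether eligibility for bilateral cases should face the heavier or the
  averaged resection is contested; the package defaults to the index
  breast for consistency with ABB scoring and exposes averaging for
  sensitivity analysis.
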