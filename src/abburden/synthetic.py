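"""Seeded synthetic patient cohorts for exercising the full pipeline.

No per-patient data from the source cohort is public, so testing and
examples run on synthetic cohorts that reproduce its *statistical* shape:

* continuous marginals (age, height, weight, and the three breast
  measurements) are truncated normals whose truncated mean/sd hit the
  published cohort summary targets exactly (the parent location/scale are
  moment-matched numerically);
* co-variation among anthropometrics, breast metrics, and a latent
  "severity" axis comes from a Gaussian copula with a configurable
  correlation matrix;
* the Regnault ptosis grade is a categorical (grades 1, 2, 2.5, 3 with
  cohort frequencies 2/31/10/57%) cut from the severity latent, so ptosis
  co-varies positively with the measurements;
* per-breast values are the patient-level value plus small asymmetry noise,
  and resection weight follows a linear model in the breast's metrics and
  ptosis with Gaussian noise, floored at a positive minimum.

A planted-cutoff variant replaces the linear weight model with a step model
that crosses a landmark weight at a known metric value, for
parameter-recovery tests of the cutoff-derivation procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import optimize, special, stats

from .core import BreastMeasurement, PatientRecord, Side

#: Copula variable order (severity is latent-only, realized as ptosis).
LATENT_VARS = ("age", "height", "weight", "sn_n", "n_imf", "base_width", "severity")

METRIC_VARS = ("sn_n", "n_imf", "base_width")


@dataclass(frozen=True)
class MarginalSpec:
    """Truncated-normal marginal target: mean/sd of the *truncated* law."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"infeasible truncation: min {self.min} >= max {self.max}")
        if not self.sd >= 0:
            raise ValueError("sd must be >= 0")
        if not self.min <= self.mean <= self.max:
            raise ValueError("mean must lie inside [min, max]")


@lru_cache(maxsize=None)
def _match_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (loc, scale) whose [lo, hi]-truncation has the target moments."""

    def residual(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(
            f"truncated-normal moment match failed for "
            f"mean={mean}, sd={sd} on [{lo}, {hi}]: {sol.message}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _default_marginals() -> dict[str, MarginalSpec]:
    # Cohort summary targets (n=84 reduction-mammaplasty patients).
    return {
        "age": MarginalSpec(48.8, 15.9, 16.0, 86.0),
        "height": MarginalSpec(1.63, 0.07, 1.47, 1.78),
        "weight": MarginalSpec(75.1, 11.4, 53.3, 118.8),
        "sn_n": MarginalSpec(30.5, 4.04, 22.5, 40.0),
        "n_imf": MarginalSpec(13.8, 2.58, 9.0, 22.0),
        "base_width": MarginalSpec(15.7, 2.32, 12.0, 24.0),
    }


def _default_corr() -> np.ndarray:
    # Latent (copula-scale) correlations; calibration choices, since pairwise
    # measurement correlations are not published. Order = LATENT_VARS.
    r = {
        ("age", "weight"): 0.10,
        ("age", "sn_n"): 0.20,
        ("age", "n_imf"): 0.10,
        ("age", "base_width"): 0.10,
        ("age", "severity"): 0.20,
        ("height", "weight"): 0.40,
        ("height", "sn_n"): 0.10,
        ("height", "n_imf"): 0.10,
        ("height", "base_width"): 0.10,
        ("weight", "sn_n"): 0.45,
        ("weight", "n_imf"): 0.40,
        ("weight", "base_width"): 0.50,
        ("weight", "severity"): 0.30,
        ("sn_n", "n_imf"): 0.55,
        ("sn_n", "base_width"): 0.50,
        ("sn_n", "severity"): 0.55,
        ("n_imf", "base_width"): 0.50,
        ("n_imf", "severity"): 0.45,
        ("base_width", "severity"): 0.45,
    }
    k = len(LATENT_VARS)
    m = np.eye(k)
    idx = {v: i for i, v in enumerate(LATENT_VARS)}
    for (a, b), v in r.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return m


@dataclass(frozen=True)
class LinearWeightModel:
    """Resection weight (g) linear in the breast's metrics and ptosis grade.

    Coefficients are calibrated so the default cohort's analytic index-breast
    (heavier-side) mean/sd of resection weight land near the emulated
    452 +/- 211 g. The intercept absorbs the expected heavier-of-two uplift
    E|D|/2 ~ 58 g, where D is the between-breast weight difference implied by
    the noise sd and metric asymmetry.
    """

    intercept: float = -1088.0
    sn_n_coef: float = 15.0
    n_imf_coef: float = 25.0
    bw_coef: float = 30.0
    ptosis_coef: float = 80.0
    noise_sd: float = 100.0
    floor: float = 50.0

    def sample(
        self,
        sn_n: np.ndarray,
        n_imf: np.ndarray,
        bw: np.ndarray,
        ptosis: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        mean = (
            self.intercept
            + self.sn_n_coef * sn_n
            + self.n_imf_coef * n_imf
            + self.bw_coef * bw
            + self.ptosis_coef * ptosis
        )
        w = mean + rng.normal(0.0, self.noise_sd, size=np.shape(sn_n))
        return np.maximum(w, self.floor)


@dataclass(frozen=True)
class StepWeightModel:
    """Step model: E[weight] = low_mean + gap * [metric >= k].

    Used to plant a known cutoff ``k`` in a synthetic cohort so the
    derivation procedure's recovery can be measured. Noise is drawn once per
    patient and shared across breasts: with independent per-breast noise the
    heavier-breast (index) selection would lift both group means by
    E[max]-mu and smear the planted step at the per-patient level where the
    scan operates.
    """

    metric: str = "n_imf"
    k: float = 14.0
    low_mean: float = 300.0
    gap: float = 240.0
    noise_sd: float = 80.0
    floor: float = 50.0

    def sample(
        self,
        sn_n: np.ndarray,
        n_imf: np.ndarray,
        bw: np.ndarray,
        ptosis: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        x = np.asarray({"sn_n": sn_n, "n_imf": n_imf, "base_width": bw}[self.metric])
        mean = self.low_mean + self.gap * (x >= self.k)
        if x.ndim == 2:  # (patients, breasts): one noise draw per patient
            noise = rng.normal(0.0, self.noise_sd, size=(x.shape[0], 1))
        else:
            noise = rng.normal(0.0, self.noise_sd, size=x.shape)
        return np.maximum(mean + noise, self.floor)


WeightModel = Union[LinearWeightModel, StepWeightModel]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a reproducible synthetic cohort."""

    n: int = 84
    seed: int = 0
    marginals: Mapping[str, MarginalSpec] = field(default_factory=_default_marginals)
    ptosis_probs: Mapping[float, float] = field(
        default_factory=lambda: {1.0: 0.02, 2.0: 0.31, 2.5: 0.10, 3.0: 0.57}
    )
    corr: np.ndarray = field(default_factory=_default_corr)
    weight_model: WeightModel = field(default_factory=LinearWeightModel)
    metric_asymmetry_sd: float = 0.4  # cm, per-breast deviation from patient mean
    bilateral_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        missing = set(LATENT_VARS[:-1]) - set(self.marginals)
        if missing:
            raise ValueError(f"marginals missing for: {sorted(missing)}")
        total = sum(self.ptosis_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"ptosis probabilities must sum to 1, got {total}")
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        k = len(LATENT_VARS)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError(f"corr must be a symmetric {k}x{k} matrix")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("corr must be positive definite")
        if not 0 <= self.bilateral_prob <= 1:
            raise ValueError("bilateral_prob must be in [0, 1]")
        if self.metric_asymmetry_sd < 0:
            raise ValueError("metric_asymmetry_sd must be >= 0")


def _sample_marginal(u: np.ndarray, spec: MarginalSpec) -> np.ndarray:
    mu, sigma = _match_truncnorm(spec.mean, spec.sd, spec.min, spec.max)
    a, b = (spec.min - mu) / sigma, (spec.max - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _ptosis_from_latent(u: np.ndarray, probs: Mapping[float, float]) -> np.ndarray:
    grades = sorted(probs)
    cum = np.cumsum([probs[g] for g in grades])
    idx = np.searchsorted(cum, u, side="left")
    idx = np.minimum(idx, len(grades) - 1)
    return np.asarray(grades, dtype=float)[idx]


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; deterministic for a given spec (incl. its seed).

    All random draws are made up front in a fixed order from one
    ``numpy.random.default_rng(spec.seed)``, so identical specs produce
    identical cohorts. Symptom/finding flags are set True, mirroring a
    cohort restricted to symptomatic functional reductions.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n, len(LATENT_VARS)

    chol = np.linalg.cholesky(spec.corr)
    z = rng.standard_normal((n, k)) @ chol.T
    bilateral = rng.random(n) < spec.bilateral_prob
    asym = rng.normal(0.0, spec.metric_asymmetry_sd, size=(n, 2, len(METRIC_VARS)))
    u = special.ndtr(z)

    cols = {
        var: _sample_marginal(u[:, i], spec.marginals[var])
        for i, var in enumerate(LATENT_VARS[:-1])
    }
    ptosis = _ptosis_from_latent(u[:, -1], spec.ptosis_probs)

    # per-breast metrics: patient value +/- asymmetry, clipped to the
    # marginal's support so plausibility bounds keep holding
    per_breast = {}
    for j, var in enumerate(METRIC_VARS):
        m = spec.marginals[var]
        vals = cols[var][:, None] + asym[:, :, j]
        per_breast[var] = np.clip(vals, m.min, m.max)

    weights = spec.weight_model.sample(
        per_breast["sn_n"],
        per_breast["n_imf"],
        per_breast["base_width"],
        np.repeat(ptosis[:, None], 2, axis=1),
        rng,
    )

    bmi = cols["weight"] / cols["height"] ** 2
    frac_out = np.mean((bmi < 16.8) | (bmi > 42.4))
    if frac_out > 0.05:
        warnings.warn(
            f"{100 * frac_out:.1f}% of generated BMIs fall far outside the "
            "emulated cohort range (18.8-40.4 kg/m^2); check height/weight "
            "marginals and correlation",
            UserWarning,
            stacklevel=2,
        )

    records = []
    width = max(4, len(str(n)))
    for i in range(n):
        sides = (Side.LEFT, Side.RIGHT) if bilateral[i] else (Side.LEFT,)
        breasts = tuple(
            BreastMeasurement(
                side=side,
                sn_n=float(per_breast["sn_n"][i, s]),
                n_imf=float(per_breast["n_imf"][i, s]),
                base_width=float(per_breast["base_width"][i, s]),
                ptosis_grade=float(ptosis[i]),
                resection_weight=float(weights[i, s]),
            )
            for s, side in enumerate(sides)
        )
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                age=float(cols["age"][i]),
                height=float(cols["height"][i]),
                weight=float(cols["weight"][i]),
                breasts=breasts,
                has_symptom=True,
                has_finding=True,
            )
        )
    return records


def planted_cutoff_spec(
    base: CohortSpec,
    metric: str,
    k: float,
    *,
    low_mean: float = 300.0,
    gap: float = 240.0,
    noise_sd: float = 80.0,
) -> CohortSpec:
    """Spec variant with a resection-weight step planted at ``metric >= k``.

    By construction E[weight | metric < k] = ``low_mean`` and
    E[weight | metric >= k] = ``low_mean + gap`` (before flooring), so with
    low_mean < 500 <= low_mean + gap the derivation's 500 g landmark sits
    inside the step. A warning is emitted when the configuration cannot
    guarantee that bracketing.
    """
    if metric not in METRIC_VARS:
        raise ValueError(f"metric must be one of {METRIC_VARS}, got {metric!r}")
    m = base.marginals[metric]
    if not m.min < k < m.max:
        raise ValueError(f"k={k} outside the {metric} truncation range [{m.min}, {m.max}]")
    if gap <= 0 or not (low_mean < 500.0 <= low_mean + gap):
        warnings.warn(
            f"planted gap ({low_mean} -> {low_mean + gap} g) does not bracket "
            "the 500 g landmark; cutoff recovery is not guaranteed",
            UserWarning,
            stacklevel=2,
        )
    model = StepWeightModel(
        metric=metric, k=float(k), low_mean=low_mean, gap=gap, noise_sd=noise_sd
    )
    return replace(base, weight_model=model)
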