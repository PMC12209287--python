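"""Synthetic judgment-record generator with a known outcome process.

Emulates the structure of a curated treatment-order corpus — the
schema, plausible marginals, and a controllable dependence between the
outcome and the clinical burden — without any claim to jurisprudential
realism.  Diagnosis and symptom texts are assembled from fixed template
pools, split so that the keyword lexicon recovers the generator's
latent severity and non-compliance bits *exactly*; that inversion is
what makes every downstream stage testable end to end.

Outcome model
-------------
For accepted requests, the probability of entire (rather than partial)
acceptance is

    P(entire) = logistic(beta0 + beta1 * Burden_Score + beta2 * t_norm)

where ``t_norm`` is the requested duration scaled over the generator's
duration grid, followed by independent label-noise flips.  The granted
duration is ``requested x F`` with ``F ~ Beta(a, b)``; ``(a, b)`` are
solved from the configured mean fraction and the target Pearson
correlation between requested and granted durations (default 0.80),
using the exact moment identity
``corr(R, RF) = mu_F sd_R / sqrt(var_F E[R^2] + mu_F^2 var_R)``.

Default condition set: 30% entire / 70% partial class balance
(beta0 = -4.2 with beta1 = 6, beta2 = -1), 5% label noise, 70% severe
diagnoses, 60% non-compliance, 40% substance use, requested durations
uniform on {0.5, 1.0, ..., 5.0} years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .evaluation import subseed
from .exceptions import OrdercastError
from .features import DEFAULT_BURDEN_WEIGHTS, BurdenWeights
from .records import JudgmentRecord

# Template pools.  Severe diagnoses each contain a default severity
# lexicon term; the non-severe pools contain none.  Non-compliant
# symptom templates each contain a default non-compliance term; the
# compliant templates contain none.
SEVERE_DIAGNOSES = (
    "paranoid schizophrenia",
    "schizoaffective disorder with active psychosis",
    "bipolar disorder type I with psychotic features",
    "chronic psychosis, treatment refractory",
    "schizophrenia, undifferentiated type",
)
NONSEVERE_DIAGNOSES = (
    "major depressive disorder",
    "adjustment disorder with anxious mood",
    "generalized anxiety disorder",
    "mood disorder not otherwise specified",
    "obsessive-compulsive disorder",
)
COMORBIDITIES = (
    "borderline personality traits",
    "mild intellectual disability",
    "insomnia",
    "post-traumatic stress symptoms",
)
NONCOMPLIANT_SYMPTOMS = (
    "refused all oral medication on the ward",
    "discontinued depot injections after discharge",
    "documented non-compliance with the treatment plan",
    "refused follow-up and discontinued therapy sessions",
)
COMPLIANT_SYMPTOMS = (
    "cooperative with the treating team and adherent to medication",
    "accepts treatment under supervision of the outpatient clinic",
    "attends appointments regularly and takes medication as prescribed",
)
SUBSTANCES = ("cannabis", "cocaine", "amphetamines", "alcohol", "opioids")
TREATMENTS = (
    "antipsychotic medication with clinical follow-up",
    "depot antipsychotic injections",
    "mood stabilizer with mandatory monitoring",
)
ACCESSORY = ("blood samples", "urinary tests", "ECT if clinically indicated")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator; defaults are the reference study
    conditions described in the module docstring."""

    n: int = 176
    seed: int = 0
    severity_prob: float = 0.70
    noncompliance_prob: float = 0.60
    substance_prob: float = 0.40
    female_prob: float = 0.40
    represented_prob: float = 0.95
    legal_aid_prob: float = 0.70          # among represented defendants
    housing_prob: float = 0.30
    denied_prob: float = 0.05
    age_mean: float = 45.0
    age_sd: float = 15.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    requested_grid: tuple[float, ...] = tuple(k * 0.5 for k in range(1, 11))
    granted_fraction_mean: float = 0.75
    target_requested_granted_corr: float = 0.80
    beta0: float = -4.2
    beta1: float = 6.0
    beta2: float = -1.0
    label_noise: float = 0.05
    burden_weights: BurdenWeights = field(
        default_factory=lambda: DEFAULT_BURDEN_WEIGHTS)

    def validate(self) -> "GeneratorConfig":
        if self.n < 1:
            raise OrdercastError(f"n={self.n} must be >= 1")
        for name in ("severity_prob", "noncompliance_prob", "substance_prob",
                     "female_prob", "represented_prob", "legal_aid_prob",
                     "housing_prob", "denied_prob", "label_noise"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise OrdercastError(f"{name}={p} outside [0, 1]")
        for name in ("age_mean", "age_sd", "beta0", "beta1", "beta2"):
            if not np.isfinite(getattr(self, name)):
                raise OrdercastError(f"{name} must be finite")
        if not self.requested_grid or min(self.requested_grid) <= 0:
            raise OrdercastError("requested_grid must be positive and non-empty")
        if not 0 < self.granted_fraction_mean < 1:
            raise OrdercastError("granted_fraction_mean must be in (0, 1)")
        if not 0 < self.target_requested_granted_corr < 1:
            raise OrdercastError(
                "target_requested_granted_corr must be in (0, 1)")
        self.granted_beta_params()  # raises if infeasible
        return self

    def granted_beta_params(self) -> tuple[float, float]:
        """Beta(a, b) parameters of the granted/requested fraction that
        hit the configured requested-granted correlation exactly (in
        expectation) given the duration grid's moments."""
        grid = np.asarray(self.requested_grid, dtype=float)
        mu_r, e_r2 = grid.mean(), (grid ** 2).mean()
        var_r = e_r2 - mu_r ** 2
        if var_r <= 0:
            raise OrdercastError("requested_grid must have > 1 distinct value "
                                 "to target a correlation")
        rho, mu_f = self.target_requested_granted_corr, self.granted_fraction_mean
        var_f = mu_f ** 2 * var_r * (1 / rho ** 2 - 1) / e_r2
        if var_f >= mu_f * (1 - mu_f):
            raise OrdercastError(
                f"correlation target {rho} infeasible for fraction mean {mu_f}")
        nu = mu_f * (1 - mu_f) / var_f - 1
        return (mu_f * nu, (1 - mu_f) * nu)


@dataclass
class LabeledDataset:
    """Modellable synthetic records with the generator's own labels and
    latent probabilities (the oracle for recovery tests)."""

    records: list[JudgmentRecord]
    outcomes: np.ndarray       # 1 = entire acceptance
    probabilities: np.ndarray  # latent P(entire) before label noise


def _requested_norm(treq: np.ndarray, grid: Sequence[float]) -> np.ndarray:
    lo, hi = min(grid), max(grid)
    return (treq - lo) / (hi - lo) if hi > lo else np.full_like(treq, 0.5)


def _generate(config: GeneratorConfig) -> tuple[list[JudgmentRecord],
                                                np.ndarray, np.ndarray,
                                                np.ndarray]:
    config.validate()
    rng = np.random.default_rng(subseed(config.seed, "synth"))
    n = config.n
    severe = rng.random(n) < config.severity_prob
    noncomp = rng.random(n) < config.noncompliance_prob
    substance = rng.random(n) < config.substance_prob
    female = rng.random(n) < config.female_prob
    represented = rng.random(n) < config.represented_prob
    legal_aid = represented & (rng.random(n) < config.legal_aid_prob)
    housing = rng.random(n) < config.housing_prob
    denied = rng.random(n) < config.denied_prob
    lo, hi = config.age_bounds
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)),
                  lo, hi)
    treq = rng.choice(np.asarray(config.requested_grid, dtype=float), size=n)
    a, b = config.granted_beta_params()
    fraction = rng.beta(a, b, size=n)
    tgrant = np.round(treq * fraction, 2)

    tnorm = _requested_norm(treq, config.requested_grid)
    w = config.burden_weights
    burden = (w.severity * severe + w.noncompliance * noncomp
              + w.time_requested * tnorm + w.substance_use * substance)
    prob_entire = expit(config.beta0 + config.beta1 * burden
                        + config.beta2 * tnorm)
    entire = rng.random(n) < prob_entire
    flips = rng.random(n) < config.label_noise
    entire = entire ^ flips

    records = []
    for i in range(n):
        if denied[i]:
            decision, extent, granted_i = "denied", "not_applicable", 0.0
        else:
            decision = "accepted"
            extent = "entire" if entire[i] else "partial"
            granted_i = float(tgrant[i])
        dx_pool = SEVERE_DIAGNOSES if severe[i] else NONSEVERE_DIAGNOSES
        main_dx = dx_pool[int(rng.integers(len(dx_pool)))]
        other = ([COMORBIDITIES[int(rng.integers(len(COMORBIDITIES)))]]
                 if rng.random() < 0.5 else [])
        symptoms = (NONCOMPLIANT_SYMPTOMS if noncomp[i]
                    else COMPLIANT_SYMPTOMS)
        symptoms_text = symptoms[int(rng.integers(len(symptoms)))]
        subs = (sorted(rng.choice(SUBSTANCES,
                                  size=int(rng.integers(1, 3)),
                                  replace=False).tolist())
                if substance[i] else [])
        records.append(JudgmentRecord(
            represented=bool(represented[i]),
            legal_aid=bool(legal_aid[i]),
            age_years=float(age[i]),
            sex="female" if female[i] else "male",
            main_diagnosis=main_dx,
            other_diagnoses=other,
            symptoms_text=symptoms_text,
            substance_use_reported=bool(substance[i]),
            substances=subs,
            request_type="treatment_and_housing" if housing[i] else "treatment",
            treatment_requested=TREATMENTS[int(rng.integers(len(TREATMENTS)))],
            accessory_requests=(list(ACCESSORY[:2])
                                if rng.random() < 0.4 else []),
            time_requested_years=float(treq[i]),
            decision=decision,
            time_granted_years=granted_i,
            acceptance_extent=extent,
        ).validate())
    return records, entire.astype(int), prob_entire, denied


def generate_records(config: GeneratorConfig) -> list[JudgmentRecord]:
    """Generate ``config.n`` schema-valid records (a ``denied_prob``
    share carries no entire/partial outcome).  Deterministic given
    ``config.seed``."""
    records, _, _, _ = _generate(config)
    return records


def generate_labeled_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate records and return the accepted (modellable) subset
    together with the generator's outcome labels and latent
    probabilities."""
    records, entire, prob, denied = _generate(config)
    keep = ~denied
    return LabeledDataset(
        records=[r for r, k in zip(records, keep) if k],
        outcomes=entire[keep],
        probabilities=prob[keep],
    )
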