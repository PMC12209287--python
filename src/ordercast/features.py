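"""Min–max scaling, the Burden_Score composite, and feature assembly.

The classifier consumes ten features in a fixed order; age and the two
durations are passed in raw years (tree ensembles are scale-invariant),
while the fuzzy layer consumes min–max-scaled copies fitted on the
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DomainError, OrdercastError
from .lexicon import SemanticFlags
from .records import JudgmentRecord

#: Classifier feature names, in the fixed column order.
FEATURE_NAMES: tuple[str, ...] = (
    "age", "time_requested", "time_granted", "legal_aid", "sex",
    "substance_use", "severity_flag", "compliance_flag",
    "burden_score", "expanded_score",
)


@dataclass(frozen=True)
class BurdenWeights:
    """Fixed weights of the clinical-legal burden composite (must sum
    to 1)."""

    severity: float = 0.35
    noncompliance: float = 0.30
    time_requested: float = 0.20
    substance_use: float = 0.15

    def __post_init__(self):
        w = (self.severity, self.noncompliance, self.time_requested,
             self.substance_use)
        if any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise DomainError(f"burden weights must be positive and sum to 1: {w}")


DEFAULT_BURDEN_WEIGHTS = BurdenWeights()


def fit_minmax(values: Sequence[float]) -> tuple[float, float]:
    """Fit per-feature (min, max) scaler parameters.

    A constant feature yields degenerate params (min == max);
    :func:`apply_minmax` then returns 0.5 for every input.
    """
    vals = list(values)
    if not vals:
        raise OrdercastError("cannot fit min-max scaler on an empty list")
    return (float(min(vals)), float(max(vals)))


def apply_minmax(x: float, params: tuple[float, float]) -> float:
    """Scale ``x`` to [0, 1], clamping out-of-range inputs."""
    mn, mx = params
    if mx == mn:
        return 0.5
    return float(np.clip((x - mn) / (mx - mn), 0.0, 1.0))


def burden_score(severity: int, noncompliance: int,
                 time_requested_norm: float, substance_use: int,
                 weights: BurdenWeights = DEFAULT_BURDEN_WEIGHTS) -> float:
    """Weighted composite of severity, non-compliance, normalized
    requested duration, and substance use.

    With the default weights:
    ``0.35*severity + 0.30*noncompliance + 0.20*time_requested_norm
    + 0.15*substance_use``.
    """
    for name, v in (("severity", severity), ("noncompliance", noncompliance),
                    ("substance_use", substance_use)):
        if v not in (0, 1):
            raise DomainError(f"{name} must be 0 or 1, got {v}")
    if not 0 <= time_requested_norm <= 1:
        raise DomainError(
            f"time_requested_norm={time_requested_norm} outside [0, 1]")
    return (weights.severity * severity
            + weights.noncompliance * noncompliance
            + weights.time_requested * time_requested_norm
            + weights.substance_use * substance_use)


def build_feature_vector(record: JudgmentRecord, flags: SemanticFlags,
                         burden: float, expanded: float) -> np.ndarray:
    """Assemble the ten-feature classifier input for one record.

    Sex is encoded female=1/male=0; booleans as 0/1; age and durations
    in raw years.
    """
    for name, v in (("burden", burden), ("expanded", expanded)):
        if v is None:
            raise OrdercastError(f"missing component: {name}")
    return np.array([
        record.age_years,
        record.time_requested_years,
        record.time_granted_years,
        int(record.legal_aid),
        1 if record.sex == "female" else 0,
        int(record.substance_use_reported),
        flags.severity_flag,
        flags.compliance_flag,
        burden,
        expanded,
    ], dtype=float)
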