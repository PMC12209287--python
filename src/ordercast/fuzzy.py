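"""Mamdani-type weighted-rule fuzzy inference engine.

The engine turns one case profile (:class:`FuzzyInput`) into a continuous
``Expanded_Score`` in [0, 1] — the graded likelihood that a treatment
order is accepted *entirely* rather than partially — plus a Low/Medium/
High category and a full activation trace.

Model
-----
Inputs are fuzzified with triangular membership functions over the
min–max-normalized age and requested-duration variables; binary
attributes (severity flag, non-compliance flag, substance use, legal
aid, sex) enter rules as crisp 0/1 conditions.  Each of the ten
expert rules is a conjunction evaluated with the ``min`` t-norm, giving
a firing strength :math:`s_i \\in [0, 1]`, and carries a hand-assigned
weight :math:`w_i \\in (0, 1]` and a consequent label with a crisp
representative value :math:`v_i`.  The score is the weighted mean over
fired rules:

.. math::

    \\text{Expanded\\_Score}
        = \\frac{\\sum_{i: s_i > 0} w_i s_i v_i}{\\sum_{i: s_i > 0} w_i s_i}

so a single fired rule yields exactly its own crisp value, and any mix
of fired rules stays inside the convex hull of their crisp values.  If
no rule fires the score defaults to the neutral midpoint 0.5.  The
crisp consequent values (Low 0.17, Medium 0.50, Medium-High 0.65,
High 0.85) are calibrated so the engine reproduces the two reference
case profiles exactly; they are ordinary configuration and can be
overridden.

Defuzzification thresholds map the score to a category: Low below 0.4,
High above 0.7, Medium in between (boundaries inclusive to Medium).

Everything — membership triangles, rule registry, weights, crisp
values, thresholds — serializes to a single JSON document, so the whole
system is inspectable and round-trippable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .exceptions import DomainError, FuzzyConfigError

# ---------------------------------------------------------------------------
# membership functions and linguistic variables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function on [0, 1] with feet ``a``/``c``
    and peak ``b``.

    Degenerate shoulders (``a == b`` or ``b == c``) give degree 1 on the
    flat end, so [0, 0, 0.3] is a left-shoulder set with full membership
    at 0.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not (0 <= self.a <= self.b <= self.c <= 1):
            raise FuzzyConfigError(
                f"invalid triangle ({self.a}, {self.b}, {self.c}): "
                "need 0 <= a <= b <= c <= 1")

    def __call__(self, x: float) -> float:
        """Membership degree of ``x``."""
        if x < self.a or x > self.c:
            return 0.0
        if x == self.b:
            return 1.0
        if x < self.b:
            return (x - self.a) / (self.b - self.a)
        return (self.c - x) / (self.c - self.b)


def triangular_membership(x: float, mf: TriangularMF) -> float:
    """Functional alias for :meth:`TriangularMF.__call__`."""
    return mf(x)


#: Default linguistic variables: label -> triangle, per fuzzified input.
DEFAULT_VARIABLES: dict[str, dict[str, TriangularMF]] = {
    "age": {
        "Young": TriangularMF(0.0, 0.0, 0.3),
        "Middle-aged": TriangularMF(0.2, 0.5, 0.7),
        "Older": TriangularMF(0.8, 1.0, 1.0),
    },
    "time_requested": {
        "Short": TriangularMF(0.0, 0.0, 0.3),
        "Medium": TriangularMF(0.2, 0.5, 0.7),
        "Long": TriangularMF(0.6, 1.0, 1.0),
    },
    "time_granted": {
        "Short": TriangularMF(0.0, 0.0, 0.3),
        "Medium": TriangularMF(0.2, 0.5, 0.7),
        "Long": TriangularMF(0.6, 1.0, 1.0),
    },
    "likelihood": {
        "Low": TriangularMF(0.0, 0.0, 0.4),
        "Medium": TriangularMF(0.3, 0.5, 0.7),
        "High": TriangularMF(0.6, 1.0, 1.0),
    },
}


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyInput:
    """One case profile, as the rule antecedents see it.

    ``age_norm`` and ``time_requested_norm`` are min–max-scaled to
    [0, 1]; the flags are crisp 0/1; ``sex`` is ``"male"``/``"female"``;
    ``burden_score`` is the weighted clinical-burden composite in [0, 1].
    """

    age_norm: float
    time_requested_norm: float
    severity: int
    noncompliance: int
    substance_use: int
    sex: str
    legal_aid: int
    burden_score: float

    def __post_init__(self):
        for name in ("age_norm", "time_requested_norm", "burden_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name}={v} outside [0, 1]")
        for name in ("severity", "noncompliance", "substance_use", "legal_aid"):
            if getattr(self, name) not in (0, 1):
                raise DomainError(f"{name} must be 0 or 1")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex={self.sex!r}")


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

#: Atomic condition kinds understood by :func:`condition_degree`.
#:   flag       — crisp equality on a 0/1 field (or on sex)
#:   membership — degree of a linguistic label on a normalized field
#:   burden_ge  — crisp threshold on burden_score
_CONDITION_KINDS = ("flag", "membership", "burden_ge")


@dataclass(frozen=True)
class Condition:
    kind: str
    #: flag: input field name; membership: linguistic variable name
    subject: str
    #: flag: expected value (0/1 or "male"/"female"); membership: label;
    #: burden_ge: threshold
    value: object

    def __post_init__(self):
        if self.kind not in _CONDITION_KINDS:
            raise FuzzyConfigError(f"unknown condition kind {self.kind!r}")


@dataclass(frozen=True)
class FuzzyRule:
    """A weighted conjunctive rule: IF all conditions THEN consequent."""

    id: int
    description: str
    conditions: tuple[Condition, ...]
    consequent: str               # key into the consequent value map
    weight: float

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise FuzzyConfigError(f"rule {self.id}: weight {self.weight} "
                                   "outside (0, 1]")


@dataclass(frozen=True)
class RuleActivation:
    rule_id: int
    strength: float
    consequent: str
    weight: float


def _flag(subject: str, value) -> Condition:
    return Condition("flag", subject, value)


def _member(variable: str, label: str) -> Condition:
    return Condition("membership", variable, label)


#: Rule-antecedent field fuzzified by each linguistic variable.
_VARIABLE_FIELD = {"age": "age_norm", "time_requested": "time_requested_norm"}

#: Threshold above which Burden_Score counts as "high" in rule 6.
DEFAULT_BURDEN_THRESHOLD = 0.6


def default_rules() -> tuple[FuzzyRule, ...]:
    """The ten expert rules with their hand-assigned weights.

    Non-compliance is the flagged direction, so "compliant" /
    "history of prior compliance" / "no compliance issues" all read as
    ``noncompliance == 0``; "low severity" and "mild/moderate diagnosis"
    read as ``severity == 0``.
    """
    return (
        FuzzyRule(1, "Severe diagnosis AND non-compliance",
                  (_flag("severity", 1), _flag("noncompliance", 1)),
                  "High", 1.0),
        FuzzyRule(2, "Severe diagnosis AND history of prior compliance",
                  (_flag("severity", 1), _flag("noncompliance", 0)),
                  "Medium", 0.8),
        FuzzyRule(3, "Low severity AND compliant",
                  (_flag("severity", 0), _flag("noncompliance", 0)),
                  "Low", 1.0),
        FuzzyRule(4, "Young male WITH substance use AND long duration requested",
                  (_member("age", "Young"), _flag("sex", "male"),
                   _flag("substance_use", 1), _member("time_requested", "Long")),
                  "High", 0.8),
        FuzzyRule(5, "Older defendant WITH severe diagnosis AND compliance",
                  (_member("age", "Older"), _flag("severity", 1),
                   _flag("noncompliance", 0)),
                  "Medium", 0.7),
        FuzzyRule(6, "Female defendant WITH high Burden_Score",
                  (_flag("sex", "female"),
                   Condition("burden_ge", "burden_score",
                             DEFAULT_BURDEN_THRESHOLD)),
                  "MediumHigh", 0.6),
        FuzzyRule(7, "Short treatment duration AND legal aid support",
                  (_member("time_requested", "Short"), _flag("legal_aid", 1)),
                  "High", 0.7),
        FuzzyRule(8, "Severe diagnosis BUT short time requested AND no "
                     "compliance issues",
                  (_flag("severity", 1), _member("time_requested", "Short"),
                   _flag("noncompliance", 0)),
                  "Medium", 0.6),
        FuzzyRule(9, "Mild/moderate diagnosis WITH non-compliance",
                  (_flag("severity", 0), _flag("noncompliance", 1)),
                  "Medium", 0.5),
        FuzzyRule(10, "Severe diagnosis WITH substance use AND long time "
                      "requested",
                  (_flag("severity", 1), _flag("substance_use", 1),
                   _member("time_requested", "Long")),
                  "High", 1.0),
    )


#: Crisp representative value of each consequent label (calibrated; see
#: module docstring).
DEFAULT_CONSEQUENT_VALUES: dict[str, float] = {
    "Low": 0.17, "Medium": 0.50, "MediumHigh": 0.65, "High": 0.85,
}

#: Defuzzification thresholds: Low below the first, High above the second.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.4, 0.7)

#: Score reported when no rule fires at all.
NO_RULE_DEFAULT = 0.5


@dataclass(frozen=True)
class FuzzyConfig:
    """Complete, serializable configuration of the inference system."""

    variables: dict[str, dict[str, TriangularMF]] = field(
        default_factory=lambda: {v: dict(m) for v, m
                                 in DEFAULT_VARIABLES.items()})
    rules: tuple[FuzzyRule, ...] = field(default_factory=default_rules)
    consequent_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENT_VALUES))
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise FuzzyConfigError(f"duplicate rule ids: {ids}")
        vals = self.consequent_values
        order = ["Low", "Medium", "MediumHigh", "High"]
        present = [l for l in order if l in vals]
        seq = [vals[l] for l in present]
        if any(not 0 <= v <= 1 for v in seq) or seq != sorted(seq) or \
                len(set(seq)) != len(seq):
            raise FuzzyConfigError(
                f"consequent values must be strictly increasing in [0, 1] "
                f"over {present}: {seq}")
        low, high = self.thresholds
        if not 0 < low < high < 1:
            raise FuzzyConfigError(f"thresholds {self.thresholds} must satisfy "
                                   "0 < low_upper < high_lower < 1")
        for rule in self.rules:
            if rule.consequent not in vals:
                raise FuzzyConfigError(
                    f"rule {rule.id}: unknown consequent {rule.consequent!r}")
            for cond in rule.conditions:
                if cond.kind == "membership":
                    labels = self.variables.get(cond.subject, {})
                    if cond.value not in labels:
                        raise FuzzyConfigError(
                            f"rule {rule.id}: unknown label "
                            f"{cond.subject}.{cond.value}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": {v: {l: [mf.a, mf.b, mf.c] for l, mf in sets.items()}
                          for v, sets in self.variables.items()},
            "rules": [{"id": r.id, "description": r.description,
                       "conditions": [{"kind": c.kind, "subject": c.subject,
                                       "value": c.value}
                                      for c in r.conditions],
                       "consequent": r.consequent, "weight": r.weight}
                      for r in self.rules],
            "consequent_values": dict(self.consequent_values),
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FuzzyConfig":
        return cls(
            variables={v: {l: TriangularMF(*abc) for l, abc in sets.items()}
                       for v, sets in data["variables"].items()},
            rules=tuple(
                FuzzyRule(r["id"], r["description"],
                          tuple(Condition(c["kind"], c["subject"], c["value"])
                                for c in r["conditions"]),
                          r["consequent"], r["weight"])
                for r in data["rules"]),
            consequent_values=dict(data["consequent_values"]),
            thresholds=tuple(data["thresholds"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FuzzyConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def condition_degree(cond: Condition, inp: FuzzyInput,
                     variables: dict[str, dict[str, TriangularMF]]) -> float:
    """Degree in [0, 1] to which one atomic condition holds."""
    if cond.kind == "flag":
        return 1.0 if getattr(inp, cond.subject) == cond.value else 0.0
    if cond.kind == "burden_ge":
        return 1.0 if inp.burden_score >= cond.value else 0.0
    # membership
    try:
        mf = variables[cond.subject][cond.value]
    except KeyError as exc:
        raise FuzzyConfigError(
            f"unknown linguistic label {cond.subject}.{cond.value}") from exc
    x = getattr(inp, _VARIABLE_FIELD[cond.subject])
    return mf(x)


def rule_strength(rule: FuzzyRule, inp: FuzzyInput,
                  variables: dict[str, dict[str, TriangularMF]] | None = None,
                  ) -> float:
    """Firing strength of a rule: minimum over its condition degrees."""
    variables = variables if variables is not None else DEFAULT_VARIABLES
    return min(condition_degree(c, inp, variables) for c in rule.conditions)


def expanded_score(activations: Sequence[RuleActivation],
                   consequent_values: dict[str, float] | None = None) -> float:
    """Weighted mean of fired rules' crisp consequent values.

    Rules with zero strength contribute nothing; with no fired rule the
    neutral default 0.5 is returned.
    """
    values = consequent_values or DEFAULT_CONSEQUENT_VALUES
    num = 0.0
    den = 0.0
    for act in activations:
        if act.strength > 0:
            num += act.weight * act.strength * values[act.consequent]
            den += act.weight * act.strength
    if den == 0:
        return NO_RULE_DEFAULT
    return num / den


def categorize(score: float,
               thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Map a score to Low / Medium / High (boundaries count as Medium)."""
    if not 0 <= score <= 1:
        raise DomainError(f"score {score} outside [0, 1]")
    low_upper, high_lower = thresholds
    if score < low_upper:
        return "Low"
    if score > high_lower:
        return "High"
    return "Medium"


@dataclass(frozen=True)
class InferenceResult:
    score: float
    category: str
    trace: tuple[RuleActivation, ...]   # fired rules only, in rule-id order

    def format_trace(self) -> str:
        """Human-readable activation trace."""
        lines = [f"Rule {a.rule_id} (weight {a.weight:g}): "
                 f"strength {a.strength:.3f} -> {a.consequent}"
                 for a in self.trace]
        return "\n".join(lines) if lines else "(no rule fired)"


def infer(inp: FuzzyInput, config: FuzzyConfig | None = None) -> InferenceResult:
    """Run the full inference: strengths, score, category, trace.

    Deterministic; the trace lists every rule with nonzero strength in
    ascending rule-id order.
    """
    config = config or FuzzyConfig()
    activations = []
    for rule in sorted(config.rules, key=lambda r: r.id):
        s = rule_strength(rule, inp, config.variables)
        if s > 0:
            activations.append(RuleActivation(rule.id, s, rule.consequent,
                                              rule.weight))
    score = expanded_score(activations, config.consequent_values)
    return InferenceResult(score=score,
                           category=categorize(score, config.thresholds),
                           trace=tuple(activations))
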