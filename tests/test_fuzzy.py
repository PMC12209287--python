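"""The weighted-rule Mamdani engine: membership, rule strengths, score
aggregation, categorization, and exact agreement with a straight-line
oracle."""

import numpy as np
import pytest

from ordercast import (
    DEFAULT_CONSEQUENT_VALUES,
    FuzzyConfig,
    FuzzyInput,
    RuleActivation,
    TriangularMF,
    categorize,
    default_rules,
    expanded_score,
    infer,
    rule_strength,
    triangular_membership,
)
from ordercast.exceptions import DomainError, FuzzyConfigError

from _oracles import straightline_inference


def _input(**overrides):
    base = dict(age_norm=0.5, time_requested_norm=0.5, severity=0,
                noncompliance=0, substance_use=0, sex="male", legal_aid=0,
                burden_score=0.0)
    base.update(overrides)
    return FuzzyInput(**base)


RULES = {r.id: r for r in default_rules()}


# -- membership -------------------------------------------------------------

@pytest.mark.parametrize("x,abc,expected", [
    (0.5, (0.2, 0.5, 0.7), 1.0),            # peak
    (0.9, (0.0, 0.0, 0.3), 0.0),            # outside support
    (0.25, (0.2, 0.5, 0.7), (0.25 - 0.2) / 0.3),  # rising ramp
    (0.6, (0.2, 0.5, 0.7), 0.5),            # falling ramp
    (0.0, (0.0, 0.0, 0.3), 1.0),            # left shoulder flat end
    (1.0, (0.8, 1.0, 1.0), 1.0),            # right shoulder flat end
])
def test_triangular_membership(x, abc, expected):
    assert triangular_membership(x, TriangularMF(*abc)) == pytest.approx(
        expected, abs=1e-12)


def test_invalid_triangle_rejected():
    with pytest.raises(FuzzyConfigError):
        TriangularMF(0.5, 0.2, 0.7)


# -- rule strengths ---------------------------------------------------------

def test_rule1_fires_fully_for_severe_noncompliant():
    inp = _input(severity=1, noncompliance=1)
    assert rule_strength(RULES[1], inp) == 1.0
    # rule 2 requires prior compliance, i.e. noncompliance == 0
    assert rule_strength(RULES[2], inp) == 0.0


def test_rule4_takes_min_of_graded_and_crisp_conditions():
    # Young degree 0.5 at age_norm 0.15; Long degree 0.8 at norm 0.92
    inp = _input(age_norm=0.15, time_requested_norm=0.92, substance_use=1)
    assert rule_strength(RULES[4], inp) == pytest.approx(0.5, abs=1e-12)


def test_rule6_burden_threshold_is_crisp():
    assert rule_strength(RULES[6], _input(sex="female", burden_score=0.6)) == 1.0
    assert rule_strength(RULES[6], _input(sex="female", burden_score=0.59)) == 0.0
    assert rule_strength(RULES[6], _input(sex="male", burden_score=0.9)) == 0.0


# -- aggregation ------------------------------------------------------------

def test_single_fired_rule_yields_its_crisp_value():
    acts = [RuleActivation(1, 1.0, "High", 1.0)]
    assert expanded_score(acts) == pytest.approx(0.85)


def test_two_rule_weighted_mean():
    acts = [RuleActivation(3, 1.0, "Low", 1.0),
            RuleActivation(7, 1.0, "High", 0.7)]
    expected = (1.0 * 0.17 + 0.7 * 0.85) / 1.7
    assert expanded_score(acts) == pytest.approx(expected)
    assert expected == pytest.approx(0.45)


def test_no_fired_rule_gives_neutral_default():
    assert expanded_score([]) == 0.5
    assert expanded_score([RuleActivation(1, 0.0, "High", 1.0)]) == 0.5


@pytest.mark.parametrize("score,expected", [
    (0.85, "High"), (0.45, "Medium"), (0.0, "Low"),
    (0.4, "Medium"), (0.7, "Medium"),   # boundaries inclusive to Medium
    (0.39999, "Low"), (0.70001, "High"),
])
def test_categorize_thresholds(score, expected):
    assert categorize(score) == expected


def test_categorize_rejects_out_of_range():
    with pytest.raises(DomainError):
        categorize(1.2)


# -- full inference ---------------------------------------------------------

def test_severe_noncompliant_long_duration_case():
    inp = _input(severity=1, noncompliance=1, time_requested_norm=1.0,
                 legal_aid=1, burden_score=0.85)
    res = infer(inp)
    assert res.score == pytest.approx(0.85)
    assert res.category == "High"
    assert [a.rule_id for a in res.trace] == [1]


def test_compliant_short_duration_case():
    inp = _input(time_requested_norm=0.0, legal_aid=1)
    res = infer(inp)
    assert res.score == pytest.approx(0.45)
    assert res.category == "Medium"
    assert [a.rule_id for a in res.trace] == [3, 7]


def test_all_zero_input_fires_only_rule3():
    inp = _input(time_requested_norm=0.0)
    res = infer(inp)
    assert res.score == pytest.approx(0.17)
    assert res.category == "Low"
    assert [a.rule_id for a in res.trace] == [3]


# -- configuration ----------------------------------------------------------

def test_default_registry_weights():
    weights = {r.id: r.weight for r in default_rules()}
    assert weights == {1: 1.0, 2: 0.8, 3: 1.0, 4: 0.8, 5: 0.7,
                       6: 0.6, 7: 0.7, 8: 0.6, 9: 0.5, 10: 1.0}


def test_config_json_round_trip(tmp_path):
    cfg = FuzzyConfig()
    path = tmp_path / "fuzzy.json"
    cfg.to_json(path)
    again = FuzzyConfig.from_json(path)
    assert again == cfg
    assert len(again.rules) == 10


def test_config_rejects_nonincreasing_consequents():
    with pytest.raises(FuzzyConfigError):
        FuzzyConfig(consequent_values={"Low": 0.5, "Medium": 0.4,
                                       "MediumHigh": 0.65, "High": 0.85})


def test_config_rejects_unknown_label():
    import dataclasses

    from ordercast.fuzzy import Condition

    rule = default_rules()[0]
    bad = rule.conditions + (Condition("membership", "age", "Ancient"),)
    with pytest.raises(FuzzyConfigError):
        FuzzyConfig(rules=(dataclasses.replace(rule, conditions=bad),))


# -- properties -------------------------------------------------------------

def _random_inputs(n, seed):
    rng = np.random.default_rng(seed)
    special = [0.0, 1.0]
    for _ in range(n):
        pick = lambda: (rng.choice(special) if rng.random() < 0.15
                        else float(rng.random()))
        yield FuzzyInput(
            age_norm=pick(), time_requested_norm=pick(),
            severity=int(rng.integers(2)), noncompliance=int(rng.integers(2)),
            substance_use=int(rng.integers(2)),
            sex=str(rng.choice(["male", "female"])),
            legal_aid=int(rng.integers(2)), burden_score=pick())


def test_engine_matches_straightline_oracle_exactly():
    """1500 random profiles: score and fired-rule trace agree bit-for-bit
    with a direct enumeration of the ten rules."""
    for inp in _random_inputs(1500, seed=42):
        res = infer(inp)
        score, fired = straightline_inference(inp)
        assert res.score == score
        assert [a.rule_id for a in res.trace] == fired


def test_score_bounded_by_fired_crisp_values():
    values = DEFAULT_CONSEQUENT_VALUES
    for inp in _random_inputs(500, seed=7):
        res = infer(inp)
        fired_vals = [values[a.consequent] for a in res.trace]
        if fired_vals:
            assert min(fired_vals) - 1e-12 <= res.score <= max(fired_vals) + 1e-12
        assert 0 <= res.score <= 1


def test_increasing_one_strength_moves_score_toward_its_value():
    rng = np.random.default_rng(3)
    for _ in range(200):
        acts = [RuleActivation(i + 1, float(rng.random()), cons, w)
                for i, (cons, w) in enumerate(
                    zip(rng.choice(list(DEFAULT_CONSEQUENT_VALUES), 4),
                        rng.uniform(0.1, 1.0, 4)))]
        base = expanded_score(acts)
        k = int(rng.integers(4))
        target = DEFAULT_CONSEQUENT_VALUES[acts[k].consequent]
        bumped = acts.copy()
        s_new = min(1.0, acts[k].strength + 0.3)
        bumped[k] = RuleActivation(acts[k].rule_id, s_new,
                                   acts[k].consequent, acts[k].weight)
        moved = expanded_score(bumped)
        if target > base:
            assert moved >= base - 1e-12
        elif target < base:
            assert moved <= base + 1e-12


def test_score_invariant_under_registry_permutation():
    cfg = FuzzyConfig()
    permuted = FuzzyConfig(rules=tuple(reversed(cfg.rules)))
    for inp in _random_inputs(200, seed=5):
        assert infer(inp, permuted) == infer(inp, cfg)
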