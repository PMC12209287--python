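"""Independent straight-line re-implementations used as test oracles.

Deliberately free of any engine abstractions: plain arithmetic over the
ten rules, so a bug in the engine cannot hide in a shared code path.
"""


def tri(x, a, b, c):
    if x < a or x > c:
        return 0.0
    if x == b:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (c - x) / (c - b)


def straightline_inference(inp):
    """Score and fired-rule ids by direct enumeration of the ten rules."""
    young = tri(inp.age_norm, 0.0, 0.0, 0.3)
    older = tri(inp.age_norm, 0.8, 1.0, 1.0)
    short = tri(inp.time_requested_norm, 0.0, 0.0, 0.3)
    long_ = tri(inp.time_requested_norm, 0.6, 1.0, 1.0)
    sev = float(inp.severity)
    nc = float(inp.noncompliance)
    su = float(inp.substance_use)
    male = 1.0 if inp.sex == "male" else 0.0
    female = 1.0 - male
    la = float(inp.legal_aid)
    high_burden = 1.0 if inp.burden_score >= 0.6 else 0.0

    strengths = {
        1: min(sev, nc),
        2: min(sev, 1.0 - nc),
        3: min(1.0 - sev, 1.0 - nc),
        4: min(young, male, su, long_),
        5: min(older, sev, 1.0 - nc),
        6: min(female, high_burden),
        7: min(short, la),
        8: min(sev, short, 1.0 - nc),
        9: min(1.0 - sev, nc),
        10: min(sev, su, long_),
    }
    weights = {1: 1.0, 2: 0.8, 3: 1.0, 4: 0.8, 5: 0.7,
               6: 0.6, 7: 0.7, 8: 0.6, 9: 0.5, 10: 1.0}
    crisp = {1: 0.85, 2: 0.50, 3: 0.17, 4: 0.85, 5: 0.50,
             6: 0.65, 7: 0.85, 8: 0.50, 9: 0.50, 10: 0.85}

    num = 0.0
    den = 0.0
    fired = []
    for i in range(1, 11):
        s = strengths[i]
        if s > 0:
            fired.append(i)
            num += weights[i] * s * crisp[i]
            den += weights[i] * s
    score = 0.5 if den == 0 else num / den
    return score, fired
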