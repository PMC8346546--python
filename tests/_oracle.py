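"""Naive reference Mamdani implementation, independent of the package's
vectorised controller.

Everything is computed the slow, explicit way: membership by a hand-rolled
piecewise-linear scan, "any one or more" / "any two or more" combinators by
literal enumeration of all qualifying clause subsets (OR over conjunctions),
and defuzzification as the plain weighted mean over fired rules.
"""

from itertools import combinations


def interp_membership(points, x):
    """Piecewise-linear membership by explicit segment scan."""
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        if x0 <= x <= x1:
            return y0 + (x - x0) * (y1 - y0) / (x1 - x0)
    raise AssertionError("unreachable")


def fuzzify_all(inputs, values):
    """input name -> {level -> degree} for every registered input."""
    fuzzified = {}
    for name, linput in inputs.items():
        if linput.crisp:
            degrees = {
                linput.levels[0].name: 1.0 if values[name] == 0 else 0.0,
                linput.levels[1].name: 1.0 if values[name] == 1 else 0.0,
            }
        else:
            degrees = {mf.name: interp_membership(mf.points, values[name]) for mf in linput.levels}
        fuzzified[name] = degrees
    return fuzzified


def clause_degree(clause, inputs, fuzzified):
    all_levels = inputs[clause.input].level_names
    allowed = clause.allowed(all_levels)
    return max(fuzzified[clause.input][level] for level in allowed)


def rule_strength(rule, inputs, fuzzified):
    """Firing strength by literal combinator expansion."""
    if not rule.clauses:
        return 1.0
    degrees = [clause_degree(c, inputs, fuzzified) for c in rule.clauses]
    if rule.combinator == "all":
        return min(degrees)
    min_size = 1 if rule.combinator == "any" else 2
    best = 0.0
    for size in range(min_size, len(degrees) + 1):
        for subset in combinations(degrees, size):
            best = max(best, min(subset))
    return best


def evaluate(controller, values):
    """Full Mamdani pass; returns action -> crisp output."""
    inputs = controller.inputs
    fuzzified = fuzzify_all(inputs, values)
    num = {}
    den = {}
    for rule in controller.rule_base.rules:
        strength = rule_strength(rule, inputs, fuzzified)
        rep = controller.rule_base.scales[rule.action].rep(rule.level)
        num[rule.action] = num.get(rule.action, 0.0) + strength * rep
        den[rule.action] = den.get(rule.action, 0.0) + strength
    out = {}
    for action, scale in controller.rule_base.scales.items():
        d = den.get(action, 0.0)
        out[action] = num[action] / d if d > 0 else controller.default_output
    return out
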