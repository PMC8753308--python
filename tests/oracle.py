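"""Independent brute-force predicate evaluator used as a cross-check.

Deliberately written from scratch against the rule semantics, sharing no
evaluation code with gmfpm.rules: plain dict walking and explicit loops.
"""

from __future__ import annotations


def oracle_evaluate(statement, features, model, closed_world=True) -> str:
    """Return 'match' / 'no_match' / 'missing' for one statement."""
    var = None
    for v in model.variables:
        if v.name == statement.variable:
            var = v
            break
    assert var is not None

    if var.name in features.missing_variables:
        return "missing"
    value = features.values.get(var.name)
    if value is None or value == {}:
        return "missing"

    p = statement.predicate
    if p.kind == "membership":
        wanted = list(p.tokens or [])
        if isinstance(value, str):
            return "match" if value in wanted else "no_match"
        hit = False
        for element_name, token in value.items():
            if token == "Yes" and element_name in wanted:
                hit = True
        return "match" if hit else "no_match"

    # count_threshold / all_of over per-element binary values
    n_elements = len(var.elements)
    n_observed = len(value)
    if not closed_world and n_observed < n_elements:
        return "missing"

    if p.kind == "count_threshold":
        positives = 0
        for token in value.values():
            if token == p.positive_token:
                positives += 1
        if p.comparator == "eq":
            ok = positives == p.k
        elif p.comparator == "ge":
            ok = positives >= p.k
        else:
            ok = positives <= p.k
        return "match" if ok else "no_match"

    # all_of: every element must carry the token; unobserved elements are
    # imputed "No" under the closed world.
    for token in value.values():
        if token != p.token:
            return "no_match"
    if n_observed < n_elements and p.token != "No":
        return "no_match"
    return "match"
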