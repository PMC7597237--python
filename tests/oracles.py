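"""Independent brute-force oracles, kept free of pathpid internals.

Everything here works on a plain ``{state tuple: probability}`` dict plus a
variable-name list, using explicit Python loops and ``math.log2`` so the
oracles share no code path with the package they check.
"""

from __future__ import annotations

import math
from itertools import permutations


def dict_from_pmf(pmf) -> tuple[list[str], dict[tuple, float]]:
    """Flatten a JointPMF into (variables, {state: prob}) without using its API."""
    from itertools import product

    variables = list(pmf.variables)
    states = {}
    for state, p in zip(product(*pmf.alphabets), pmf.table.ravel()):
        if p > 0:
            states[state] = float(p)
    return variables, states


def _group_value(variables, state, group):
    if isinstance(group, str):
        group = (group,)
    return tuple(state[variables.index(v)] for v in group)


def brute_marginal(variables, states, group) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for state, p in states.items():
        key = _group_value(variables, state, group)
        out[key] = out.get(key, 0.0) + p
    return out


def brute_entropy(states) -> float:
    return -sum(p * math.log2(p) for p in states.values() if p > 0)


def brute_mi(variables, states, ga, gb) -> float:
    pa = brute_marginal(variables, states, ga)
    pb = brute_marginal(variables, states, gb)
    pab: dict[tuple, float] = {}
    for state, p in states.items():
        key = (_group_value(variables, state, ga), _group_value(variables, state, gb))
        pab[key] = pab.get(key, 0.0) + p
    total = 0.0
    for (a, b), p in pab.items():
        total += p * math.log2(p / (pa[a] * pb[b]))
    return total


def brute_cmi(variables, states, ga, gb, gc) -> float:
    """I(A;B|C) by stratifying on C and weighting per-stratum MIs."""
    pc = brute_marginal(variables, states, gc)
    total = 0.0
    for c, pcv in pc.items():
        stratum = {
            s: p / pcv
            for s, p in states.items()
            if _group_value(variables, s, gc) == c
        }
        total += pcv * brute_mi(variables, stratum, ga, gb)
    return total


def brute_channel(variables, states, src, dst) -> dict[tuple, dict[tuple, float]]:
    """p(dst|src) as nested dicts; rows only for positive-mass source states."""
    ps = brute_marginal(variables, states, src)
    joint: dict[tuple, dict[tuple, float]] = {}
    for state, p in states.items():
        a = _group_value(variables, state, src)
        b = _group_value(variables, state, dst)
        joint.setdefault(a, {})[b] = joint.get(a, {}).get(b, 0.0) + p
    return {a: {b: v / ps[a] for b, v in row.items()} for a, row in joint.items()}


def brute_path_mi(variables, states, nodes) -> float:
    """Path MI via step-by-step channel multiplication on dicts.

    ``nodes`` is a sequence of groups; adjacent equal groups use an exact
    identity channel.
    """
    def as_g(g):
        return (g,) if isinstance(g, str) else tuple(g)

    nodes = [as_g(n) for n in nodes]
    tensor = None  # dict src_state -> dict node_state -> prob
    p_src = brute_marginal(variables, states, nodes[0])
    tensor = {a: {a: 1.0} for a in p_src}
    for a, b in zip(nodes[:-1], nodes[1:]):
        if a == b:
            step = {s: {s: 1.0} for s in brute_marginal(variables, states, a)}
        else:
            step = brute_channel(variables, states, a, b)
        new: dict[tuple, dict[tuple, float]] = {}
        for x, row in tensor.items():
            acc: dict[tuple, float] = {}
            for mid, w in row.items():
                for y, q in step.get(mid, {}).items():
                    acc[y] = acc.get(y, 0.0) + w * q
            new[x] = acc
        tensor = new
    # propagated joint and target marginal
    joint = {
        (x, z): p_src[x] * w for x, row in tensor.items() for z, w in row.items()
    }
    p_tgt: dict[tuple, float] = {}
    for (x, z), p in joint.items():
        p_tgt[z] = p_tgt.get(z, 0.0) + p
    total = 0.0
    for (x, z), p in joint.items():
        if p > 0:
            total += p * math.log2(tensor[x][z] / p_tgt[z])
    return total


def brute_redundancy(variables, states, sources, target, admissible=None) -> float:
    """Min path MI over all source permutations (or a given admissible set)."""
    if admissible is None:
        admissible = [
            tuple(perm) + (target,) for perm in permutations(sources)
        ]
    if not admissible:
        return 0.0
    return min(brute_path_mi(variables, states, nodes) for nodes in admissible)


def brute_imin(variables, states, sources, target) -> float:
    pt = brute_marginal(variables, states, target)
    total = 0.0
    for z, pz in pt.items():
        best = None
        for src in sources:
            pa = brute_marginal(variables, states, src)
            joint = {}
            for s, p in states.items():
                a = _group_value(variables, s, src)
                t = _group_value(variables, s, target)
                if t == z:
                    joint[a] = joint.get(a, 0.0) + p
            spec = sum(
                (paz / pz) * math.log2((paz / pa[a]) / pz) for a, paz in joint.items()
            )
            best = spec if best is None else min(best, spec)
        total += pz * best
    return total
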