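"""Programmatic reconstruction of reference distributions and generators.

Every named distribution is built with exact rational arithmetic
(:class:`fractions.Fraction`) and converted to floats only at the
:class:`~pathpid.pmf.JointPMF` boundary, so printed fractions such as 5/6
or 5/12 are reproduced bit-exactly downstream.

Random-system generators draw row-stochastic channels along a DAG and
propagate a root pmf, giving valid joint pmfs that honor the Markov
assumptions; they are deterministic per seed.
"""

from __future__ import annotations

import re
from fractions import Fraction
from itertools import product

import numpy as np

from .errors import InputError
from .pmf import JointPMF

F = Fraction


def _pmf(variables, states, alphabets=None) -> JointPMF:
    return JointPMF.from_states(variables, states, alphabets=alphabets)


# ---------------------------------------------------------------------------
# boolean machinery over hidden uniform bits
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"w\d+|and|or|not|xor|[()\s]|[01]|&|\||\^|~", re.IGNORECASE)


def _compile_formula(expr: str, n_hidden: int):
    """Validate and normalize a boolean formula over hidden bits W1..Wk."""
    if not isinstance(expr, str) or not expr.strip():
        raise InputError(f"malformed boolean formula: {expr!r}")
    pos = 0
    for m in _FORMULA_TOKEN.finditer(expr):
        if m.start() != pos:
            raise InputError(f"malformed boolean formula {expr!r} near {expr[pos:]!r}")
        pos = m.end()
    if pos != len(expr):
        raise InputError(f"malformed boolean formula {expr!r} near {expr[pos:]!r}")

    def keyword(m):
        word = m.group(0).lower()
        return {"and": "and", "or": "or", "not": "not", "xor": "^"}.get(word, word)

    norm = re.sub(r"(?i)\b(and|or|not|xor)\b", keyword, expr)
    for m in re.finditer(r"(?i)\bw(\d+)\b", expr):
        if not 1 <= int(m.group(1)) <= n_hidden:
            raise InputError(
                f"formula {expr!r} references W{m.group(1)} but only {n_hidden} hidden bits exist"
            )
    norm = re.sub(r"(?i)\bw(\d+)\b", lambda m: f"w{m.group(1)}", norm)
    try:
        code = compile(norm, "<formula>", "eval")
    except SyntaxError as exc:
        raise InputError(f"malformed boolean formula: {expr!r}") from exc

    def run(bits: tuple[int, ...]) -> int:
        env = {f"w{i + 1}": bits[i] for i in range(n_hidden)}
        return int(bool(eval(code, {"__builtins__": {}}, env)))

    return run


def hidden_cause_system(
    boolean_spec: dict[str, str],
    n_hidden: int = 2,
    hidden_name: str = "W",
    marginalize_hidden: bool = True,
) -> JointPMF:
    """Observed variables as boolean functions of uniform hidden bits.

    ``boolean_spec`` maps each observed variable name to a formula over the
    hidden bits ``W1 .. Wk`` (operators: And/Or/Not/Xor, case-insensitive,
    or ``& | ~ ^``).  With ``marginalize_hidden=False`` the hidden word is
    kept as an extra variable whose symbols are bit strings.
    """
    if not boolean_spec:
        raise InputError("boolean_spec must define at least one variable")
    funcs = {
        name: _compile_formula(expr, n_hidden) for name, expr in boolean_spec.items()
    }
    variables = list(boolean_spec)
    states: dict[tuple, Fraction] = {}
    weight = F(1, 2 ** n_hidden)
    for bits in product((0, 1), repeat=n_hidden):
        obs = tuple(funcs[name](bits) for name in variables)
        if marginalize_hidden:
            key = obs
        else:
            key = obs + ("".join(map(str, bits)),)
        states[key] = states.get(key, F(0)) + weight
    alphabets: list = [(0, 1)] * len(variables)
    names = list(variables)
    if not marginalize_hidden:
        names.append(hidden_name)
        alphabets.append(
            tuple("".join(map(str, bits)) for bits in product((0, 1), repeat=n_hidden))
        )
    return _pmf(names, states, alphabets=alphabets)


# ---------------------------------------------------------------------------
# named reference distributions
# ---------------------------------------------------------------------------

def _two_bit_copy() -> JointPMF:
    states = {
        (x, y, f"{x}{y}"): F(1, 4) for x in (0, 1) for y in (0, 1)
    }
    z_alpha = ("00", "01", "10", "11")
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), z_alpha))


def _common_cause_3var() -> JointPMF:
    return hidden_cause_system(
        {"X": "W1", "Y": "W1 Or W2", "Z": "W1 And W2"}, marginalize_hidden=True
    )


def _common_cause_4var() -> JointPMF:
    return hidden_cause_system(
        {"X": "W1", "Y": "W1 Or W2", "Z": "W1 And W2"}, marginalize_hidden=False
    )


def _neg_synergy_3var() -> JointPMF:
    return hidden_cause_system(
        {"X": "W1 And W2", "Y": "W1 And (Not W2)", "Z": "W2"},
        marginalize_hidden=True,
    )


def _neg_synergy_4var() -> JointPMF:
    return hidden_cause_system(
        {"X": "W1 And W2", "Y": "W1 And (Not W2)", "Z": "W2"},
        marginalize_hidden=False,
    )


def _dyadic() -> JointPMF:
    rows = [
        (0, 0, 0), (0, 2, 1), (1, 0, 2), (1, 2, 3),
        (2, 1, 0), (2, 3, 1), (3, 1, 2), (3, 3, 3),
    ]
    states = {r: F(1, 8) for r in rows}
    alpha = (0, 1, 2, 3)
    return _pmf(("X", "Y", "Z"), states, alphabets=(alpha, alpha, alpha))


def _triadic() -> JointPMF:
    rows = [
        (0, 0, 0), (1, 1, 1), (0, 2, 2), (1, 3, 3),
        (2, 0, 2), (3, 1, 3), (2, 2, 0), (3, 3, 1),
    ]
    states = {r: F(1, 8) for r in rows}
    alpha = (0, 1, 2, 3)
    return _pmf(("X", "Y", "Z"), states, alphabets=(alpha, alpha, alpha))


def _pwunq() -> JointPMF:
    rows = [(0, 1, 1), (1, 0, 1), (0, 2, 2), (2, 0, 2)]
    states = {r: F(1, 4) for r in rows}
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1, 2), (0, 1, 2), (1, 2)))


def _5a() -> JointPMF:
    states = {(0, 0, 0): F(1, 3), (0, 1, 1): F(1, 3), (1, 0, 2): F(1, 3)}
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1, 2)))


def _5b() -> JointPMF:
    states = {
        (0, 0, 0): F(1, 4), (0, 1, 1): F(1, 4),
        (1, 0, 2): F(1, 4), (1, 1, 1): F(1, 4),
    }
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1, 2)))


def _5c() -> JointPMF:
    # six printed rows, two of which repeat the (x, y) pair; repeated state
    # rows accumulate, which is the only consistent verbatim reading
    rows = [
        ((0, 0, 0), F(1, 6)), ((0, 1, 1), F(1, 6)), ((1, 0, 2), F(1, 6)),
        ((1, 1, 0), F(1, 6)), ((0, 1, 1), F(1, 6)), ((1, 1, 1), F(1, 6)),
    ]
    states: dict[tuple, Fraction] = {}
    for state, p in rows:
        states[state] = states.get(state, F(0)) + p
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1, 2)))


def _reduced_or() -> JointPMF:
    states = {(0, 0, 0): F(1, 2), (0, 1, 1): F(1, 4), (1, 0, 1): F(1, 4)}
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1)))


def _binary_op(op) -> JointPMF:
    states = {
        (x, y, op(x, y)): F(1, 4) for x in (0, 1) for y in (0, 1)
    }
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1)))


def _sum_dist() -> JointPMF:
    states = {
        (x, y, x + y): F(1, 4) for x in (0, 1) for y in (0, 1)
    }
    return _pmf(("X", "Y", "Z"), states, alphabets=((0, 1), (0, 1), (0, 1, 2)))


_NAMED = {
    "two_bit_copy": _two_bit_copy,
    "common_cause_3var": _common_cause_3var,
    "common_cause_4var": _common_cause_4var,
    "neg_synergy_3var": _neg_synergy_3var,
    "neg_synergy_4var": _neg_synergy_4var,
    "dyadic": _dyadic,
    "triadic": _triadic,
    "pwunq": _pwunq,
    "5a": _5a,
    "5b": _5b,
    "5c": _5c,
    "reduced_or": _reduced_or,
    "xor": lambda: _binary_op(lambda x, y: x ^ y),
    "and": lambda: _binary_op(lambda x, y: x & y),
    "or": lambda: _binary_op(lambda x, y: x | y),
    "sum": _sum_dist,
}

FIXTURE_NAMES = tuple(sorted(_NAMED))


def named_distribution(name: str) -> JointPMF:
    """Return one of the built-in reference distributions by name."""
    try:
        builder = _NAMED[name.lower()]
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# random systems
# ---------------------------------------------------------------------------

_DEFAULT_NAMES = ("X", "Y", "Z", "W")


def _var_names(n: int) -> tuple[str, ...]:
    if n <= len(_DEFAULT_NAMES):
        return _DEFAULT_NAMES[:n]
    return tuple(f"V{i + 1}" for i in range(n))


def random_channel_system(
    n_vars: int,
    alphabet_sizes=2,
    edge_density: float = 1.0,
    seed: int = 0,
    edges: list[tuple[int, int]] | None = None,
) -> JointPMF:
    """Random joint pmf from a random DAG with Dirichlet channels.

    Variables are topologically ordered; each candidate edge ``i -> j``
    (``i < j``) is kept with probability ``edge_density`` unless an explicit
    ``edges`` list is given.  Each variable's conditional rows (one per
    joint parent state) are Dirichlet(1) draws; roots get Dirichlet
    marginals.  Deterministic per seed.
    """
    if n_vars < 2:
        raise InputError("need at least two variables")
    if isinstance(alphabet_sizes, int):
        sizes = [alphabet_sizes] * n_vars
    else:
        sizes = list(alphabet_sizes)
    if len(sizes) != n_vars or any(s < 2 for s in sizes):
        raise InputError("alphabet sizes must give every variable >= 2 symbols")
    rng = np.random.default_rng(seed)
    if edges is None:
        edges = [
            (i, j)
            for i in range(n_vars)
            for j in range(i + 1, n_vars)
            if rng.random() < edge_density
        ]
    else:
        for i, j in edges:
            if not (0 <= i < j < n_vars):
                raise InputError(f"edge {(i, j)!r} is not topological")
    parents = [sorted(i for i, j in edges if j == k) for k in range(n_vars)]
    conditionals = []
    for k in range(n_vars):
        n_parent_states = int(np.prod([sizes[p] for p in parents[k]])) if parents[k] else 1
        conditionals.append(rng.dirichlet(np.ones(sizes[k]), size=n_parent_states))
    table = np.zeros(tuple(sizes))
    for state in np.ndindex(*sizes):
        p = 1.0
        for k in range(n_vars):
            if parents[k]:
                row = int(
                    np.ravel_multi_index(
                        tuple(state[q] for q in parents[k]),
                        tuple(sizes[q] for q in parents[k]),
                    )
                )
            else:
                row = 0
            p *= conditionals[k][row][state[k]]
        table[state] = p
    names = _var_names(n_vars)
    alphabets = tuple(tuple(range(s)) for s in sizes)
    return JointPMF(names, alphabets, table)


def random_markov_chain(
    alphabet_sizes=(2, 2, 2), seed: int = 0
) -> JointPMF:
    """Random chain system V1 -> V2 -> ... -> Vn (X -> Y -> Z for n = 3)."""
    sizes = list(alphabet_sizes) if not isinstance(alphabet_sizes, int) else [alphabet_sizes] * 3
    chain_edges = [(i, i + 1) for i in range(len(sizes) - 1)]
    return random_channel_system(
        len(sizes), sizes, seed=seed, edges=chain_edges
    )
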