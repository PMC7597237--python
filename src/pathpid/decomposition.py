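"""Path-based partial information decomposition.

Redundancy is the minimum path-based mutual information over all admissible
paths that visit every source once and end at the target; unique
information is the per-source mutual information minus the redundancy; and
synergy is the additivity remainder, so

    I(sources-join; target) = U_1 + U_2 + R + S

holds exactly by construction.  Cumulative redundancy values live on the
Williams-Beer lattice of source antichains and partial-information atoms
are recovered by Moebius inversion.  The classical Imin redundancy is
provided as an independent reference measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .channels import channel_from_joint, compose
from .errors import DiagnosticError, InputError
from .paths import Path, path_mutual_information
from .pmf import JointPMF, as_group
from .structure import SystemGraph, enumerate_redundancy_paths, infer_graph

NEG_TOL = 1e-9


# ---------------------------------------------------------------------------
# redundancy / unique / synergy
# ---------------------------------------------------------------------------

def _join(groups: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    out: list[str] = []
    for g in groups:
        for v in g:
            if v not in out:
                out.append(v)
    return tuple(out)


def path_redundancy(
    pmf: JointPMF,
    sources,
    target,
    graph: SystemGraph | None = None,
    tol: float = 1e-9,
    strict: bool = False,
    return_paths: bool = False,
):
    """Path-based redundancy of a set of sources about a target, in bits.

    For a single source this is the self-redundancy realized through the
    Kronecker-delta path ``{X}{X}{target}``, which equals I(X;target).  For
    several sources it is the minimum path MI over the admissible source
    permutations; an empty admissible set yields 0 (independent sources
    share nothing through indirect paths).
    """
    groups = [as_group(s) for s in sources]
    tgt = as_group(target)
    for g in groups:
        if set(g) == set(tgt):
            raise InputError("target may not be listed as a source")
    if graph is None:
        graph = infer_graph(pmf, tol)
    if len(groups) == 1:
        path = Path((groups[0], groups[0], tgt))
        used = [(path, path_mutual_information(pmf, path))]
        value = used[0][1]
    else:
        paths = enumerate_redundancy_paths(graph, groups, tgt, strict=strict)
        used = [(p, path_mutual_information(pmf, p)) for p in paths]
        value = min((mi for _, mi in used), default=0.0)
    if return_paths:
        return value, used
    return value


def unique_information(
    pmf: JointPMF,
    source,
    other_sources,
    target,
    graph: SystemGraph | None = None,
    tol: float = 1e-9,
    strict: bool = False,
) -> float:
    """U(source; target) = I(source; target) - R(all sources; target).

    A value below ``-tol`` raises :class:`DiagnosticError` (it signals
    inconsistent inputs, not a quantity to clip); smaller negative dust is
    clipped to 0.
    """
    src = as_group(source)
    others = [as_group(s) for s in as_sources(other_sources)]
    tgt = as_group(target)
    if graph is None:
        graph = infer_graph(pmf, tol)
    r = path_redundancy(pmf, [src] + others, tgt, graph=graph, tol=tol, strict=strict)
    u = pmf._mi_groups(src, tgt) - r
    if u < -tol:
        raise DiagnosticError(
            f"unique information of {src!r} is {u:.6g} < 0: inconsistent inputs"
        )
    return max(u, 0.0)


def as_sources(sources) -> list:
    """Normalize a sources argument to a list of group specs."""
    if isinstance(sources, str):
        return [sources]
    return list(sources)


def synergy(
    pmf: JointPMF,
    sources,
    target,
    graph: SystemGraph | None = None,
    tol: float = 1e-9,
    strict: bool = False,
) -> float:
    """Synergy as the additivity remainder; may be negative.

    ``S = I(join; target) - U_1 - U_2 - R``.  Negative synergy is a
    diagnostic signal (e.g. an unobserved common cause), not an error.
    """
    groups = [as_group(s) for s in as_sources(sources)]
    if len(groups) != 2:
        raise InputError("the numeric decomposition supports exactly two sources")
    tgt = as_group(target)
    if graph is None:
        graph = infer_graph(pmf, tol)
    r = path_redundancy(pmf, groups, tgt, graph=graph, tol=tol, strict=strict)
    total = pmf._mi_groups(_join(groups), tgt)
    i1 = pmf._mi_groups(groups[0], tgt)
    i2 = pmf._mi_groups(groups[1], tgt)
    # S = total - (i1 - r) - (i2 - r) - r
    return total - i1 - i2 + r


# ---------------------------------------------------------------------------
# redundancy lattice
# ---------------------------------------------------------------------------

Node = frozenset  # frozenset of frozenset[int]


def _node_label(node: Node) -> str:
    cols = sorted(node, key=lambda c: (len(c), sorted(c)))
    return "".join("{" + "".join(str(i) for i in sorted(c)) + "}" for c in cols)


@dataclass(frozen=True, eq=False)
class Lattice:
    """The redundancy lattice: antichains of non-empty source subsets.

    ``alpha <= beta`` iff every collection in beta contains some collection
    in alpha.  ``nodes`` are listed bottom-up (topologically sorted, ties
    broken by label), so cumulative-value tuples in that order are
    unambiguous.
    """

    n_sources: int
    nodes: tuple[Node, ...]

    @staticmethod
    def leq(a: Node, b: Node) -> bool:
        return all(any(c <= col for c in a) for col in b)

    def strictly_below(self, node: Node) -> tuple[Node, ...]:
        return tuple(m for m in self.nodes if m != node and self.leq(m, node))

    @property
    def bottom(self) -> Node:
        return self.nodes[0]

    @property
    def top(self) -> Node:
        return self.nodes[-1]

    def label(self, node: Node) -> str:
        return _node_label(node)

    def node_from_label(self, label: str) -> Node:
        for node in self.nodes:
            if _node_label(node) == label:
                return node
        raise InputError(f"no lattice node labeled {label!r}")

    def covers(self) -> list[tuple[Node, Node]]:
        """Hasse-diagram edges (lower, upper)."""
        out = []
        for a in self.nodes:
            for b in self.nodes:
                if a is b or not self.leq(a, b) or self.leq(b, a):
                    continue
                if any(
                    self.leq(a, c) and self.leq(c, b) and c not in (a, b)
                    for c in self.nodes
                ):
                    continue
                out.append((a, b))
        return out


def build_lattice(n_sources: int) -> Lattice:
    """Enumerate the redundancy lattice for 2 or 3 sources.

    Nodes are the antichains of non-empty subsets of the source index set:
    4 nodes for two sources, 18 for three.
    """
    if n_sources not in (2, 3):
        raise InputError("redundancy lattices are supported for 2 or 3 sources")
    base = list(range(1, n_sources + 1))
    subsets = [
        frozenset(c)
        for r in range(1, n_sources + 1)
        for c in combinations(base, r)
    ]
    antichains: list[Node] = []
    for r in range(1, len(subsets) + 1):
        for combo in combinations(subsets, r):
            if all(
                not (a < b or b < a) for a, b in combinations(combo, 2)
            ):
                antichains.append(frozenset(combo))
    depth = {
        node: sum(Lattice.leq(m, node) for m in antichains) for node in antichains
    }
    antichains.sort(key=lambda node: (depth[node], _node_label(node)))
    return Lattice(n_sources, tuple(antichains))


def moebius_atoms(lattice: Lattice, cumulative: Mapping) -> dict:
    """Partial-information atoms from cumulative lattice values.

    ``atom(node) = cumulative(node) - sum of atoms strictly below``; summing
    the atoms back up reproduces the cumulative values exactly.  Keys of
    ``cumulative`` may be nodes or their labels.
    """
    values: dict[Node, float] = {}
    for key, val in cumulative.items():
        node = lattice.node_from_label(key) if isinstance(key, str) else key
        values[node] = float(val)
    missing = [lattice.label(n) for n in lattice.nodes if n not in values]
    if missing:
        raise InputError(f"missing cumulative values for nodes {missing}")
    atoms: dict[Node, float] = {}
    for node in lattice.nodes:  # bottom-up order
        below = lattice.strictly_below(node)
        atoms[node] = values[node] - sum(atoms[m] for m in below)
    return atoms


def lattice_cumulative_values(
    pmf: JointPMF,
    sources,
    target,
    graph: SystemGraph | None = None,
    tol: float = 1e-9,
    strict: bool = False,
) -> dict:
    """Cumulative redundancy per lattice node for 2 or 3 sources.

    Single-collection nodes use self-redundancy of the (joint) collection;
    multi-collection nodes apply the path-based redundancy to the
    collections as sources.  The three-source lattice is experimental
    plumbing: values are well-defined but no reference decompositions exist.
    """
    groups = [as_group(s) for s in as_sources(sources)]
    tgt = as_group(target)
    lattice = build_lattice(len(groups))
    if graph is None:
        graph = infer_graph(pmf, tol)
    values: dict[Node, float] = {}
    for node in lattice.nodes:
        collections = [
            _join([groups[i - 1] for i in sorted(col)]) for col in node
        ]
        values[node] = path_redundancy(
            pmf, collections, tgt, graph=graph, tol=tol, strict=strict
        )
    return values


# ---------------------------------------------------------------------------
# full two-source decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class PIDResult:
    """Two-source decomposition with its lattice atoms."""

    sources: tuple[tuple[str, ...], ...]
    target: tuple[str, ...]
    redundancy: float
    unique: dict  # source group -> bits
    synergy: float
    total: float
    paths_used: tuple  # (Path, path MI) pairs considered for redundancy
    lattice: Lattice
    cumulative: dict  # label -> bits
    atoms: dict  # label -> bits ({12} synergy, {1}/{2} unique, {1}{2} redundancy)

    @property
    def has_negative_atom(self) -> bool:
        return any(v < -NEG_TOL for v in self.atoms.values())

    def additivity_residual(self) -> float:
        return self.total - (
            sum(self.unique.values()) + self.redundancy + self.synergy
        )


def decompose(
    pmf: JointPMF,
    sources,
    target,
    tol: float = 1e-9,
    strict: bool = False,
    graph: SystemGraph | None = None,
) -> PIDResult:
    """Run the full two-source path-based PID.

    Infers the association graph, enumerates admissible redundancy paths,
    and returns redundancy, per-source unique information, and synergy,
    together with the populated two-source lattice.
    """
    groups = [as_group(s) for s in as_sources(sources)]
    if len(groups) != 2:
        raise InputError("decompose supports exactly two sources (groups allowed)")
    tgt = as_group(target)
    if graph is None:
        graph = infer_graph(pmf, tol)
    r, used = path_redundancy(
        pmf, groups, tgt, graph=graph, tol=tol, strict=strict, return_paths=True
    )
    i1 = pmf._mi_groups(groups[0], tgt)
    i2 = pmf._mi_groups(groups[1], tgt)
    total = pmf._mi_groups(_join(groups), tgt)
    uniques = {}
    for g, i_g in zip(groups, (i1, i2)):
        u = i_g - r
        if u < -tol:
            raise DiagnosticError(
                f"unique information of {g!r} is {u:.6g} < 0: inconsistent inputs"
            )
        uniques[g] = max(u, 0.0)
    s = total - i1 - i2 + r
    lattice = build_lattice(2)
    cumulative = {"{1}{2}": r, "{1}": i1, "{2}": i2, "{12}": total}
    atoms_by_node = moebius_atoms(lattice, cumulative)
    atoms = {lattice.label(n): v for n, v in atoms_by_node.items()}
    return PIDResult(
        sources=tuple(groups),
        target=tgt,
        redundancy=r,
        unique=uniques,
        synergy=s,
        total=total,
        paths_used=tuple(used),
        lattice=lattice,
        cumulative=cumulative,
        atoms=atoms,
    )


# ---------------------------------------------------------------------------
# diagnostics and reference measures
# ---------------------------------------------------------------------------

def unique_eq25_diagnostic(
    pmf: JointPMF, source, target, other=None
) -> tuple[float, float]:
    """Two divergence sums probing where unique information can come from.

    The first sum measures the divergence between the direct channel
    ``source -> target`` and the indirect cascade through the other source;
    it vanishes when the association is indirect.  The second compares the
    direct channel with the cascade entering through the other source; it
    vanishes when the two sources are copies of each other.  Both brackets
    are read as log-ratios of direct to indirect tensors.  Diagnostic only;
    the primary unique information comes from the decomposition equations.
    """
    src = as_group(source)
    tgt = as_group(target)
    if other is None:
        rest = [v for v in pmf.variables if v not in src + tgt]
        if len(rest) != 1:
            raise InputError(
                "cannot infer the other source; pass `other=` explicitly"
            )
        other = rest[0]
    oth = as_group(other)

    b = channel_from_joint(pmf, src, tgt)            # direct source->target
    ind1 = compose(
        channel_from_joint(pmf, src, oth), channel_from_joint(pmf, oth, tgt)
    )
    a = channel_from_joint(pmf, oth, src)
    ind2 = compose(a, b)                             # other -> source -> target

    d = pmf._dist([oth, src, tgt])
    sum1 = 0.0
    sum2 = 0.0
    for (io, is_, it), p in np.ndenumerate(d):
        if p <= 0:
            continue
        direct = b.matrix[is_, it]
        d1 = ind1.matrix[is_, it]
        d2 = ind2.matrix[io, it]
        sum1 += p * (np.log2(direct / d1) if d1 > 0 else np.inf)
        sum2 += p * (np.log2(direct / d2) if d2 > 0 else np.inf)
    return float(sum1), float(sum2)


def imin(pmf: JointPMF, sources, target) -> float:
    """Williams-Beer Imin: expected minimum source-specific information.

    ``Imin = sum_z p(z) min_k sum_a p(a|z) log2(p(z|a)/p(z))``.  For a
    single source this equals I(source; target).
    """
    groups = [as_group(s) for s in as_sources(sources)]
    if not groups:
        raise InputError("need at least one source")
    tgt = as_group(target)
    p_t = pmf.group_marginal(tgt)
    specific = np.zeros((len(groups), p_t.shape[0]))
    for k, g in enumerate(groups):
        joint = pmf._dist([g, tgt])  # (a, z)
        p_a = joint.sum(axis=1)
        for z in range(joint.shape[1]):
            if p_t[z] <= 0:
                continue
            acc = 0.0
            for ai in range(joint.shape[0]):
                paz = joint[ai, z]
                if paz <= 0:
                    continue
                p_z_given_a = paz / p_a[ai]
                acc += (paz / p_t[z]) * np.log2(p_z_given_a / p_t[z])
            specific[k, z] = acc
    mask = p_t > 0
    return float((p_t[mask] * specific.min(axis=0)[mask]).sum())


# ---------------------------------------------------------------------------
# axiom verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxiomCheck:
    name: str
    lhs: float
    rhs: float
    relation: str  # "eq" or "ge"
    holds: bool


def _check(name: str, lhs: float, rhs: float, relation: str, tol: float) -> AxiomCheck:
    if relation == "eq":
        holds = abs(lhs - rhs) <= tol
    else:
        holds = lhs >= rhs - tol
    return AxiomCheck(name, float(lhs), float(rhs), relation, holds)


def verify_axioms(
    pmf: JointPMF,
    sources,
    target,
    graph: SystemGraph | None = None,
    tol: float = 1e-9,
    strict: bool = False,
) -> dict[str, AxiomCheck]:
    """Numerically verify the redundancy axioms on one system.

    Covers symmetry, self-redundancy, monotonicity, the redundancy bound,
    the three-way redundancy inequality, the identity property (target =
    join of the sources), the interaction-information identity, and -- when
    a spare variable exists -- left monotonicity of the target.
    """
    groups = [as_group(s) for s in as_sources(sources)]
    if len(groups) != 2:
        raise InputError("verify_axioms expects exactly two sources")
    s1, s2 = groups
    tgt = as_group(target)
    if graph is None:
        graph = infer_graph(pmf, tol)

    def red(srcs, t):
        return path_redundancy(pmf, srcs, t, graph=graph, tol=tol, strict=strict)

    def red_with_count(srcs, t):
        value, used = path_redundancy(
            pmf, srcs, t, graph=graph, tol=tol, strict=strict, return_paths=True
        )
        return value, len(used)

    checks: dict[str, AxiomCheck] = {}
    r, n_paths = red_with_count([s1, s2], tgt)
    checks["symmetry"] = _check("symmetry", r, red([s2, s1], tgt), "eq", tol)
    i1 = pmf._mi_groups(s1, tgt)
    i2 = pmf._mi_groups(s2, tgt)
    checks["self_redundancy_1"] = _check(
        "self_redundancy_1", red([s1], tgt), i1, "eq", tol
    )
    checks["self_redundancy_2"] = _check(
        "self_redundancy_2", red([s2], tgt), i2, "eq", tol
    )
    checks["monotonicity_1"] = _check("monotonicity_1", red([s1], tgt), r, "ge", tol)
    checks["monotonicity_2"] = _check("monotonicity_2", red([s2], tgt), r, "ge", tol)
    i12 = pmf.mutual_information(s1, s2)
    checks["redundancy_bound"] = _check(
        "redundancy_bound", min(i12, i1, i2), r, "ge", tol
    )
    checks["lattice_monotone_top_1"] = _check(
        "lattice_monotone_top_1",
        pmf.mutual_information(_join([s1, s2]), tgt), i1, "ge", tol,
    )
    checks["lattice_monotone_top_2"] = _check(
        "lattice_monotone_top_2",
        pmf.mutual_information(_join([s1, s2]), tgt), i2, "ge", tol,
    )
    if not (set(s1) | set(s2)) & set(tgt):
        r_a, n_a = red_with_count([tgt, s2], s1)
        r_b, n_b = red_with_count([tgt, s1], s2)
        if n_paths and n_a and n_b:
            # only meaningful when every orientation has an admissible path;
            # an absent source-source edge empties one set by convention
            checks["three_way_inequality"] = _check(
                "three_way_inequality", r, min(r_a, r_b), "ge", tol
            )
        join = _join([s1, s2])
        checks["identity"] = _check(
            "identity", red([s1, s2], join), i12, "eq", tol
        )
        s = synergy(pmf, [s1, s2], tgt, graph=graph, tol=tol, strict=strict)
        ii = pmf.interaction_information(s1, s2, tgt)
        checks["interaction_identity"] = _check(
            "interaction_identity", s - r, ii, "eq", tol
        )
    spare = [v for v in pmf.variables if v not in set(s1) | set(s2) | set(tgt)]
    if spare:
        wide = tgt + (spare[0],)
        checks["left_monotonicity"] = _check(
            "left_monotonicity", red([s1, s2], wide), r, "ge", tol
        )
    return checks
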