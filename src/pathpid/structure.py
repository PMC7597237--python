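"""Association-graph inference and admissible redundancy paths.

An undirected edge between two observed variables is:

* ``absent``   -- its direct channel has identical rows (no association);
* ``indirect`` -- some length-2 cascade through a third observed variable
  reproduces the direct tensor, in both orientations, so the association is
  fully explained without a direct edge (witness paths are recorded);
* ``present``  -- otherwise.

By default only *absent* edges disqualify redundancy paths: indirect edges
still carry their cascade tensor and remain traversable.  Strict pruning
(``strict=True``) also disqualifies indirect edges; this is what recovers
``U(distal) = 0`` on Markov chains, but it empties the admissible set of
systems whose edges explain each other circularly (e.g. the triadic set),
so it is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

from .channels import (
    Channel,
    channel_from_joint,
    channels_equal,
    compose,
    is_null_channel,
)
from .errors import InputError
from .paths import Path
from .pmf import JointPMF, as_group

ABSENT = "absent"
INDIRECT = "indirect"
PRESENT = "present"


@dataclass(frozen=True)
class EdgeRecord:
    """One unordered pair of vertices with both oriented channels."""

    u: str
    v: str
    status: str
    witnesses: tuple[Path, ...]  # cascade paths explaining an indirect edge
    channel_uv: Channel
    channel_vu: Channel


@dataclass(frozen=True, eq=False)
class SystemGraph:
    """Vertices plus retained/pruned edges, with pruning provenance."""

    pmf: JointPMF
    tol: float
    vertices: tuple[str, ...]
    edges: dict = field(default_factory=dict)  # frozenset({u, v}) -> EdgeRecord

    def edge(self, u: str, v: str) -> EdgeRecord:
        key = frozenset({u, v})
        if key not in self.edges:
            raise InputError(f"no edge record for pair ({u!r}, {v!r})")
        return self.edges[key]

    def status(self, u: str, v: str) -> str:
        return self.edge(u, v).status

    @property
    def pruned(self) -> list[tuple[tuple[str, str], str, Path | None]]:
        """(pair, reason, witness) for every non-retained edge."""
        out = []
        for rec in self.edges.values():
            if rec.status != PRESENT:
                witness = rec.witnesses[0] if rec.witnesses else None
                out.append(((rec.u, rec.v), rec.status, witness))
        return out

    def traversable(self, group_u, group_v, strict: bool = False) -> bool:
        """Can a redundancy path use the (group_u, group_v) edge?"""
        gu, gv = as_group(group_u), as_group(group_v)
        if len(gu) == 1 and len(gv) == 1 and frozenset({gu[0], gv[0]}) in self.edges:
            status = self.status(gu[0], gv[0])
            if strict:
                return status == PRESENT
            return status != ABSENT
        # group endpoints (joins) are tested directly on their channel
        if set(gu) == set(gv):
            return True
        return not is_null_channel(channel_from_joint(self.pmf, gu, gv), self.tol)


def infer_graph(pmf: JointPMF, tol: float = 1e-9) -> SystemGraph:
    """Classify every vertex pair as present, absent, or indirect.

    An edge is pruned as indirect only when the cascade through some third
    vertex matches the direct tensor in *both* orientations within ``tol``.
    All candidate witnesses are recorded; mutually-exclusive prunings (edges
    that explain each other) are thereby exposed rather than reconciled.
    """
    vertices = pmf.variables
    direct: dict[tuple[str, str], Channel] = {}
    for u, v in permutations(vertices, 2):
        direct[(u, v)] = channel_from_joint(pmf, u, v)
    edges: dict = {}
    for u, v in combinations(vertices, 2):
        c_uv, c_vu = direct[(u, v)], direct[(v, u)]
        if is_null_channel(c_uv, tol) or is_null_channel(c_vu, tol):
            status, witnesses = ABSENT, ()
        else:
            found = []
            for w in vertices:
                if w in (u, v):
                    continue
                fwd = compose(direct[(u, w)], direct[(w, v)])
                bwd = compose(direct[(v, w)], direct[(w, u)])
                if channels_equal(c_uv, fwd, tol) and channels_equal(c_vu, bwd, tol):
                    found.append(Path.of(u, w, v))
            status = INDIRECT if found else PRESENT
            witnesses = tuple(found)
        edges[frozenset({u, v})] = EdgeRecord(u, v, status, witnesses, c_uv, c_vu)
    return SystemGraph(pmf, tol, vertices, edges)


def enumerate_redundancy_paths(
    graph: SystemGraph, sources, target, strict: bool = False
) -> list[Path]:
    """Admissible indirect paths: every source once, ending at the target.

    The candidate set is all permutations of the sources followed by the
    target; a candidate survives iff every consecutive edge is traversable
    in the graph.  The result is invariant under permutation of the
    ``sources`` argument.
    """
    groups = [as_group(s) for s in sources]
    if not groups:
        raise InputError("need at least one source")
    tgt = as_group(target)
    for g in groups:
        if set(g) == set(tgt):
            raise InputError(f"target {tgt!r} may not be listed as a source")
    out = []
    for perm in permutations(groups):
        nodes = perm + (tgt,)
        if all(
            graph.traversable(a, b, strict=strict)
            for a, b in zip(nodes[:-1], nodes[1:])
        ):
            out.append(Path(nodes))
    out.sort(key=str)
    return out


def graph_rows(graph: SystemGraph) -> list[tuple[str, str, str, str]]:
    """Edge list as (vertex1, vertex2, status, witness) text rows."""
    rows = []
    for u, v in combinations(graph.vertices, 2):
        rec = graph.edge(u, v)
        witness = ";".join(str(w) for w in rec.witnesses)
        rows.append((rec.u, rec.v, rec.status, witness))
    return rows
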