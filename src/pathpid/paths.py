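"""Paths through a system and path-based mutual information.

A path is an ordered sequence of vertex groups, written
``{X1}{X2}...{Xl}``.  Its tensor is the ordered product of the per-edge
channels, each estimated from the full joint pmf.  The path-based mutual
information is the mutual information of the *path-propagated* joint
``diag(p(source)) . T`` with its own marginals: the source marginal is the
actual one, the target marginal is the propagated one.  For a single edge
this reduces exactly to the classical mutual information.

The same path traversed backwards uses the Bayes-reversed channel of every
edge, in reversed order; its mutual information is identical (traverse
invariance), which this module realizes simply by reversing the node order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

from .channels import Channel, channel_from_joint, compose
from .errors import InputError
from .pmf import JointPMF, as_group


@dataclass(frozen=True)
class Path:
    """An ordered sequence of vertex groups from a source to a target.

    The path must be simple: no vertex group may repeat, except that a group
    may be repeated *adjacently* (the self-path ``{X}{X}`` whose edge is the
    Kronecker delta, used for self-redundancy).
    """

    nodes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        nodes = tuple(as_group(n) for n in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(nodes) < 2:
            raise InputError("a path needs at least two nodes")
        for i, a in enumerate(nodes):
            for j in range(i + 2, len(nodes)):
                if set(a) == set(nodes[j]):
                    raise InputError(
                        f"vertex group {a!r} repeats non-adjacently in path {self}"
                    )

    @classmethod
    def of(cls, *nodes) -> "Path":
        """Build a path from node specs (strings or sequences of names)."""
        return cls(tuple(as_group(n) for n in nodes))

    @property
    def source(self) -> tuple[str, ...]:
        return self.nodes[0]

    @property
    def target(self) -> tuple[str, ...]:
        return self.nodes[-1]

    def reverse(self) -> "Path":
        """The same path traversed in the opposite direction."""
        return Path(tuple(reversed(self.nodes)))

    def __str__(self) -> str:
        return "".join("{" + "".join(map(str, n)) + "}" for n in self.nodes)


def edge_channels(pmf: JointPMF, path: Path) -> list[Channel]:
    """Per-edge channels of a path, estimated from the full joint pmf."""
    return [
        channel_from_joint(pmf, a, b)
        for a, b in zip(path.nodes[:-1], path.nodes[1:])
    ]


def path_tensor(pmf: JointPMF, path: Path) -> Channel:
    """Ordered product of the per-edge channels; row-stochastic."""
    return reduce(compose, edge_channels(pmf, path))


def _path_distributions(pmf: JointPMF, path: Path):
    """(source marginal, tensor, propagated joint, propagated target marginal)."""
    tensor = path_tensor(pmf, path)
    p_src = pmf.group_marginal(path.source)
    joint = p_src[:, np.newaxis] * tensor.matrix
    p_tgt = p_src @ tensor.matrix
    return p_src, tensor, joint, p_tgt


def path_joint(pmf: JointPMF, path: Path) -> JointPMF:
    """The path-propagated joint over (source, target) as a JointPMF.

    This is ``diag(p(source)) . T``; its marginal over the source equals the
    actual source marginal exactly, while the target marginal is the
    propagated one (not, in general, the empirical target marginal).
    """
    src, tgt = path.source, path.target
    if set(src) & set(tgt):
        raise InputError(
            "path_joint needs disjoint source and target groups; "
            "use path_mutual_information for overlapping endpoints"
        )
    _, tensor, joint, _ = _path_distributions(pmf, path)
    variables = src + tgt
    alphabets = tuple(pmf.alphabets[ax] for ax in pmf.axes_of(src)) + tuple(
        pmf.alphabets[ax] for ax in pmf.axes_of(tgt)
    )
    shape = tuple(len(a) for a in alphabets)
    return JointPMF(variables, alphabets, joint.reshape(shape))


def path_mutual_information(pmf: JointPMF, path: Path) -> float:
    """Path-based mutual information of a path, in bits (non-negative)."""
    _, tensor, joint, p_tgt = _path_distributions(pmf, path)
    mask = joint > 0
    ratio = tensor.matrix[mask] / np.broadcast_to(p_tgt, joint.shape)[mask]
    mi = float((joint[mask] * np.log2(ratio)).sum())
    # exact KL form; clip float dust so callers can rely on >= 0
    return max(mi, 0.0)


@dataclass(frozen=True)
class DPIReport:
    """Per-edge mutual informations versus the path MI (data processing)."""

    path: Path
    edge_mi: tuple[float, ...]
    path_mi: float
    bound: float
    satisfied: bool


def dpi_report(pmf: JointPMF, path: Path, tol: float = 1e-9) -> DPIReport:
    """Check the data processing inequality: path MI <= every edge MI."""
    edge_mis = []
    for a, b in zip(path.nodes[:-1], path.nodes[1:]):
        # adjacent identical groups (delta edge) carry I(X;X) = H(X)
        edge_mis.append(JointPMF._mi_from_joint(pmf._dist([a, b])))
    pmi = path_mutual_information(pmf, path)
    bound = min(edge_mis)
    return DPIReport(path, tuple(edge_mis), pmi, bound, pmi <= bound + tol)
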