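"""Discrete-memoryless-channel tensors.

A channel is a row-stochastic matrix mapping a source group's pmf to a
destination group's pmf.  Channels are always estimated from a joint pmf;
composition of channels along a cascade is plain matrix multiplication.

Zero-probability source symbols leave the corresponding conditional row
undefined.  Such rows are filled with the uniform distribution, flagged in
``Channel.defined``, and excluded from row comparisons so that unreachable
states never drive structure pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .pmf import JointPMF, as_group

#: default tolerance for channel comparisons on exact (rational) fixtures
DEFAULT_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class Channel:
    """Row-stochastic transition tensor for one oriented association."""

    source: tuple[str, ...]
    dest: tuple[str, ...]
    source_states: tuple
    dest_states: tuple
    matrix: np.ndarray
    defined: np.ndarray  # bool per row: estimated from positive source mass

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "defined", np.asarray(self.defined, dtype=bool))
        if m.ndim != 2:
            raise InputError("channel matrix must be 2-D")
        if m.shape != (len(self.source_states), len(self.dest_states)):
            raise InputError("channel matrix shape does not match state counts")
        if m.min() < -1e-12 or np.abs(m.sum(axis=1) - 1.0).max() > DEFAULT_TOL:
            raise InputError("channel rows must be probability vectors")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def channel_from_joint(pmf: JointPMF, src, dst) -> Channel:
    """Estimate the channel ``p(dst | src)`` from a joint pmf.

    When the two groups coincide the channel is the Kronecker delta (a
    noiseless copy).  Overlapping groups are allowed: the conditional is
    supported only on destination states consistent with the source state.
    """
    src, dst = as_group(src), as_group(dst)
    if src == dst:
        n = len(pmf.group_states(src))
        return Channel(
            src, dst, pmf.group_states(src), pmf.group_states(dst),
            np.eye(n), np.ones(n, dtype=bool),
        )
    joint = pmf._dist([src, dst])
    row_mass = joint.sum(axis=1)
    defined = row_mass > 0
    matrix = np.empty_like(joint)
    matrix[defined] = joint[defined] / row_mass[defined, np.newaxis]
    matrix[~defined] = 1.0 / joint.shape[1]
    return Channel(src, dst, pmf.group_states(src), pmf.group_states(dst), matrix, defined)


def reverse_channel(pmf: JointPMF, src, dst) -> Channel:
    """Bayes reversal: the channel reconstructing ``src`` from ``dst``.

    Propagating the destination marginal through it recovers the source
    marginal exactly.
    """
    return channel_from_joint(pmf, dst, src)


def propagate(row_pmf, channel: Channel) -> np.ndarray:
    """Push a source probability vector through a channel (``p @ A``)."""
    p = np.asarray(row_pmf, dtype=float).ravel()
    if p.shape[0] != channel.shape[0]:
        raise InputError(
            f"pmf length {p.shape[0]} does not match channel source size {channel.shape[0]}"
        )
    if p.min() < -1e-12 or abs(float(p.sum()) - 1.0) > DEFAULT_TOL:
        raise InputError("input must be a probability vector")
    return p @ channel.matrix


def compose(c1: Channel, c2: Channel) -> Channel:
    """Cascade two channels; the tensor is the matrix product."""
    if c1.dest != c2.source or c1.dest_states != c2.source_states:
        raise InputError(
            f"cannot compose: {c1.dest!r} does not match {c2.source!r}"
        )
    return Channel(
        c1.source, c2.dest, c1.source_states, c2.dest_states,
        c1.matrix @ c2.matrix, c1.defined.copy(),
    )


def is_null_channel(c: Channel, tol: float = DEFAULT_TOL) -> bool:
    """True iff all (defined) rows are identical within ``tol``.

    A channel with identical rows cannot transmit information; it signals an
    absent association.
    """
    rows = c.matrix[c.defined]
    if rows.shape[0] <= 1:
        return True
    spread = rows.max(axis=0) - rows.min(axis=0)
    return bool(spread.max() <= tol)


def channels_equal(c1: Channel, c2: Channel, tol: float = DEFAULT_TOL) -> bool:
    """Elementwise equality within ``tol``, over rows defined in both."""
    if c1.shape != c2.shape:
        raise InputError(f"shape mismatch: {c1.shape} vs {c2.shape}")
    both = c1.defined & c2.defined
    if not both.any():
        return True
    return bool(np.abs(c1.matrix[both] - c2.matrix[both]).max() <= tol)
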