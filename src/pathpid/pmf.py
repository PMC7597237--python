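"""Joint probability mass functions over named discrete variables.

The :class:`JointPMF` is the single source of truth for every measure in
this package: channels, path tensors, and decompositions are all estimated
from it.  Probabilities are stored as a dense :class:`numpy.ndarray` whose
axes follow the declared variable order; alphabets are declared rather than
inferred, so states with zero probability keep their place and channel row
indexing stays stable.

All information measures use log base 2 and return bits, with the usual
convention ``0 * log 0 == 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError

#: absolute tolerance for normalization checks of in-memory pmfs
NORM_ATOL = 1e-9

GroupLike = "str | Sequence[str]"


def as_group(group) -> tuple[str, ...]:
    """Normalize a variable group spec to a tuple of variable names.

    A group is either a single variable name or an ordered sequence of
    names (a *join* such as ``("X", "Y")``, written ``{XY}`` in path
    notation).  Join states are ordered as the lexicographic product of the
    member alphabets, in the group's variable order.
    """
    if isinstance(group, str):
        return (group,)
    g = tuple(group)
    if not g:
        raise InputError("variable group must be non-empty")
    if any(not isinstance(v, str) for v in g):
        raise InputError(f"variable names must be strings, got {g!r}")
    if len(set(g)) != len(g):
        raise InputError(f"duplicate variable in group {g!r}")
    return g


def _require_disjoint(*groups: tuple[str, ...]) -> None:
    seen: set[str] = set()
    for g in groups:
        overlap = seen.intersection(g)
        if overlap:
            raise InputError(
                f"variable groups must be pairwise disjoint; {sorted(overlap)} repeated"
            )
        seen.update(g)


def _h(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector/array."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True, eq=False)
class JointPMF:
    """A normalized joint pmf over named discrete variables.

    Parameters
    ----------
    variables:
        Ordered variable names, one per table axis.
    alphabets:
        Per-variable ordered symbol labels.  Symbols may be any hashable
        objects; file readers produce strings.
    table:
        Array of probabilities with shape ``tuple(len(a) for a in alphabets)``.
        Must be non-negative and sum to 1 within ``NORM_ATOL``.
    """

    variables: tuple[str, ...]
    alphabets: tuple[tuple, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "alphabets", tuple(tuple(a) for a in self.alphabets))
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if len(self.variables) == 0:
            raise InputError("a JointPMF needs at least one variable")
        if len(set(self.variables)) != len(self.variables):
            raise InputError(f"duplicate variable names in {self.variables!r}")
        if len(self.alphabets) != len(self.variables):
            raise InputError("need exactly one alphabet per variable")
        for var, alpha in zip(self.variables, self.alphabets):
            if len(alpha) == 0:
                raise InputError(f"alphabet of {var!r} is empty")
            if len(set(alpha)) != len(alpha):
                raise InputError(f"alphabet of {var!r} has duplicate symbols")
        shape = tuple(len(a) for a in self.alphabets)
        if table.shape != shape:
            raise InputError(
                f"table shape {table.shape} does not match alphabet sizes {shape}"
            )
        if table.min() < -1e-12:
            raise InputError("probabilities must be non-negative")
        if abs(float(table.sum()) - 1.0) > NORM_ATOL:
            raise InputError(
                f"probabilities sum to {float(table.sum())!r}, expected 1 within {NORM_ATOL}"
            )

    # -- construction ----------------------------------------------------

    @classmethod
    def from_states(
        cls,
        variables: Sequence[str],
        states: Mapping[tuple, object],
        alphabets: Sequence[Sequence] | None = None,
    ) -> "JointPMF":
        """Build a pmf from a mapping ``state tuple -> probability``.

        When ``alphabets`` is omitted, symbols are collected per variable in
        first-appearance order of the mapping.
        """
        variables = tuple(variables)
        if alphabets is None:
            collected: list[list] = [[] for _ in variables]
            for state in states:
                if len(state) != len(variables):
                    raise InputError(
                        f"state {state!r} has {len(state)} symbols, expected {len(variables)}"
                    )
                for sym, pool in zip(state, collected):
                    if sym not in pool:
                        pool.append(sym)
            alphabets = [tuple(pool) for pool in collected]
        alphabets = tuple(tuple(a) for a in alphabets)
        index = [{sym: i for i, sym in enumerate(a)} for a in alphabets]
        table = np.zeros(tuple(len(a) for a in alphabets))
        for state, prob in states.items():
            try:
                idx = tuple(ix[sym] for sym, ix in zip(state, index))
            except KeyError as exc:
                raise InputError(
                    f"symbol {exc.args[0]!r} in state {state!r} not in declared alphabet"
                ) from exc
            table[idx] += float(prob)
        return cls(variables, alphabets, table)

    # -- indexing helpers ------------------------------------------------

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.table.shape

    def axes_of(self, group) -> tuple[int, ...]:
        group = as_group(group)
        axes = []
        for v in group:
            try:
                axes.append(self.variables.index(v))
            except ValueError:
                raise InputError(
                    f"unknown variable {v!r}; declared variables are {list(self.variables)}"
                ) from None
        return tuple(axes)

    def group_states(self, group) -> tuple[tuple, ...]:
        """All joint states of a group, in lexicographic product order."""
        axes = self.axes_of(group)
        out: list[tuple] = [()]
        for ax in axes:
            out = [s + (sym,) for s in out for sym in self.alphabets[ax]]
        return tuple(out)

    def _dist(self, groups: Sequence) -> np.ndarray:
        """Joint distribution over one or more variable groups.

        Groups may overlap (or coincide); each full system state contributes
        its probability to the single cell consistent with it, so the result
        is always a valid joint distribution over the group states.
        """
        groups = [as_group(g) for g in groups]
        axes_per_group = [self.axes_of(g) for g in groups]
        dims_per_group = [
            tuple(self.table.shape[ax] for ax in axes) for axes in axes_per_group
        ]
        grids = np.indices(self.table.shape)
        flat_ids = []
        for axes, dims in zip(axes_per_group, dims_per_group):
            flat_ids.append(
                np.ravel_multi_index([grids[ax] for ax in axes], dims).ravel()
            )
        out_shape = tuple(int(np.prod(d)) for d in dims_per_group)
        out = np.zeros(out_shape)
        np.add.at(out, tuple(flat_ids), self.table.ravel())
        return out

    def group_marginal(self, group) -> np.ndarray:
        """Marginal probability vector of a group over its product states."""
        return self._dist([group]).ravel()

    # -- operations ------------------------------------------------------

    def marginalize(self, keep) -> "JointPMF":
        """Sum out every variable not in ``keep`` (result in ``keep`` order)."""
        keep = as_group(keep)
        axes = self.axes_of(keep)
        drop = [i for i in range(self.n_variables) if i not in axes]
        t = self.table.transpose(tuple(axes) + tuple(drop))
        if drop:
            t = t.reshape(t.shape[: len(axes)] + (-1,)).sum(axis=-1)
        return JointPMF(
            keep, tuple(self.alphabets[ax] for ax in axes), t.copy()
        )

    def entropy(self) -> float:
        """Joint Shannon entropy H of the full system, in bits."""
        return _h(self.table)

    @staticmethod
    def _mi_from_joint(joint: np.ndarray) -> float:
        """Mutual information of a 2-D joint distribution with its own marginals."""
        pa = joint.sum(axis=1)
        pb = joint.sum(axis=0)
        mask = joint > 0
        denom = np.outer(pa, pb)[mask]
        return float((joint[mask] * np.log2(joint[mask] / denom)).sum())

    def mutual_information(self, group_a, group_b) -> float:
        """I(A;B) in bits between two disjoint variable groups.

        Exactly symmetric in its arguments: the joint is always evaluated in
        a canonical axis order, so ``I(A;B)`` and ``I(B;A)`` are the same
        floating-point number.
        """
        ga, gb = as_group(group_a), as_group(group_b)
        _require_disjoint(ga, gb)
        return self._mi_groups(ga, gb)

    def _mi_groups(self, ga, gb) -> float:
        """Group MI without the disjointness requirement (internal).

        With overlapping groups this is still a well-defined mutual
        information between the two group-valued random variables (used for
        the identity property, where the target is the join of the sources).
        """
        if self.axes_of(gb) < self.axes_of(ga):
            ga, gb = gb, ga
        return self._mi_from_joint(self._dist([ga, gb]))

    def conditional_mutual_information(self, group_a, group_b, cond) -> float:
        """I(A;B|C) in bits between pairwise-disjoint variable groups."""
        ga, gb, gc = as_group(group_a), as_group(group_b), as_group(cond)
        _require_disjoint(ga, gb, gc)
        d = self._dist([ga, gb, gc])
        pc = d.sum(axis=(0, 1))
        pac = d.sum(axis=1)
        pbc = d.sum(axis=0)
        mask = d > 0
        num = d * pc[np.newaxis, np.newaxis, :]
        den = pac[:, np.newaxis, :] * pbc[np.newaxis, :, :]
        return float((d[mask] * np.log2(num[mask] / den[mask])).sum())

    def interaction_information(self, group_x, group_y, group_z) -> float:
        """Signed interaction information ``I(X;Y|Z) - I(X;Y)`` in bits.

        Under the decomposition identity this equals synergy minus
        redundancy with Z as the target; it may be negative.
        """
        cmi = self.conditional_mutual_information(group_x, group_y, group_z)
        mi = self.mutual_information(group_x, group_y)
        return cmi - mi

    # -- comparison ------------------------------------------------------

    def allclose(self, other: "JointPMF", atol: float = 1e-12) -> bool:
        return (
            self.variables == other.variables
            and self.alphabets == other.alphabets
            and bool(np.allclose(self.table, other.table, atol=atol, rtol=0.0))
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        vars_ = ",".join(self.variables)
        return f"JointPMF({vars_}; shape={self.table.shape})"
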