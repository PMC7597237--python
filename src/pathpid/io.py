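"""Reading and writing pmf documents (TSV/CSV/JSON) and graph exports.

TSV/CSV dialect: a header row of variable names plus a final probability
column, '#' comments, '.' decimal separator; probabilities may be written
as fractions ("5/6") and are parsed exactly.  Symbols are read as strings
and alphabets follow first-appearance order unless declared in a JSON
header.
"""

from __future__ import annotations

import csv
import json
import logging
from fractions import Fraction
from pathlib import Path as FilePath

from .errors import InputError
from .pmf import JointPMF
from .structure import SystemGraph, graph_rows

log = logging.getLogger("pathpid")

#: default normalization tolerance for files (looser than the in-memory one)
FILE_NORM_TOL = 1e-6

_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        fmt = fmt.lower()
        if fmt not in ("tsv", "csv", "json"):
            raise InputError(f"unsupported format {fmt!r}")
        return fmt
    suffix = FilePath(path).suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "json"):
        return suffix
    return "tsv"


def _parse_number(text: str) -> Fraction:
    try:
        return Fraction(text.strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise InputError(f"cannot parse probability {text!r}") from exc


def _table_rows(path, delim: str) -> list[list[str]]:
    rows = []
    with open(path, newline="") as fh:
        for raw in csv.reader(fh, delimiter=delim):
            if not raw:
                continue
            cells = [c.strip() for c in raw]
            if cells[0].startswith("#") or all(c == "" for c in cells):
                continue
            rows.append(cells)
    if not rows:
        raise InputError(f"{path}: empty file")
    return rows


def _build(variables, state_rows, alphabets, counts: bool, tol: float) -> JointPMF:
    states: dict[tuple, Fraction] = {}
    for state, prob in state_rows:
        if state in states:
            raise InputError(f"duplicate state row {state!r}")
        states[state] = prob
    total = sum(states.values())
    if total == 0:
        raise InputError("probabilities sum to zero")
    if counts:
        states = {s: p / total for s, p in states.items()}
    elif abs(float(total) - 1.0) > tol:
        raise InputError(
            f"probabilities sum to {float(total)!r} (deficit {1.0 - float(total):.3g}); "
            f"expected 1 within {tol}"
        )
    else:
        states = {s: p / total for s, p in states.items()}  # exact renormalization
    return JointPMF.from_states(variables, states, alphabets=alphabets)


def read_pmf(path, fmt: str | None = None, counts: bool = False,
             tol: float = FILE_NORM_TOL) -> JointPMF:
    """Read a pmf document; the last column (or "p" field) is the probability."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            variables = list(doc["variables"])
            raw_states = doc["states"]
        except (KeyError, TypeError) as exc:
            raise InputError(f"{path}: JSON pmf needs 'variables' and 'states'") from exc
        alphabets = doc.get("alphabets")
        if alphabets is not None:
            if isinstance(alphabets, dict):
                alphabets = [list(map(str, alphabets[v])) for v in variables]
            else:
                alphabets = [list(map(str, a)) for a in alphabets]
        state_rows = []
        for row in raw_states:
            if len(row) != len(variables) + 1:
                raise InputError(f"{path}: ragged state row {row!r}")
            state_rows.append(
                (tuple(str(s) for s in row[:-1]), _parse_number(str(row[-1])))
            )
        return _build(variables, state_rows, alphabets, counts, tol)
    rows = _table_rows(path, _DELIMS[fmt])
    header = rows[0]
    if len(header) < 2:
        raise InputError(f"{path}: need at least one variable column plus probability")
    variables = header[:-1]
    state_rows = []
    for cells in rows[1:]:
        if len(cells) != len(header):
            raise InputError(f"{path}: ragged row {cells!r}")
        state_rows.append((tuple(cells[:-1]), _parse_number(cells[-1])))
    return _build(variables, state_rows, None, counts, tol)


def write_pmf(pmf: JointPMF, path, fmt: str | None = None) -> None:
    """Write a pmf document; probabilities carry full double precision."""
    fmt = _infer_format(path, fmt)
    entries = [
        (state, float(p))
        for state, p in zip(
            (tuple(s) for s in _full_states(pmf)), pmf.table.ravel()
        )
        if p > 0
    ]
    if fmt == "json":
        doc = {
            "variables": list(pmf.variables),
            "alphabets": [[str(s) for s in a] for a in pmf.alphabets],
            "states": [[*(str(s) for s in state), repr(p)] for state, p in entries],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return
    delim = _DELIMS[fmt]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(list(pmf.variables) + ["p"])
        for state, p in entries:
            writer.writerow([str(s) for s in state] + [repr(p)])


def _full_states(pmf: JointPMF):
    from itertools import product

    return product(*pmf.alphabets)


def read_observations(path, fmt: str | None = None) -> JointPMF:
    """Plug-in pmf from raw categorical records (one per row, with header)."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        raise InputError("observations are read from TSV/CSV only")
    rows = _table_rows(path, _DELIMS[fmt])
    variables = rows[0]
    records = rows[1:]
    if not records:
        raise InputError(f"{path}: no observation records")
    if len(records) == 1:
        log.warning("only one observation record: the plug-in pmf is degenerate")
    counts: dict[tuple, Fraction] = {}
    for cells in records:
        if len(cells) != len(variables):
            raise InputError(f"{path}: ragged observation row {cells!r}")
        state = tuple(cells)
        counts[state] = counts.get(state, Fraction(0)) + 1
    total = sum(counts.values())
    return JointPMF.from_states(
        variables, {s: Fraction(c, total) for s, c in counts.items()}
    )


def write_graph(graph: SystemGraph, path, fmt: str | None = None) -> None:
    """Export a system graph as edge-list TSV or JSON."""
    fmt = _infer_format(path, fmt)
    rows = graph_rows(graph)
    if fmt == "json":
        doc = {
            "vertices": list(graph.vertices),
            "edges": [
                {"vertex1": u, "vertex2": v, "status": s, "witness": w}
                for u, v, s, w in rows
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["vertex1", "vertex2", "status", "witness"])
        writer.writerows(rows)
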