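"""Tabular output of feature vectors (wide format, one molecule per row)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

from .vector import FeatureVector

__all__ = ["write_table", "read_table"]


def write_table(
    rows: Sequence[FeatureVector],
    format: Literal["csv", "tsv", "json"],
    path: str | Path,
    ids: Sequence[str] | None = None,
    digits: int = 6,
) -> None:
    """Write feature vectors as a wide table with a header of names.

    All rows must share an identical name list; floats are serialized
    with *digits* significant digits so repeated runs are byte-identical.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    names = rows[0].names
    for i, r in enumerate(rows):
        if r.names != names:
            raise ValueError(
                f"row {i} has a different feature name list than row 0"
            )
    if ids is not None and len(ids) != len(rows):
        raise ValueError("ids length must match number of rows")
    fmt = f"{{:.{digits}g}}"
    if format == "json":
        payload = []
        for i, r in enumerate(rows):
            entry = {n: float(fmt.format(v)) for n, v in r}
            if ids is not None:
                entry = {"id": ids[i], **entry}
            payload.append(entry)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {format!r}")
    sep = "," if format == "csv" else "\t"
    with open(path, "w") as fh:
        header = list(names)
        if ids is not None:
            header = ["id"] + header
        fh.write(sep.join(header) + "\n")
        for i, r in enumerate(rows):
            cells = [fmt.format(v) for v in r.values]
            if ids is not None:
                cells = [ids[i]] + cells
            fh.write(sep.join(cells) + "\n")


def read_table(path: str | Path, format: Literal["csv", "tsv"] = "csv") -> tuple[list[str], list[FeatureVector]]:
    """Read a table written by :func:`write_table`; returns (ids, rows).

    If the first column is named ``id`` it is split off as identifiers,
    otherwise ids are row numbers.
    """
    sep = "," if format == "csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        has_id = header and header[0] == "id"
        names = header[1:] if has_id else header
        ids: list[str] = []
        rows: list[FeatureVector] = []
        for i, line in enumerate(fh):
            cells = line.rstrip("\n").split(sep)
            if has_id:
                ids.append(cells[0])
                cells = cells[1:]
            else:
                ids.append(str(i))
            rows.append(FeatureVector(names, [float(c) for c in cells]))
    return ids, rows
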