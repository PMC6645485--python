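"""Matrix readers, the bundled clinical example and report serialization."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .anova import ScoreMatrix
from .exceptions import ParseError

__all__ = ["read_matrix", "fixture_table5", "write_report"]

_DELIMITERS = (",", "\t", ";")

# Electromyographic median frequencies (Hz) from the lumbar left side of the
# back muscles of 10 subjects, recorded in the morning on three separate days
# (Elfving et al. 1999); the standard worked example for this analysis.
_EMG_DATA = (
    (59.9, 67.7, 72.2),
    (62.9, 66.5, 67.9),
    (58.9, 50.1, 47.9),
    (46.8, 50.0, 53.9),
    (62.5, 67.8, 62.6),
    (44.8, 42.7, 48.4),
    (57.3, 49.6, 48.0),
    (49.0, 45.2, 57.5),
    (43.5, 41.5, 47.4),
    (39.2, 50.9, 56.3),
)


def fixture_table5() -> ScoreMatrix:
    """The bundled 10 x 3 electromyography reliability matrix (Hz)."""
    return ScoreMatrix(
        np.array(_EMG_DATA, dtype=float),
        measurement_labels=("Day 1", "Day 2", "Day 3"),
    )


def _detect_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ParseError(
            "could not detect a delimiter (expected ',', tab or ';')", row=1
        )
    return best


def _is_numeric_row(cells: list[str]) -> bool:
    try:
        [float(c) for c in cells]
        return True
    except ValueError:
        return False


def read_matrix(path, delimiter: str | None = None) -> ScoreMatrix:
    """Read an n x k score matrix from a delimited text file.

    One row per subject, one column per measurement.  The delimiter is
    auto-detected among comma, tab and semicolon unless given; a single
    header row is detected by a non-numeric first line and recorded as
    measurement labels.  Ragged rows, non-numeric cells or a matrix smaller
    than 2 x 2 raise :class:`ParseError` with the offending location.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path} is empty")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])

    rows = list(csv.reader(lines, delimiter=delimiter))
    rows = [[c.strip() for c in r] for r in rows]

    labels = None
    if not _is_numeric_row(rows[0]):
        labels = tuple(rows[0])
        rows = rows[1:]
        if not rows:
            raise ParseError("file contains a header but no data rows", row=2)

    k = len(rows[0])
    offset = 2 if labels else 1
    data = np.empty((len(rows), k), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != k:
            raise ParseError(
                f"ragged row: expected {k} columns, found {len(row)}",
                row=i + offset,
            )
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r}", row=i + offset, column=j + 1
                ) from None

    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ParseError(
            f"matrix must be at least 2 x 2, got {data.shape[0]} x {data.shape[1]}"
        )
    return ScoreMatrix(data, measurement_labels=labels)


def write_report(report, path) -> None:
    """Serialize an analysis or simulation report to JSON.

    ``report`` may be an object exposing ``to_dict()`` (e.g.
    :class:`iccsim.model.IccResults` or
    :class:`iccsim.simulate.SimulationResult`) or a plain mapping.  Key order
    is stable (insertion order) and the file round-trips losslessly through
    ``json.load``.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    payload.setdefault("schema_version", 1)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
        fh.write("\n")
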