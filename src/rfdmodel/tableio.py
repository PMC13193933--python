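"""Tabular export of predictions (CSV / JSON) and the single-point report.

Data goes to standard output or a file; diagnostics go to logging (standard
error), so piped CSV stays clean.  Numbers are written with ``repr``
(shortest round-tripping form), so a written table re-parsed from text
equals the source values at full double precision and identical inputs
produce byte-identical output.
"""

from __future__ import annotations

import io
import json
import sys
from pathlib import Path
from typing import Sequence, TextIO

from .model import PredictionResult

__all__ = ["write_table", "render_table", "render_report"]

TABLE_FIELDS = ("duration_min", "predicted_rfd", "absolute_loss", "percent_loss")


def _rows(results: Sequence[PredictionResult]) -> list[dict[str, float]]:
    return [
        {
            "duration_min": r.duration,
            "predicted_rfd": r.predicted_rfd,
            "absolute_loss": r.absolute_loss,
            "percent_loss": r.percent_loss,
        }
        for r in results
    ]


def render_table(results: Sequence[PredictionResult], fmt: str = "csv") -> str:
    """Serialize results as CSV (header + one row per duration) or a JSON array."""
    if not results:
        raise ValueError("results must be non-empty")
    rows = _rows(results)
    if fmt == "csv":
        buf = io.StringIO()
        buf.write(",".join(TABLE_FIELDS) + "\n")
        for row in rows:
            buf.write(",".join(repr(row[f]) for f in TABLE_FIELDS) + "\n")
        return buf.getvalue()
    if fmt == "json":
        return json.dumps(rows, indent=2) + "\n"
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def write_table(
    results: Sequence[PredictionResult],
    fmt: str = "csv",
    destination: str | Path | TextIO | None = None,
) -> None:
    """Write the serialized table to a path, an open stream, or stdout."""
    text = render_table(results, fmt)
    if destination is None:
        sys.stdout.write(text)
    elif hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def render_report(result: PredictionResult, rfd0: float) -> str:
    """Human-readable single-duration report with full and rounded values."""
    return (
        f"aerobic duration:      {result.duration:g} min\n"
        f"baseline RFD:          {rfd0!r} N/s\n"
        f"predicted RFD:         {result.predicted_rfd!r} N/s  (~{result.predicted_rfd_rounded})\n"
        f"absolute RFD loss:     {result.absolute_loss!r} N/s  (~{result.absolute_loss_rounded})\n"
        f"percent RFD loss:      {result.percent_loss!r} %  (~{result.percent_loss_rounded}%)\n"
    )
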