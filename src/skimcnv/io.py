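"""Writers for call sets plus coordinate-convention converters.

Internally every interval is 0-based half-open (BED convention).
Printed genome coordinates such as ``chr3:197580000..197770000`` are
1-based inclusive; the two tiny converters below are the only place the
conventions meet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "to_one_based",
    "from_one_based",
    "calls_to_bed",
    "calls_to_frame",
    "axiom_calls_to_frame",
]

SCORE_CAP = 100.0


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last


def _score(E: float) -> float:
    """-log10(E), capped (E of 0 would otherwise be infinite)."""
    if E <= 0:
        return SCORE_CAP
    return float(min(SCORE_CAP, -np.log10(E)))


def calls_to_frame(calls) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "name": f"{c.line_id}:{c.mode}",
            "score": round(_score(c.E), 3),
            "strand": ".",
            "n_windows": c.n_windows,
            "n_interruptions": c.n_interruptions,
            "E": c.E,
            "sig_tags": ",".join(str(a) for a in c.sig_tags),
            "components": ";".join(f"{s}-{e}" for s, e in c.components),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "n_windows", "n_interruptions", "E", "sig_tags", "components",
        ],
    )


def calls_to_bed(calls, path) -> None:
    """Write CNV calls as BED6+ (extra columns after strand)."""
    calls_to_frame(calls).to_csv(path, sep="\t", header=False, index=False)


def axiom_calls_to_frame(calls) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "line_id": c.line_id,
            "n_null": c.n_null,
            "n_interruptions": c.n_interruptions,
            "E": c.E,
            "sig_tags": ",".join(str(a) for a in c.sig_tags),
            "likely_contiguous": c.likely_contiguous,
            "marker_ids": ",".join(c.marker_ids),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "line_id", "n_null",
            "n_interruptions", "E", "sig_tags", "likely_contiguous", "marker_ids",
        ],
    )
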