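"""Deletion screening from SNP-array genotype matrices.

A marker whose assay gives no signal in either fluorescence channel is
scored as the null call "---".  In an inbred background every line
should score identically, so a run of null calls private to one line
points at a deletion of the probed sequence - while an isolated null is
more likely a technical failure.  Candidate deletions are runs of at
least ``min_run`` nulls (default 3), tolerated across a single
interrupting valid call, scored for chance expectation with the runs
model, and the interrupting calls themselves are classified for
reliability (a marker heterozygous only in the deletion line, or
scored inconsistently with every other line, is probably a mis-score).

Hemizygous deletions are invisible to this assay: one intact homologue
still produces signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import FlagTrack, find_runs
from .genome import GenomeModel
from .runs import DEFAULT_ALPHA_LEVELS, RunStatParams, estimate_p, run_frequency

__all__ = [
    "MarkerMatrix",
    "AxiomCall",
    "read_genotype_matrix",
    "filter_fixed_heterozygotes",
    "null_runs",
    "classify_interruptions",
    "is_het",
]

NULL_CALL = "---"


def is_het(call: str) -> bool:
    """True for genuine two-allele scores like ``T/G`` (not ``---``)."""
    if call == NULL_CALL or "/" not in call:
        return False
    a, b = call.split("/", 1)
    return a != b


@dataclass
class MarkerMatrix:
    """Ordered marker positions plus a markers x lines call table."""

    markers: pd.DataFrame  # columns marker_id, chrom, pos
    calls: pd.DataFrame  # index marker_id, one column per line

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos"}
        if not required <= set(self.markers.columns):
            raise ValueError(f"markers frame needs columns {sorted(required)}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if self.markers["pos"].isna().any():
            raise ValueError("markers with missing positions")
        order = self.markers.sort_values(["chrom", "pos"], kind="stable").index
        self.markers = self.markers.loc[order].reset_index(drop=True)
        self.calls = self.calls.loc[self.markers["marker_id"]]
        if (self.calls == "").any().any() or self.calls.isna().any().any():
            raise ValueError("every call must be non-empty")

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_tsv(self, path) -> None:
        out = self.markers.copy()
        for lid in self.line_ids:
            out[lid] = self.calls[lid].to_numpy()
        out.to_csv(path, sep="\t", index=False)


@dataclass
class AxiomCall:
    """A candidate deletion: a significant run of null marker scores."""

    line_id: str
    chrom: str
    start: int  # bp of first null marker
    end: int  # bp one past the last null marker (half-open)
    n_null: int
    E: float
    sig_tags: tuple[float, ...] = ()
    marker_ids: tuple[str, ...] = ()
    interruptions: list[dict] = field(default_factory=list)
    likely_contiguous: bool = False

    @property
    def n_interruptions(self) -> int:
        return len(self.interruptions)


def read_genotype_matrix(path) -> MarkerMatrix:
    """Read a genotype-call TSV: marker_id, chrom, pos, then line columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["marker_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}, got {list(df.columns[:3])}")
    if df["pos"].isna().any():
        bad = df.loc[df["pos"].isna(), "marker_id"].iloc[0]
        raise ValueError(f"{path}: marker {bad!r} has no position")
    line_cols = list(df.columns[3:])
    if not line_cols:
        raise ValueError(f"{path}: no line columns")
    markers = df[required].copy()
    calls = df[line_cols].copy()
    calls.index = markers["marker_id"]
    return MarkerMatrix(markers=markers, calls=calls)


def filter_fixed_heterozygotes(matrix: MarkerMatrix) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Drop markers scored heterozygous in every line.

    Such markers reflect probe/template mismatch rather than genotype
    and carry no deletion information.  Returns the filtered matrix and
    the removed markers.
    """
    if len(matrix.line_ids) < 2:
        raise ValueError("fixed-heterozygote filtering needs at least 2 lines")
    het = matrix.calls.map(is_het)
    fixed = het.all(axis=1).to_numpy()
    removed = matrix.markers[fixed].reset_index(drop=True)
    kept = MarkerMatrix(
        markers=matrix.markers[~fixed].reset_index(drop=True),
        calls=matrix.calls.loc[~fixed],
    )
    return kept, removed


def _marker_grid(matrix: MarkerMatrix) -> GenomeModel:
    """A degenerate one-window-per-marker grid so marker tracks can reuse
    the window run-assembly machinery."""
    sizes = matrix.markers.groupby("chrom", sort=True).size()
    return GenomeModel([(c, int(n)) for c, n in sizes.items()], window_size=1)


def null_runs(
    matrix: MarkerMatrix,
    line: str,
    min_run: int = 3,
    interruption_tolerance: int = 1,
    alpha_levels=DEFAULT_ALPHA_LEVELS,
    merge_gap_markers: int = 5,
) -> tuple[list[AxiomCall], list[str]]:
    """Candidate deletions for one line from its null-call track.

    Runs of "---" (interruptions of up to ``interruption_tolerance``
    valid calls tolerated) with at least ``min_run`` nulls become
    candidates; the chance expectation E uses the line's isolated-null
    rate and the marker count as track size.  Candidates separated by at
    most ``merge_gap_markers`` markers are merged as one deletion.

    Returns ``(candidates, isolated_null_marker_ids)``; isolated nulls
    are reported as low-confidence annotations, never as calls.
    """
    if line not in matrix.line_ids:
        raise ValueError(f"unknown line id {line!r}")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    # order calls identically to the marker-grid window order
    ordered = matrix.markers.sort_values(["chrom", "pos"], kind="stable")
    nulls = (matrix.calls[line].to_numpy() == NULL_CALL)
    grid = _marker_grid(matrix)
    track = FlagTrack(
        line_id=line, mode="hom_del", flags=nulls,
        mask=np.zeros(len(nulls), dtype=bool), grid=grid,
    )
    runs = find_runs(track, gap_tolerance=interruption_tolerance)

    candidates = [r for r in runs if r.n_flagged >= min_run]
    isolated = [r for r in runs if r.n_flagged < min_run]
    spans = [(r.first, r.last + 1) for r in candidates]
    try:
        p = estimate_p(nulls, spans)
    except ValueError:
        p = 0.0
    params = RunStatParams(p=p, n_intervals=matrix.n_markers, alpha_levels=tuple(alpha_levels))

    chroms = ordered["chrom"].to_numpy()
    pos = ordered["pos"].to_numpy()
    ids = ordered["marker_id"].to_numpy()

    calls: list[AxiomCall] = []
    for r in candidates:
        E = params.n_intervals * run_frequency(params.p, r.n_flagged)
        null_idx = np.asarray(r.window_indices)
        inter_idx = [i for i in range(r.first, r.last + 1) if i not in set(r.window_indices)]
        calls.append(
            AxiomCall(
                line_id=line,
                chrom=str(chroms[null_idx[0]]),
                start=int(pos[null_idx[0]]),
                end=int(pos[null_idx[-1]]) + 1,
                n_null=r.n_flagged,
                E=E,
                sig_tags=tuple(a for a in alpha_levels if E <= a),
                marker_ids=tuple(str(ids[i]) for i in null_idx),
                interruptions=[
                    {"marker_id": str(ids[i]), "call": str(matrix.calls[line].iloc[i])}
                    for i in inter_idx
                ],
            )
        )
    calls = _merge_marker_calls(calls, chroms, ids, merge_gap_markers)
    isolated_ids = [str(ids[r.window_indices[0]]) for r in isolated]
    return calls, isolated_ids


def _merge_marker_calls(
    calls: list[AxiomCall], chroms: np.ndarray, ids: np.ndarray, merge_gap_markers: int
) -> list[AxiomCall]:
    """Merge candidates separated by <= ``merge_gap_markers`` markers."""
    if not calls:
        return calls
    index_of = {str(m): i for i, m in enumerate(ids)}
    calls = sorted(calls, key=lambda c: index_of[c.marker_ids[0]])
    out: list[AxiomCall] = []
    cur = calls[0]
    for nxt in calls[1:]:
        gap = index_of[nxt.marker_ids[0]] - index_of[cur.marker_ids[-1]] - 1
        if nxt.chrom == cur.chrom and gap <= merge_gap_markers:
            cur = AxiomCall(
                line_id=cur.line_id,
                chrom=cur.chrom,
                start=cur.start,
                end=nxt.end,
                n_null=cur.n_null + nxt.n_null,
                E=min(cur.E, nxt.E),
                sig_tags=max(cur.sig_tags, nxt.sig_tags, key=len),
                marker_ids=cur.marker_ids + nxt.marker_ids,
                interruptions=cur.interruptions + nxt.interruptions,
            )
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def classify_interruptions(
    matrix: MarkerMatrix, call: AxiomCall, het_other_max: int = 0
) -> AxiomCall:
    """Label each interrupting marker of a candidate for reliability.

    ``line_specific_het``: heterozygous in the deletion line but in at
    most ``het_other_max`` other lines - almost certainly a mis-score of
    a hemizygous-looking signal.  ``inconsistent``: the call differs
    from the modal call of the other lines.  ``valid`` otherwise.  A
    candidate whose interruptions are all unreliable is flagged
    ``likely_contiguous``.
    """
    lookup = matrix.calls
    others = [l for l in matrix.line_ids if l != call.line_id]
    for item in call.interruptions:
        mid = item["marker_id"]
        this = str(lookup.loc[mid, call.line_id])
        other_calls = [str(lookup.loc[mid, l]) for l in others]
        if is_het(this):
            # heterozygous interruptions: unreliable only when private to
            # the deletion line (a hemizygous-looking mis-score)
            n_het_others = sum(is_het(c) for c in other_calls)
            item["reliability"] = (
                "line_specific_het" if n_het_others <= het_other_max else "valid"
            )
        else:
            valid_others = [c for c in other_calls if c != NULL_CALL]
            modal = max(set(valid_others), key=valid_others.count) if valid_others else None
            item["reliability"] = (
                "inconsistent" if (modal is not None and this != modal) else "valid"
            )
    call.likely_contiguous = bool(call.interruptions) and all(
        item["reliability"] != "valid" for item in call.interruptions
    )
    return call
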