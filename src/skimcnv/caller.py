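"""Window-depth CNV calling: flagging, run assembly, scoring, summaries.

Per line, each unmasked window is flagged into one of three depth
classes relative to the cross-line statistics:

* ``hom_del``  - normalized depth below ``mu - 3 sigma`` (candidate
  homozygous deletion);
* ``hemi_del`` - depth strictly closer to ``mu / 2`` than to ``mu``
  (candidate hemizygous deletion; homozygous deletions also satisfy
  this, so the hemizygous screen contains the homozygous one);
* ``dup``      - depth at least twice ``mu`` (candidate duplication).

Flagged windows are assembled into runs, tolerating short interruptions
(a single discordant window by default), and each run is scored with the
runs model: the expected number of equally long chance runs in the
track.  Because a hemizygous deletion also drags windows below the
``mu - 3 sigma`` line, a homozygous call is additionally required to sit
at near-zero depth (run median below ``mu / 4``, i.e. closer to zero
than to half depth); runs failing that are left to the hemizygous
screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth import DepthMatrix, WindowStats
from .genome import GenomeModel
from .runs import DEFAULT_ALPHA_LEVELS, RunStatParams, estimate_p, run_frequency

__all__ = [
    "FlagTrack",
    "Run",
    "CnvCall",
    "SpectrumSummary",
    "flag_windows",
    "find_runs",
    "call_events",
    "call_line",
    "call_population",
    "merge_nearby",
    "hom_within_hemi",
    "unique_deletions",
    "duplication_spacing",
    "estimate_deleted_bp_within_window",
]

MODES = ("hom_del", "hemi_del", "dup")

#: a homozygous call must have run median depth below this multiple of mu
HOM_MAX_RELATIVE_DEPTH = 0.25


@dataclass
class FlagTrack:
    """One line's boolean flag vector for one mode, plus the window mask."""

    line_id: str
    mode: str
    flags: np.ndarray  # over all grid windows; False wherever masked
    mask: np.ndarray
    grid: GenomeModel

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.flags = np.asarray(self.flags, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.flags[self.mask].any():
            raise ValueError("masked windows must not carry flags")

    @property
    def n_assayed(self) -> int:
        return int((~self.mask).sum())


@dataclass(frozen=True)
class Run:
    """A maximal group of flagged intervals allowing short interruptions.

    Indices are positions in the *assayable* (unmasked) subsequence of
    one chromosome's track; ``window_indices`` map back to the global
    grid.  ``n_flagged`` counts flagged intervals only; interruptions
    are the unflagged assayable intervals between the first and last.
    """

    first: int
    last: int  # inclusive, in assayable-track coordinates
    n_flagged: int
    n_interruptions: int
    window_indices: tuple[int, ...] = ()  # global indices of flagged windows


@dataclass
class CnvCall:
    """One called copy-number event."""

    line_id: str
    chrom: str
    start: int
    end: int
    mode: str
    n_windows: int
    n_interruptions: int
    E: float
    sig_tags: tuple[float, ...] = ()
    components: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.components:
            self.components = [(self.start, self.end)]

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "CnvCall") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def flag_windows(depth_norm: DepthMatrix, stats: WindowStats, mode: str) -> list[FlagTrack]:
    """Flag each line's windows into one depth class.

    Rules (x = normalized depth, per window): homozygous deletion
    ``x < mu - 3 sigma``; hemizygous deletion ``|x - mu/2| < |x - mu|``
    (strict, so the equidistant point 3 mu/4 is not flagged); duplication
    ``x >= 2 mu``.  Masked windows are never flagged.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if depth_norm.state != "normalized":
        raise ValueError("flag_windows expects a normalized matrix")
    if depth_norm.grid is not stats.grid and depth_norm.grid.n_windows != stats.grid.n_windows:
        raise ValueError("depth matrix and stats are on different grids")
    x = depth_norm.values
    mu, sigma = stats.mu, stats.sigma
    if mode == "hom_del":
        flags = x < (mu - 3 * sigma)
    elif mode == "hemi_del":
        flags = np.abs(x - mu / 2) < np.abs(x - mu)
    else:
        flags = x >= 2 * mu
    flags &= ~stats.mask
    return [
        FlagTrack(line_id=lid, mode=mode, flags=flags[i], mask=stats.mask, grid=depth_norm.grid)
        for i, lid in enumerate(depth_norm.line_ids)
    ]


def _runs_in_vector(flags: np.ndarray, gap_tolerance: int, window_indices: np.ndarray) -> list[Run]:
    """Assemble runs in one assayable boolean vector."""
    hits = np.flatnonzero(flags)
    if hits.size == 0:
        return []
    runs: list[Run] = []
    group_start = 0
    breaks = np.flatnonzero(np.diff(hits) - 1 > gap_tolerance)
    bounds = np.concatenate([breaks, [hits.size - 1]])
    for b in bounds:
        first, last = int(hits[group_start]), int(hits[b])
        n_flagged = b - group_start + 1
        runs.append(
            Run(
                first=first,
                last=last,
                n_flagged=int(n_flagged),
                n_interruptions=int(last - first + 1 - n_flagged),
                window_indices=tuple(int(w) for w in window_indices[hits[group_start : b + 1]]),
            )
        )
        group_start = b + 1
    return runs


def find_runs(flag_track: FlagTrack, gap_tolerance: int = 1) -> list[Run]:
    """Maximal flagged runs, tolerating internal gaps of <= ``gap_tolerance``.

    Masked windows are transparent: they count neither as flags nor as
    gaps.  Runs never join across chromosome boundaries.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    runs: list[Run] = []
    offset = 0
    for chrom, _ in flag_track.grid.chromosomes:
        sl = flag_track.grid.chrom_window_slice(chrom)
        assayable = np.flatnonzero(~flag_track.mask[sl]) + sl.start
        sub = flag_track.flags[assayable]
        for r in _runs_in_vector(sub, gap_tolerance, assayable):
            runs.append(replace(r, first=r.first + offset, last=r.last + offset))
        offset += len(assayable)
    return runs


def _sig_tags(E: float, alpha_levels) -> tuple[float, ...]:
    return tuple(a for a in alpha_levels if E <= a)


def call_events(
    runs: list[Run],
    params: RunStatParams,
    alpha_levels=DEFAULT_ALPHA_LEVELS,
    grid: GenomeModel | None = None,
    line_id: str = "",
    mode: str = "hom_del",
) -> list[CnvCall]:
    """Score runs with E = N * p**n (1-p)**2 and emit calls.

    The genomic span runs from the first flagged window's start to the
    last flagged window's end (interruptions are reported, not used to
    extend breakpoints).  ``sig_tags`` lists the alpha levels at which
    the chance expectation E falls at or below the threshold.
    """
    calls = []
    for r in runs:
        E = params.n_intervals * run_frequency(params.p, r.n_flagged)
        first_w, last_w = r.window_indices[0], r.window_indices[-1]
        if grid is not None:
            chrom = str(grid.window_chrom[first_w])
            if str(grid.window_chrom[last_w]) != chrom:
                raise ValueError("run crosses a chromosome boundary")
            start = int(grid.window_start[first_w])
            end = int(grid.window_end[last_w])
        else:
            chrom, start, end = "", first_w, last_w + 1
        calls.append(
            CnvCall(
                line_id=line_id,
                chrom=chrom,
                start=start,
                end=end,
                mode=mode,
                n_windows=r.n_flagged,
                n_interruptions=r.n_interruptions,
                E=E,
                sig_tags=_sig_tags(E, alpha_levels),
            )
        )
    return calls


def _hom_depth_ok(
    run: Run, depth_norm: DepthMatrix, stats: WindowStats, line_index: int
) -> bool:
    """Homozygous zygosity check: run median depth closer to 0 than mu/2."""
    idx = list(run.window_indices)
    rel = depth_norm.values[line_index, idx] / np.where(stats.mu[idx] > 0, stats.mu[idx], 1.0)
    return float(np.median(rel)) < HOM_MAX_RELATIVE_DEPTH


def _spans_from_bool(exclude: np.ndarray) -> list[tuple[int, int]]:
    """Half-open spans of True stretches in a boolean vector."""
    idx = np.flatnonzero(exclude)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def call_line(
    flag_track: FlagTrack,
    depth_norm: DepthMatrix | None = None,
    stats: WindowStats | None = None,
    gap_tolerance: int = 1,
    alpha_levels=DEFAULT_ALPHA_LEVELS,
    p_exclude_windows: np.ndarray | None = None,
) -> tuple[list[CnvCall], RunStatParams]:
    """Full calling pass for one line and mode, with p re-estimation.

    The chance-flag rate p is first estimated over the track, runs are
    provisionally accepted at the loosest alpha level, p is then
    re-estimated excluding accepted runs (so real events do not inflate
    the error rate) and every run is re-scored once.  For the
    homozygous mode, runs whose median depth is not near zero are
    dropped here and left to the hemizygous screen; passing the
    hemizygous call footprint as ``p_exclude_windows`` keeps
    deletion-driven flags out of the error-rate estimate.
    """
    runs = find_runs(flag_track, gap_tolerance)
    if flag_track.mode == "hom_del":
        if depth_norm is None or stats is None:
            raise ValueError("hom_del calling needs the depth matrix and stats")
        li = depth_norm.line_ids.index(flag_track.line_id)
        runs = [r for r in runs if _hom_depth_ok(r, depth_norm, stats, li)]
    assayable_flags = flag_track.flags[~flag_track.mask]
    N = flag_track.n_assayed
    base_exclude = (
        [] if p_exclude_windows is None
        else _spans_from_bool(np.asarray(p_exclude_windows, dtype=bool)[~flag_track.mask])
    )

    def score(p: float) -> tuple[list[CnvCall], list[Run]]:
        params = RunStatParams(p=p, n_intervals=N, alpha_levels=tuple(alpha_levels))
        calls = call_events(
            runs, params, alpha_levels, flag_track.grid, flag_track.line_id, flag_track.mode
        )
        accepted = [r for r, c in zip(runs, calls) if c.sig_tags]
        return calls, accepted

    def safe_p(spans) -> float | None:
        try:
            return estimate_p(assayable_flags, spans)
        except ValueError:  # spans cover the whole track
            return None

    p0 = safe_p(base_exclude)
    if p0 is None:
        p0 = estimate_p(assayable_flags)
    _, accepted = score(p0)
    spans = base_exclude + [(r.first, r.last + 1) for r in accepted]
    p1 = safe_p(spans)
    if p1 is None:
        p1 = p0
    calls, _ = score(p1)
    return calls, RunStatParams(p=p1, n_intervals=N, alpha_levels=tuple(alpha_levels))


def _call_footprint(calls: list[CnvCall], grid: GenomeModel) -> np.ndarray:
    """Boolean grid mask of windows covered by significant calls."""
    fp = np.zeros(grid.n_windows, dtype=bool)
    for c in calls:
        if not c.sig_tags:
            continue
        sl, _ = grid.overlap_fractions(c.chrom, c.start, c.end)
        fp[sl] = True
    return fp


def call_population(
    depth_norm: DepthMatrix,
    stats: WindowStats,
    modes=MODES,
    gap_tolerance: int = 1,
    alpha_levels=DEFAULT_ALPHA_LEVELS,
    merge_gap_bp: int = 200_000,
    significant_only: bool = True,
):
    """Run the caller for every line and mode.

    The hemizygous screen runs first; its significant call footprint is
    excluded from the homozygous channel's error-rate estimate, since a
    hemizygous deletion also drags windows below the homozygous flag
    line without being a homozygous event.  Returns ``(calls, params)``
    where ``params`` maps ``(line_id, mode)`` to the fitted
    :class:`RunStatParams`.  Calls are merged within ``merge_gap_bp``
    and, by default, filtered to those significant at some alpha level.
    """
    all_calls: list[CnvCall] = []
    fitted: dict[tuple[str, str], RunStatParams] = {}
    hemi_fp: dict[str, np.ndarray] = {}

    ordered = [m for m in ("hemi_del", "hom_del", "dup") if m in modes]
    for mode in ordered:
        for track in flag_windows(depth_norm, stats, mode):
            exclude = hemi_fp.get(track.line_id) if mode == "hom_del" else None
            calls, params = call_line(
                track, depth_norm, stats, gap_tolerance, alpha_levels,
                p_exclude_windows=exclude,
            )
            fitted[(track.line_id, mode)] = params
            if mode == "hemi_del":
                hemi_fp[track.line_id] = _call_footprint(calls, depth_norm.grid)
            all_calls.extend(calls)
    if significant_only:
        all_calls = [c for c in all_calls if c.sig_tags]
    return merge_nearby(all_calls, merge_gap_bp), fitted


def merge_nearby(calls: list[CnvCall], max_gap_bp: int = 200_000) -> list[CnvCall]:
    """Merge same-line same-mode calls separated by <= ``max_gap_bp``.

    Merging is transitive along the chromosome.  The merged call keeps
    the component spans (preserving split-deletion structure) and takes
    ``E`` from its strongest component.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    out: list[CnvCall] = []
    keyed: dict[tuple[str, str, str], list[CnvCall]] = {}
    for c in calls:
        keyed.setdefault((c.line_id, c.mode, c.chrom), []).append(c)
    for group in keyed.values():
        group = sorted(group, key=lambda c: c.start)
        cluster = [group[0]]
        for c in group[1:]:
            if c.start - cluster[-1].end <= max_gap_bp:
                cluster.append(c)
            else:
                out.append(_merge_cluster(cluster))
                cluster = [c]
        out.append(_merge_cluster(cluster))
    return sorted(out, key=lambda c: (c.line_id, c.mode, c.chrom, c.start))


def _merge_cluster(cluster: list[CnvCall]) -> CnvCall:
    if len(cluster) == 1:
        return cluster[0]
    components = [comp for c in cluster for comp in c.components]
    E = min(c.E for c in cluster)
    tags = max((c.sig_tags for c in cluster), key=len)
    return CnvCall(
        line_id=cluster[0].line_id,
        chrom=cluster[0].chrom,
        start=min(c.start for c in cluster),
        end=max(c.end for c in cluster),
        mode=cluster[0].mode,
        n_windows=sum(c.n_windows for c in cluster),
        n_interruptions=sum(c.n_interruptions for c in cluster),
        E=E,
        sig_tags=tags,
        components=sorted(components),
    )


def hom_within_hemi(calls: list[CnvCall], min_containment: float = 0.5) -> pd.DataFrame:
    """Associate homozygous calls with the hemizygous span containing them.

    A homozygous deletion nested in a longer hemizygous deletion is a
    common configuration; association requires at least
    ``min_containment`` of the homozygous span to lie within the
    hemizygous call.
    """
    homs = [c for c in calls if c.mode == "hom_del"]
    hemis = [c for c in calls if c.mode == "hemi_del"]
    rows = []
    for i, h in enumerate(homs):
        parent = None
        for j, z in enumerate(hemis):
            if z.line_id != h.line_id or z.chrom != h.chrom:
                continue
            ov = min(h.end, z.end) - max(h.start, z.start)
            if ov > 0 and ov / h.size >= min_containment:
                parent = j
                break
        rows.append(
            (h.line_id, h.chrom, h.start, h.end, parent,
             hemis[parent].start if parent is not None else pd.NA,
             hemis[parent].end if parent is not None else pd.NA)
        )
    return pd.DataFrame(
        rows,
        columns=["line_id", "chrom", "hom_start", "hom_end",
                 "hemi_index", "hemi_start", "hemi_end"],
    )


@dataclass
class SpectrumSummary:
    """Unique-deletion size spectrum and genome coverage."""

    bin_edges: np.ndarray  # bp, width = bin size
    counts: np.ndarray
    curve: np.ndarray  # fitted reciprocal reference c / size at bin midpoints
    unique_sizes: np.ndarray
    unique_deleted_bp: int
    genome_fraction: float
    n_unique: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size_lo": self.bin_edges[:-1],
                "size_hi": self.bin_edges[1:],
                "count": self.counts,
                "reciprocal_curve": self.curve,
            }
        )


def _union_bp(intervals: list[tuple[str, int, int]]) -> int:
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def unique_deletions(
    calls: list[CnvCall],
    genome_bp: int,
    reciprocal_overlap: float = 0.5,
    bin_bp: int = 10_000,
) -> SpectrumSummary:
    """Collapse same-locus deletion calls across lines and summarize.

    Calls (any deletion mode) whose reciprocal overlap is at least
    ``reciprocal_overlap`` are treated as one deletion shared by sibling
    lineages (single-linkage).  Each unique deletion's size is the span
    of the union of its members; the histogram uses ``bin_bp``-wide size
    classes with a fitted reciprocal (c / size) reference curve.
    """
    dels = [c for c in calls if c.mode in ("hom_del", "hemi_del")]
    if not dels:
        return SpectrumSummary(
            bin_edges=np.array([0, bin_bp]),
            counts=np.array([0]),
            curve=np.array([0.0]),
            unique_sizes=np.array([]),
            unique_deleted_bp=0,
            genome_fraction=0.0,
            n_unique=0,
        )
    # single-linkage clustering by reciprocal overlap
    parent = list(range(len(dels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(dels)):
        for j in range(i + 1, len(dels)):
            a, b = dels[i], dels[j]
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0 and ov / a.size >= reciprocal_overlap and ov / b.size >= reciprocal_overlap:
                parent[find(i)] = find(j)

    clusters: dict[int, list[CnvCall]] = {}
    for i, c in enumerate(dels):
        clusters.setdefault(find(i), []).append(c)

    sizes = []
    for members in clusters.values():
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        sizes.append(end - start)
    sizes = np.asarray(sorted(sizes))

    union_bp = _union_bp([(c.chrom, c.start, c.end) for c in dels])
    n_bins = max(1, int(np.ceil(sizes.max() / bin_bp)))
    edges = np.arange(0, (n_bins + 1) * bin_bp, bin_bp)
    counts, _ = np.histogram(sizes, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2
    # reciprocal reference scaled to the same total count
    curve = (1.0 / mids) * (counts.sum() / np.sum(1.0 / mids))
    return SpectrumSummary(
        bin_edges=edges,
        counts=counts,
        curve=curve,
        unique_sizes=sizes,
        unique_deleted_bp=int(union_bp),
        genome_fraction=union_bp / genome_bp,
        n_unique=len(sizes),
    )


def duplication_spacing(calls: list[CnvCall], threshold_bp: int = 1_000_000,
                        merge_gaps_bp=(200_000, 500_000, 1_000_000)) -> dict:
    """Gap sizes between consecutive same-chromosome duplication calls.

    Fragmented detection of one long duplication shows up as many calls
    separated by short gaps; the summary reports the gap distribution
    around ``threshold_bp`` (>= inclusive) and how many duplication
    events would remain if calls were merged at various gap sizes.
    """
    dups = sorted(
        (c for c in calls if c.mode == "dup"),
        key=lambda c: (c.line_id, c.chrom, c.start),
    )
    gaps = []
    for prev, cur in zip(dups, dups[1:]):
        if prev.line_id == cur.line_id and prev.chrom == cur.chrom:
            gaps.append(cur.start - prev.end)
    gaps = np.asarray(gaps, dtype=np.int64)
    merged_counts = {}
    for g in merge_gaps_bp:
        merged_counts[int(g)] = len(merge_nearby(dups, max_gap_bp=int(g))) if dups else 0
    return {
        "n_dups": len(dups),
        "gaps": gaps,
        "n_below_threshold": int((gaps < threshold_bp).sum()),
        "n_at_or_above_threshold": int((gaps >= threshold_bp).sum()),
        "threshold_bp": int(threshold_bp),
        "merged_dup_counts": merged_counts,
    }


def estimate_deleted_bp_within_window(
    x: float, mu: float, window_size: int = 10_000
) -> float:
    """Diagnostic sub-window deletion size from a single low window.

    For a deletion smaller than one window, the depth reduction is
    proportional to the deleted fraction: estimated deleted bp =
    ``window_size * (1 - x / mu)``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    return window_size * (1 - x / mu)
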