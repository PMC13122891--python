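"""Per-window read-depth matrices: ingestion, normalization, statistics.

The calling pipeline works on a lines x windows matrix of read counts.
Each line is normalized by its own median window count (robust to the
line's deletions), after which the per-window mean and standard
deviation across lines drive the three depth classes of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "DepthMatrix",
    "WindowStats",
    "read_window_counts",
    "normalize",
    "window_stats",
    "count_reads_in_windows",
]


@dataclass
class DepthMatrix:
    """Lines x windows read counts (raw) or unitless normalized depths."""

    grid: GenomeModel
    values: np.ndarray
    line_ids: list[str]
    state: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.line_ids), self.grid.n_windows):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {self.grid.n_windows} windows"
            )
        if self.state not in ("raw", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw":
            if np.any(self.values < 0) or not np.issubdtype(self.values.dtype, np.integer):
                raise ValueError("raw counts must be non-negative integers")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line(self, line_id: str) -> np.ndarray:
        return self.values[self.line_ids.index(line_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.grid.window_chrom,
                "start": self.grid.window_start,
                "end": self.grid.window_end,
            }
        )
        for i, lid in enumerate(self.line_ids):
            df[lid] = self.values[i]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path, line_id: str) -> None:
        """Write one line's track as 4-column bedGraph."""
        i = self.line_ids.index(line_id)
        pd.DataFrame(
            {
                "chrom": self.grid.window_chrom,
                "start": self.grid.window_start,
                "end": self.grid.window_end,
                "value": self.values[i],
            }
        ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class WindowStats:
    """Cross-line per-window depth statistics.

    ``mu``/``sigma`` are the mean and population standard deviation
    (divide by n) of normalized depth across lines; masked windows are
    excluded from flagging and are transparent to run assembly.
    """

    grid: GenomeModel
    mu: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.window_chrom,
                "start": self.grid.window_start,
                "end": self.grid.window_end,
                "mu": self.mu,
                "sigma": self.sigma,
                "masked": self.mask,
            }
        )


def _read_track(path) -> pd.DataFrame:
    """Read one bedGraph or 4-column TSV track (header optional)."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 1], str)
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=["chrom", "start", "end", "count"],
        dtype={"chrom": str},
    )
    for col in ("start", "end", "count"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+(\.\d+)?")].index
            line_no = (int(bad[0]) + 1 + int(has_header)) if len(bad) else "?"
            raise ValueError(f"{path}: malformed numeric field in line {line_no}")
    return df


def read_window_counts(paths, grid: GenomeModel, line_ids: list[str] | None = None) -> DepthMatrix:
    """Assemble a raw DepthMatrix from per-line track files.

    Every file must cover exactly the grid's windows (any row order);
    missing or extra intervals are an error naming the first offender.
    """
    paths = list(paths)
    if line_ids is None:
        import os

        line_ids = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    key_index = {
        (c, int(s)): i
        for i, (c, s) in enumerate(zip(grid.window_chrom, grid.window_start))
    }
    values = np.zeros((len(paths), grid.n_windows), dtype=np.int64)
    for row, path in enumerate(paths):
        df = _read_track(path)
        seen = np.zeros(grid.n_windows, dtype=bool)
        for c, s, e, v in zip(df["chrom"], df["start"], df["end"], df["count"]):
            idx = key_index.get((c, int(s)))
            if idx is None or int(e) != grid.window_end[idx]:
                raise ValueError(f"{path}: interval {c}:{int(s)}-{int(e)} not on the grid")
            if seen[idx]:
                raise ValueError(f"{path}: duplicate interval {c}:{int(s)}-{int(e)}")
            seen[idx] = True
            values[row, idx] = int(v)
        if not seen.all():
            i = int(np.flatnonzero(~seen)[0])
            raise ValueError(
                f"{path}: missing window {grid.window_chrom[i]}:"
                f"{grid.window_start[i]}-{grid.window_end[i]}"
            )
    return DepthMatrix(grid=grid, values=values, line_ids=line_ids, state="raw")


def normalize(depth_raw: DepthMatrix, mask: np.ndarray | None = None) -> DepthMatrix:
    """Divide each line by its own median count over unmasked windows.

    The median (not the mean) keeps the normalizer insensitive to the
    line's own large deletions or duplications.  Lines whose median
    count is zero cannot be normalized (failed sample).
    """
    if depth_raw.state != "raw":
        raise ValueError("normalize expects a raw matrix")
    if mask is None:
        mask = depth_raw.grid.partial_windows
    use = ~np.asarray(mask, dtype=bool)
    if not use.any():
        raise ValueError("all windows masked")
    med = np.median(depth_raw.values[:, use], axis=1)
    bad = np.flatnonzero(med <= 0)
    if len(bad):
        raise ValueError(
            f"line {depth_raw.line_ids[bad[0]]!r} has zero median depth (failed sample)"
        )
    return DepthMatrix(
        grid=depth_raw.grid,
        values=depth_raw.values / med[:, None],
        line_ids=list(depth_raw.line_ids),
        state="normalized",
    )


def window_stats(
    depth_norm: DepthMatrix,
    min_mu: float = 0.1,
    exclude_partial: bool = True,
    outlier_band: tuple[float, float] = (0.75, 2.0),
    min_lines: int = 3,
) -> WindowStats:
    """Per-window mean/SD of normalized depth across lines, plus mask.

    ``mu`` and ``sigma`` describe the depth of a *typical* line at each
    window, so lines that are themselves aberrant there - depth outside
    ``outlier_band`` times the cross-line median, i.e. in the deletion
    or duplication classes - are excluded from the estimate.  Without
    this, in modest populations the event-carrying lines drag
    ``mu - 3 sigma`` below zero over shared deletions and push
    ``2 mu`` above a duplicated line's own depth.  Windows where the
    band would leave fewer than ``min_lines`` lines fall back to all
    lines.  ``sigma`` is the ddof=1 sample SD (for three lines at 0.9,
    1.0, 1.1 it is exactly 0.1).

    Windows whose mean falls below ``min_mu`` are treated as unmappable
    and masked; short terminal windows are masked by default because
    their low counts mimic deletions.  Needs >= 3 lines.
    """
    if depth_norm.state != "normalized":
        raise ValueError("window_stats expects a normalized matrix")
    n = depth_norm.n_lines
    if n < 3:
        raise ValueError("window statistics need at least 3 lines")
    x = depth_norm.values
    med = np.median(x, axis=0)
    lo, hi = outlier_band
    ok = (x > lo * med) & (x < hi * med)
    fallback = ok.sum(axis=0) < min(min_lines, n)
    ok[:, fallback] = True
    n_ok = ok.sum(axis=0)
    mu = np.where(ok, x, 0.0).sum(axis=0) / n_ok
    resid2 = np.where(ok, (x - mu) ** 2, 0.0).sum(axis=0)
    sigma = np.sqrt(resid2 / np.maximum(n_ok - 1, 1))
    mask = mu < min_mu
    if exclude_partial:
        mask |= depth_norm.grid.partial_windows
    return WindowStats(grid=depth_norm.grid, mu=mu, sigma=sigma, mask=mask)


def count_reads_in_windows(
    bam_path, grid: GenomeModel, line_id: str | None = None, min_mapq: int = 0
) -> DepthMatrix:
    """Count mapped reads per window from a BAM/SAM file.

    Convenience ingestion hook: each read is assigned to the window
    containing its leftmost aligned position; unmapped reads and reads
    below ``min_mapq`` are skipped.
    """
    import os

    import pysam

    counts = np.zeros(grid.n_windows, dtype=np.int64)
    lengths = grid.chrom_lengths
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if chrom not in lengths:
                continue
            counts[grid.window_index(chrom, read.reference_start)] += 1
    if line_id is None:
        line_id = os.path.splitext(os.path.basename(str(bam_path)))[0]
    return DepthMatrix(grid=grid, values=counts[None, :], line_ids=[line_id], state="raw")
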