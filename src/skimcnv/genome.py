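"""Genome window grids.

A :class:`GenomeModel` holds chromosome lengths, a fixed non-overlapping
window grid (default 10 kb windows), and a per-window mappability factor
shared by every sample.  All coordinates are 0-based half-open (BED
convention); converters to the 1-based inclusive coordinates used in
printed genome positions live in :mod:`skimcnv.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel"]

DEFAULT_WINDOW_SIZE = 10_000


@dataclass
class GenomeModel:
    """Chromosome lengths plus a fixed window grid.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs, in the order windows are laid
        out.  Lengths must be positive.
    window_size
        Window width in bp.  The last window of a chromosome may be
        shorter (``ceil(length / window_size)`` windows per chromosome).
    mappability
        Optional per-window positive factor (dimensionless, mean ~1)
        modelling systematic coverage variation shared by all samples.
        Defaults to 1 everywhere.
    """

    chromosomes: list[tuple[str, int]]
    window_size: int = DEFAULT_WINDOW_SIZE
    mappability: np.ndarray | None = None

    # derived, filled in __post_init__
    window_chrom: np.ndarray = field(init=False, repr=False)
    window_start: np.ndarray = field(init=False, repr=False)
    window_end: np.ndarray = field(init=False, repr=False)
    chrom_offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

        chroms, starts, ends = [], [], []
        offsets: dict[str, int] = {}
        for name, length in self.chromosomes:
            offsets[name] = len(chroms)
            s = np.arange(0, length, self.window_size, dtype=np.int64)
            e = np.minimum(s + self.window_size, length)
            chroms.extend([name] * len(s))
            starts.append(s)
            ends.append(e)
        self.window_chrom = np.asarray(chroms, dtype=object)
        self.window_start = np.concatenate(starts)
        self.window_end = np.concatenate(ends)
        self.chrom_offsets = offsets

        if self.mappability is None:
            self.mappability = np.ones(self.n_windows)
        else:
            self.mappability = np.asarray(self.mappability, dtype=float)
            if self.mappability.shape != (self.n_windows,):
                raise ValueError(
                    f"mappability has shape {self.mappability.shape}, "
                    f"expected ({self.n_windows},)"
                )
            if np.any(self.mappability <= 0):
                raise ValueError("mappability factors must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.window_start)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    @property
    def window_widths(self) -> np.ndarray:
        return self.window_end - self.window_start

    @property
    def partial_windows(self) -> np.ndarray:
        """Boolean mask of terminal windows shorter than ``window_size``."""
        return self.window_widths < self.window_size

    def n_windows_chrom(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.window_size)

    def chrom_window_slice(self, chrom: str) -> slice:
        """Slice of the global window arrays covering one chromosome."""
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_windows_chrom(chrom))

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing ``pos`` on ``chrom``."""
        length = self.chrom_lengths[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        return self.chrom_offsets[chrom] + pos // self.window_size

    def overlap_fractions(self, chrom: str, start: int, end: int) -> tuple[slice, np.ndarray]:
        """Windows overlapped by [start, end) and the fraction of each
        window's width covered.  Returns (global window slice, fractions)."""
        if not 0 <= start < end <= self.chrom_lengths[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        first = self.chrom_offsets[chrom] + start // self.window_size
        last = self.chrom_offsets[chrom] + (end - 1) // self.window_size
        sl = slice(first, last + 1)
        ov_start = np.maximum(self.window_start[sl], start)
        ov_end = np.minimum(self.window_end[sl], end)
        frac = (ov_end - ov_start) / self.window_widths[sl]
        return sl, frac
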