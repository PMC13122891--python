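"""Synthetic skim-sequencing populations with known CNV truth sets.

This module generates everything the callers consume: a window grid with
shared mappability variation, implanted homozygous/hemizygous deletions
and duplications whose sizes follow a truncated reciprocal (1/size) law,
per-window Poisson read counts scaled by copy number, and SNP-array
genotype matrices in which deleted markers score as the null call "---".

The depth model is deliberately simple: reads land in a 10 kb window at a
Poisson rate proportional to ``lambda * mappability * copy_factor``,
where the copy factor is 1 for two intact homologues, 0.5 for a
hemizygous deletion, 0 for a homozygous deletion and >=2 for a
duplication.  Windows partially overlapped by an event scale
proportionally, as do short terminal windows.  Mappability is drawn once
per window and shared by every line, emulating the common coverage
profile of a population mapped to one assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DEFAULT_WINDOW_SIZE, GenomeModel

__all__ = [
    "TruthEvent",
    "TruthSet",
    "SimConfig",
    "make_genome",
    "implant_events",
    "sample_sizes",
    "simulate_depth",
    "simulate_marker_calls",
]

EVENT_KINDS = ("hom_del", "hemi_del", "dup")

#: expected-depth multiplier for each event class
COPY_FACTORS = {"hom_del": 0.0, "hemi_del": 0.5, "dup": 2.0}

NULL_CALL = "---"


@dataclass(frozen=True)
class TruthEvent:
    """One implanted copy-number event."""

    line_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    kind: str
    copy_factor: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.start}-{self.end}")
        lo, hi = {"hom_del": (0, 0), "hemi_del": (0.5, 0.5), "dup": (2, np.inf)}[self.kind]
        if not lo <= self.copy_factor <= hi:
            raise ValueError(
                f"copy_factor {self.copy_factor} inconsistent with kind {self.kind!r}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """All implanted events of a simulated population."""

    events: list[TruthEvent]
    size_law_exponent: float = 1.0
    seed: int | None = None

    def for_line(self, line_id: str) -> list[TruthEvent]:
        return [e for e in self.events if e.line_id == line_id]

    @property
    def line_ids(self) -> list[str]:
        return sorted({e.line_id for e in self.events})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.line_id, e.chrom, e.start, e.end, e.kind, e.copy_factor)
                for e in self.events
            ],
            columns=["line_id", "chrom", "start", "end", "kind", "copy_factor"],
        )

    def to_bed(self, path) -> None:
        """Write the truth ledger as BED with ``line:kind`` in the name column."""
        df = self.to_frame()
        out = df[["chrom", "start", "end"]].copy()
        out["name"] = df["line_id"] + ":" + df["kind"]
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SimConfig:
    """Population-level simulation parameters.

    ``mean_reads_per_window`` is the expected read count of a fully
    mappable 10 kb window at copy number two; 67 corresponds to ~1x
    coverage with 150 bp reads.  ``null_error_rate`` is the chance an
    intact marker scores "---" through technical failure and
    ``het_error_rate`` the chance a valid call is mis-scored as a
    heterozygote; ``fixed_het_fraction`` markers score heterozygous in
    every line (probe/template mismatch rather than true heterozygosity).
    """

    n_lines: int = 20
    mean_reads_per_window: float = 67.0
    marker_count: int = 71_562
    null_error_rate: float = 0.001
    het_error_rate: float = 0.03
    fixed_het_fraction: float = 1_623 / 71_562
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.mean_reads_per_window <= 0:
            raise ValueError("mean_reads_per_window must be positive")
        for name in ("null_error_rate", "het_error_rate", "fixed_het_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    def line_ids(self) -> list[str]:
        width = len(str(self.n_lines))
        return [f"line{str(i + 1).zfill(width)}" for i in range(self.n_lines)]


def _rng(seed, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


_STAGES = {"genome": 0, "events": 1, "depth": 2, "markers": 3}


def make_genome(
    chrom_lengths: dict[str, int] | list[tuple[str, int]],
    window_size: int = DEFAULT_WINDOW_SIZE,
    mappability_sd: float = 0.0,
    seed: int = 0,
) -> GenomeModel:
    """Build a window grid with lognormal per-window mappability.

    The mappability factors have mean 1 and standard deviation
    ``mappability_sd`` and are shared by all simulated lines.
    ``mappability_sd=0`` gives exactly 1 everywhere.
    """
    if mappability_sd < 0:
        raise ValueError("mappability_sd must be >= 0")
    chroms = list(chrom_lengths.items()) if isinstance(chrom_lengths, dict) else list(chrom_lengths)
    grid = GenomeModel(chroms, window_size=window_size)
    if mappability_sd > 0:
        # lognormal with E=1, SD=mappability_sd
        sigma2 = np.log1p(mappability_sd**2)
        mu = -sigma2 / 2
        rng = _rng(seed, "genome")
        grid.mappability = rng.lognormal(mu, np.sqrt(sigma2), size=grid.n_windows)
    return grid


def sample_sizes(
    rng: np.random.Generator, n: int, min_size: float, max_size: float, exponent: float = 1.0
) -> np.ndarray:
    """Draw event sizes from a truncated power law, density ~ size**(-exponent).

    The default exponent of 1 (frequency inversely proportional to size)
    is sampled by inverse CDF: ``s = min * (max/min)**u`` with u uniform.
    """
    if min_size > max_size:
        raise ValueError("min_size > max_size")
    if min_size == max_size:
        return np.full(n, float(min_size))
    u = rng.random(n)
    if exponent == 1.0:
        return min_size * (max_size / min_size) ** u
    # general truncated power law via inverse CDF
    a = 1.0 - exponent
    lo, hi = min_size**a, max_size**a
    return (lo + u * (hi - lo)) ** (1.0 / a)


def implant_events(
    genome: GenomeModel,
    n_lines: int,
    events_per_line: int,
    min_size: int = 30_000,
    max_size: int = 3_000_000,
    zygosity_mix: dict[str, float] | None = None,
    seed: int = 0,
    size_law_exponent: float = 1.0,
    line_ids: list[str] | None = None,
    max_retries: int = 1000,
) -> TruthSet:
    """Place non-overlapping events per line with 1/size frequencies.

    Chromosomes are chosen with probability proportional to length and
    start positions uniformly; proposals overlapping an earlier event of
    the same line are rejected and redrawn, erroring after
    ``max_retries`` failures (infeasible packing).
    """
    if events_per_line < 0:
        raise ValueError("events_per_line must be >= 0")
    longest = max(length for _, length in genome.chromosomes)
    if events_per_line > 0:
        if min_size < genome.window_size:
            raise ValueError("min_size must be at least one window")
        if max_size > longest:
            raise ValueError("max_size exceeds the longest chromosome")
    mix = zygosity_mix or {"hom_del": 0.5, "hemi_del": 0.35, "dup": 0.15}
    kinds = list(mix)
    probs = np.asarray([mix[k] for k in kinds], dtype=float)
    if np.any(probs < 0) or probs.sum() == 0:
        raise ValueError("zygosity_mix must have non-negative weights, not all zero")
    probs = probs / probs.sum()

    rng = _rng(seed, "events")
    names = [c for c, _ in genome.chromosomes]
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=float)
    chrom_p = lengths / lengths.sum()

    if line_ids is None:
        width = len(str(n_lines))
        line_ids = [f"line{str(i + 1).zfill(width)}" for i in range(n_lines)]

    events: list[TruthEvent] = []
    for line in line_ids:
        placed: dict[str, list[tuple[int, int]]] = {}
        for _ in range(events_per_line):
            for attempt in range(max_retries):
                size = int(round(sample_sizes(rng, 1, min_size, max_size, size_law_exponent)[0]))
                ci = rng.choice(len(names), p=chrom_p)
                chrom, length = names[ci], int(lengths[ci])
                if size > length:
                    continue
                start = int(rng.integers(0, length - size + 1))
                end = start + size
                if any(s < end and start < e for s, e in placed.get(chrom, [])):
                    continue
                placed.setdefault(chrom, []).append((start, end))
                kind = kinds[rng.choice(len(kinds), p=probs)]
                events.append(
                    TruthEvent(line, chrom, start, end, kind, COPY_FACTORS[kind])
                )
                break
            else:
                raise RuntimeError(
                    f"could not place event for {line} after {max_retries} retries "
                    "(infeasible packing)"
                )
    return TruthSet(events=events, size_law_exponent=size_law_exponent, seed=seed)


def copy_factor_matrix(genome: GenomeModel, truth: TruthSet, line_ids: list[str]) -> np.ndarray:
    """Effective per-window copy multiplier per line.

    A window partially overlapped by an event interpolates between 1 and
    the event's copy factor by the overlapped fraction of the window.
    """
    cf = np.ones((len(line_ids), genome.n_windows))
    index = {lid: i for i, lid in enumerate(line_ids)}
    for ev in truth.events:
        if ev.line_id not in index:
            raise ValueError(f"truth event for unknown line {ev.line_id!r}")
        sl, frac = genome.overlap_fractions(ev.chrom, ev.start, ev.end)
        cf[index[ev.line_id], sl] += (ev.copy_factor - 1.0) * frac
    return cf


def simulate_depth(genome: GenomeModel, truth: TruthSet, config: SimConfig):
    """Poisson per-window read counts for every line.

    ``count[j, i] ~ Poisson(lambda * mappability_i * copy_factor_ij *
    width_i / window_size)``; short terminal windows therefore collect
    proportionally fewer reads.  Returns a raw
    :class:`~skimcnv.depth.DepthMatrix`.
    """
    from .depth import DepthMatrix  # local import to avoid a cycle

    line_ids = config.line_ids()
    cf = copy_factor_matrix(genome, truth, line_ids)
    width_frac = genome.window_widths / genome.window_size
    mean = config.mean_reads_per_window * genome.mappability * width_frac * cf
    rng = _rng(config.seed, "depth")
    counts = rng.poisson(mean).astype(np.int64)
    return DepthMatrix(grid=genome, values=counts, line_ids=line_ids, state="raw")


_BASES = np.array(list("ACGT"))


def simulate_marker_calls(
    genome: GenomeModel, truth: TruthSet, config: SimConfig
) -> tuple["MarkerMatrix", pd.DataFrame]:
    """Simulate an array genotyping screen of the population.

    Marker positions are uniform over the genome.  In a given line a
    marker inside a homozygous deletion always scores "---"; a marker on
    an intact (or hemizygous) template scores "---" with probability
    ``null_error_rate``, a spurious heterozygote with probability
    ``het_error_rate``, and the line's true homozygous genotype
    otherwise.  A ``fixed_het_fraction`` of markers scores heterozygous
    in every line.

    Returns the marker matrix and a ledger frame attributing every "---"
    score to either a truth deletion or the noise channel.
    """
    from .axiom import MarkerMatrix  # local import to avoid a cycle

    if config.marker_count < 1:
        raise ValueError("marker_count must be >= 1")
    rng = _rng(config.seed, "markers")
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=float)
    names = [c for c, _ in genome.chromosomes]
    chrom_p = lengths / lengths.sum()
    ci = rng.choice(len(names), size=config.marker_count, p=chrom_p)
    pos = (rng.random(config.marker_count) * lengths[ci]).astype(np.int64)
    order = np.lexsort((pos, ci))
    ci, pos = ci[order], pos[order]
    chroms = np.asarray(names, dtype=object)[ci]
    marker_ids = np.asarray([f"M{str(i + 1).zfill(6)}" for i in range(config.marker_count)])

    # reference and alternate alleles per marker (alt used for het mis-scores)
    ref_idx = rng.integers(0, 4, size=config.marker_count)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.marker_count)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]
    hom_call = np.char.add(np.char.add(ref, "/"), ref)
    het_call = np.char.add(np.char.add(ref, "/"), alt)

    fixed_het = rng.random(config.marker_count) < config.fixed_het_fraction

    line_ids = config.line_ids()
    calls = np.tile(hom_call, (len(line_ids), 1))
    calls[:, fixed_het] = het_call[None, fixed_het]

    # deletion nulls are deterministic; noise channels apply to intact markers
    in_hom_del = np.zeros((len(line_ids), config.marker_count), dtype=bool)
    index = {lid: i for i, lid in enumerate(line_ids)}
    for ev in truth.events:
        if ev.kind != "hom_del":
            continue
        j = index[ev.line_id]
        hit = (chroms == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
        in_hom_del[j, hit] = True

    u = rng.random(calls.shape)
    noise_null = ~in_hom_del & (u < config.null_error_rate)
    noise_het = (
        ~in_hom_del
        & ~noise_null
        & ~fixed_het[None, :]
        & (u >= config.null_error_rate)
        & (u < config.null_error_rate + config.het_error_rate)
    )
    calls[noise_het] = np.broadcast_to(het_call, calls.shape)[noise_het]
    calls[in_hom_del | noise_null] = NULL_CALL

    ledger_rows = []
    for j, lid in enumerate(line_ids):
        for i in np.flatnonzero(in_hom_del[j]):
            ledger_rows.append((lid, marker_ids[i], "deletion"))
        for i in np.flatnonzero(noise_null[j]):
            ledger_rows.append((lid, marker_ids[i], "noise"))
    ledger = pd.DataFrame(ledger_rows, columns=["line_id", "marker_id", "null_source"])

    markers = pd.DataFrame({"marker_id": marker_ids, "chrom": chroms, "pos": pos})
    matrix = MarkerMatrix(
        markers=markers,
        calls=pd.DataFrame(calls.T, columns=line_ids, index=marker_ids),
    )
    return matrix, ledger
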