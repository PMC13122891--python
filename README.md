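# skimcnv

Deletion and duplication discovery in mutagenized plant populations from
two cheap genome-wide assays: low-coverage ("skim") short-read
sequencing and SNP-array genotyping. The package is aimed at groups
running forward/reverse genetic screens on fast-neutron (or similar
ionizing-radiation) mutant collections, where most induced mutations are
large deletions and the question is *which lines carry a deletion over
my locus of interest, and how much of the genome does the collection
already cover?*

## What it computes

**Windowed read-depth CNV calling.** Reads from each mutant line
(~1× coverage) are counted in fixed 10 kb windows; each line is
normalized by its own median window count, so the normalized depth
x<sub>ij</sub> of line *j* in window *i* is ~1 for two intact copies.
Against the cross-line per-window mean μ<sub>i</sub> and standard
deviation σ<sub>i</sub>, windows are flagged into three classes:

* homozygous deletion: x < μ − 3σ (and the run sits at near-zero depth),
* hemizygous deletion: x strictly closer to μ/2 than to μ,
* duplication: x ≥ 2μ.

**Runs-theory significance.** Isolated flags are indistinguishable from
error; real events produce contiguous runs. If flags occur by chance
independently with probability *p* per window, a maximal run of exactly
*n* flags occurs with frequency

&nbsp;&nbsp;&nbsp;&nbsp;F = pⁿ(1 − p)²

so over N windows the expected number of chance runs of length *n* is
E = N·F. A run is called significant at level α when E ≤ α. *p* is
estimated per line and per flag class from flags outside accepted runs,
with one re-estimation pass after provisional calling. The same
machinery yields the detection floor: the smallest *n* with E ≤ α times
the window size (3 windows = 30 kb at N = 4.45×10⁵, p = 0.004,
α = 0.05).

**Array null-call screen.** In an inbred background every line should
genotype identically on a SNP array; a marker whose assay returns no
signal in either channel ("---") in one line points at a deleted probe
sequence. Runs of ≥3 nulls (tolerating a single interrupting valid
call, which is often a mis-score) are scored with the same runs model,
and interrupting calls are classified for reliability (line-specific
heterozygote / inconsistent with the other lines / valid). Markers
heterozygous in *every* line are probe–template mismatches and are
removed first.

**Population summaries.** Unique deletions across sibling lines
(reciprocal-overlap collapsing), the deletion size spectrum against a
reciprocal (c/size) reference curve, duplication spacing diagnostics,
and genome-saturation arithmetic: if each of M families deletes an
average fraction f of the genome, a given locus is deleted somewhere
with probability P = 1 − (1 − f)ᴹ.

**Synthetic populations.** A generator simulates the whole study:
lognormal per-window mappability shared across lines, Poisson read
counts scaled by copy number (0 / 0.5 / 1 / ≥2), deletion sizes drawn
from a truncated 1/size law, and marker matrices with null and
heterozygote mis-score noise — with the full truth ledger returned, so
every stage of the caller is testable without any sequencing data.

## Worked example

```python
import skimcnv as sc
from skimcnv import io

grid = sc.make_genome({"chr1": 40_000_000, "chr2": 40_000_000},
                      mappability_sd=0.1, seed=42)
truth = sc.implant_events(grid, n_lines=12, events_per_line=3,
                          min_size=30_000, max_size=2_000_000, seed=42)
config = sc.SimConfig(n_lines=12, mean_reads_per_window=67.0,
                      marker_count=5_000, seed=42)
norm = sc.normalize(sc.simulate_depth(grid, truth, config))
stats = sc.window_stats(norm)
calls, fitted = sc.call_population(norm, stats)
print(io.calls_to_frame(calls)[["chrom", "start", "end", "name",
                                "score", "n_windows", "E"]].head(4))
```

```
chrom    start      end            name   score  n_windows             E
 chr1  1610000  2580000 line01:hemi_del 100.000         97 2.832610e-168
 chr1 36030000 36870000 line01:hemi_del 100.000         84 2.680013e-145
 chr2 15800000 16730000 line01:hemi_del 100.000         93 3.324374e-161
 chr1  1610000  2580000  line01:hom_del 100.000         97 2.094632e-225
```

Each row is one call: `score` is −log₁₀ of the chance expectation E
(capped at 100), `n_windows` the number of flagged windows. Note the
0.97 Mb homozygous deletion of line01 is also — correctly — detected by
the hemizygous screen, which subsumes it. Summaries:

```python
summary = sc.unique_deletions(calls, genome_bp=grid.total_bp)
f = sc.per_family_fraction(summary.unique_deleted_bp, grid.total_bp, 12)
print(summary.n_unique, summary.unique_deleted_bp, round(summary.genome_fraction, 4))
print(round(sc.hit_probability(f, 5000), 3))
```

```
31 11390000 0.1424
1.0
```

Twelve simulated lines already delete 14.2% of this (small) genome;
5,000 such families would saturate it. The fitted per-window error rate
for line01's homozygous channel is 4.4×10⁻³, giving a 30 kb detection
floor (`sc.detection_limit_bp(fitted[("line01", "hom_del")], 0.05)`).

A CLI wraps the same stages
(`skimcnv simulate | call-cnv | call-axiom | saturate | pipeline`); see
`skimcnv --help`. The scientific background, parameter defaults and
known limitations are documented in `docs/methods.md`.

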