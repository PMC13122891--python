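# Methods

This note documents the models behind `skimcnv`, the parameters that
matter, what the synthetic-data generator does and does not emulate,
and the numerical choices a user reproducing or extending the analyses
should know about.

## The detection problem

Ionizing-radiation mutagenesis (fast neutrons at tens of Gy) produces
mostly large deletions, occasionally accompanied by duplications when
an excised fragment re-inserts elsewhere and co-segregates with the
wild-type homologue. Two assays see these events cheaply at genome
scale:

1. **Skim sequencing.** ~1× short-read coverage per line, reads counted
   in fixed 10 kb windows along the assembly. A homozygous deletion has
   essentially no coverage, a hemizygous one about half, a duplication
   about double.
2. **SNP-array genotyping.** In a fully inbred background every line
   genotypes identically, so a marker returning no signal in either
   channel ("---", a null call) in one line indicates either a deleted
   probe sequence or a technical failure.

Both assays produce a linear track of per-interval detect/fail calls,
and in both the single-interval failure is uninformative: the signal is
*contiguity*.

## Depth model and normalization

Per-line window counts are modelled as Poisson with rate
λ·m<sub>i</sub>·c<sub>ij</sub>·(w<sub>i</sub>/w), where λ is the
expected count of a fully mappable window at copy number two (67 ≈ 1×
coverage with 150 bp reads in 10 kb windows), m<sub>i</sub> a per-window
mappability factor shared by all lines, c<sub>ij</sub> the line's copy
factor (0, 0.5, 1, ≥2), and w<sub>i</sub>/w the width fraction of short
terminal windows.

Each line is normalized by the **median** of its own window counts over
unmasked windows. The median, unlike the mean, is unaffected by the
line's own multi-megabase deletions or duplications, and makes
normalization idempotent up to per-line scale: doubling a line's
sequencing depth leaves its normalized track unchanged.

## Cross-line window statistics

Flagging compares each line to the *typical* line at each window:
μ<sub>i</sub> and σ<sub>i</sub> are the mean and sample SD (ddof = 1;
three lines at 0.9, 1.0, 1.1 give σ = 0.1 exactly) of normalized depth
across lines. In a modest population the event-carrying lines
themselves would distort these: two lines sharing a deleted window push
the plain mean down and the SD up until μ − 3σ < 0 (homozygous
deletions become unflaggable there), and a duplicated line drags 2μ
above its own depth. `window_stats` therefore excludes, per window,
lines whose depth falls outside a (0.75·median, 2·median) band — the
same "closer to half / at least double" classes the caller uses —
before computing μ and σ, falling back to all lines where fewer than 3
remain. With hundreds of lines and rare events the robust and plain
estimates coincide; the difference only matters for small populations.

Windows with μ below a floor (default 0.1) are masked as unmappable, as
are short terminal windows (their low counts mimic deletions); masked
windows are transparent to run assembly — neither flag nor gap.

## Flag classes and zygosity

For normalized depth x at a window with statistics (μ, σ):

* homozygous-deletion flag: x < μ − 3σ;
* hemizygous-deletion flag: |x − μ/2| < |x − μ| (strict, so the
  equidistant point 3μ/4 is not flagged);
* duplication flag: x ≥ 2μ (boundary inclusive).

The classes overlap by construction: zero depth is also "closer to
half than to full", so the hemizygous screen subsumes the homozygous
one — a property, not a bug, since genuinely nested homozygous segments
inside long hemizygous deletions occur and are reported by the
`hom_within_hemi` association. The converse overlap is the harmful
one: at ~1× coverage a hemizygous window (expected x ≈ 0.5) usually
also sits below μ − 3σ. A homozygous *call* therefore additionally
requires the run's median relative depth to be below μ/4 — closer to
zero than to half depth, the natural extension of the class logic —
and runs failing that are left to the hemizygous screen.

## Runs significance

Under a uniform per-interval error rate p, the chance frequency of a
maximal run of exactly n failures at a given position is approximated
by F = pⁿ(1−p)², the two boundary factors demanding the run be
delimited by successes; over N assayed intervals the expected number of
such chance runs per track is E = N·F. A run is tagged significant at
level α when E ≤ α (default levels 0.05 and 0.01). Runs of length ≥ n
are assessed by their own exact flagged length. The Monte-Carlo
calibration test verifies the formula against counted exact-length runs
on 10⁶-interval Bernoulli tracks across p ∈ {0.001, 0.01, 0.1}.

p is estimated separately per line and per flag class, since the error
channels differ (the homozygous channel's background is orders of
magnitude quieter than the hemizygous one). The estimate is flags
outside accepted runs / intervals outside accepted runs, with one
re-estimation pass: score with the whole-track estimate, provisionally
accept runs at the loosest α, re-estimate excluding them, re-score
once. For the homozygous channel the footprint of significant
hemizygous calls is also excluded from the estimate — those flags are
explained by a real (hemizygous) event, not error.

The detection floor is min{n : N·F(n) ≤ α} × window size. At the
full-study scale (N = 4.45×10⁵ windows, p = 0.004, α = 0.05) this is 3
windows = 30 kb. At the synthetic study conditions below, the
hemizygous channel's background (p ≈ 0.015–0.02 at λ = 67) puts its own
floor at 4 windows = 40 kb; smaller hemizygous events are genuinely
indistinguishable from chance at α = 0.05.

## Run assembly, merging, and spans

Runs tolerate internal interruptions of up to `gap_tolerance`
consecutive unflagged intervals (default 1, mirroring the marker
screen's "single valid call" rule; the 0-vs-1 choice was evaluated on
pooled simulations and is statistically neutral for recovery). Call
spans run from the first to the last *flagged* window — interruptions
are reported but never extend breakpoints. Same-line, same-class calls
within 200 kb (configurable) merge transitively into one call that
keeps its component spans — deletions genuinely split by a re-inserted
internal fragment stay visible as components — and takes E from its
strongest component.

Runs never join across chromosome boundaries, in either caller.

## Marker screen specifics

Markers heterozygous in **every** line are removed before calling: they
reflect probe/template mismatch, not genotype. Candidates are runs of
at least 3 nulls (interruption tolerance 1); nearby candidates within 5
markers merge, the distance being in markers rather than bp because
marker density varies. Isolated nulls are reported as low-confidence
annotations, never calls. Interrupting calls are classified:
`line_specific_het` (heterozygous in the deletion line only — a
hemizygous-looking mis-score), `inconsistent` (homozygous call
differing from the modal call of the other lines), else `valid`; a
candidate whose interruptions are all unreliable is flagged likely
contiguous. Hemizygous deletions are not callable from this assay — one
intact homologue still yields signal.

## Population summaries and saturation

Deletion calls are collapsed across sibling lineages by reciprocal
overlap ≥ 50% (single linkage); each unique deletion's size is the span
of its members' union. The size spectrum is binned in 10 kb classes
with a reciprocal reference curve c/size scaled to the same total
count, reflecting the observed ~1/size frequency law. Duplication
spacing diagnostics report the gap distribution between consecutive
duplication calls (≥ 1 Mb counted inclusively) and how many events
would remain under merging at several gap sizes — duplication detection
is intrinsically fragmentary, because the threshold 2μ sits exactly at
a duplicated window's expected depth, so roughly half its windows flag.

Saturation arithmetic assumes deletions are placed independently and
uniformly across families: with per-family deleted fraction
f = deleted bp / (genome bp × families screened), the probability that
a given locus is deleted in at least one of M families is
P = 1 − (1 − f)ᴹ. With a screened sample whose unique deletions cover
16.5% of the genome across 210 families, M = 5,000 gives P ≈ 0.98. The
independence/uniformity assumption is stated in every report; real
deletions cluster in gene-poor regions and sibling lineages share
events, both of which reduce effective coverage.

## Synthetic-data generator

The generator emulates the study conditions end to end:

| parameter | default | why |
|---|---|---|
| window size | 10 kb | the assay's resolution unit |
| λ (reads/window at CN 2) | 67 | ~1× coverage, 150 bp reads |
| mappability | lognormal, mean 1, SD 0.1 | shared per-window coverage texture; moderate, since array probes and skim windows in genic space behave well |
| deletion size law | ∝ 1/size on [30 kb, 3 Mb] | observed reciprocal spectrum; sampled by inverse CDF |
| zygosity mix | 0.50 hom / 0.35 hemi / 0.15 dup | deletions dominate; duplications are a minority of events concentrated in few lines |
| marker count | 71,562 | the screen's successfully scored, positioned markers |
| fixed-het fraction | 1,623 / 71,562 | probe-mismatch markers observed at this rate |
| marker het mis-score rate | 0.03 | the screen's overall non-fixed heterozygous score rate; an upper bound, since true residual heterozygosity cannot be separated |
| marker null error rate | 0.001 | chosen so isolated nulls are rare but present (~70 per line); the study's achieved type-I rate is not published at this granularity |

One global seed drives everything through deterministically derived
per-stage substreams, so identical configurations are byte-identical.

**What it does not emulate:** read-level artefacts (GC bias beyond the
lognormal factor, mapping ambiguity, duplicate reads), segregation
within families (each line is a fixed genotype), non-uniform event
placement, assembly errors, and physical re-insertion of duplicated
fragments (duplications are modelled purely as ≥2× depth over a span).
Passing recovery tests therefore demonstrates the statistical machinery
under the stated noise model, not robustness to every artefact of real
libraries.

## Test problem sizes

The recovery suite uses 12 replicate populations of 20 lines on a
200 Mb genome (5 × 40 Mb chromosomes) at λ = 67 with 5 events per line
— several hundred events pooled, so recovery rates are estimated to a
couple of percent while the whole suite runs in well under a minute.
Measured under these conditions: ~99% of homozygous and ~92% of
hemizygous deletions ≥ 30 kb are recovered with correct zygosity and
breakpoints within one window; false significant calls average ~0.02
per line at α = 0.05. The hemizygous shortfall is concentrated in
30–40 kb events below that channel's 40 kb floor (see above), which is
a property of the method at 1× coverage, not of the implementation.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; converters to/from
  1-based inclusive printed coordinates live in `skimcnv.io`.
* σ uses ddof = 1; the hemizygous tie (x = 3μ/4) is not flagged; the
  duplication boundary (x = 2μ) is; the ≥1 Mb duplication-gap boundary
  is inclusive.
* `estimate_p` refuses empty tracks and tracks fully covered by
  accepted runs; `normalize` refuses lines with zero median (failed
  samples); `window_stats` refuses fewer than 3 lines.
* Event placement rejects overlapping proposals within a line and
  errors after bounded retries rather than looping forever.
* `families_needed` corrects the closed-form ceiling by local search so
  its contract holds exactly at floating-point boundaries.
* A sub-window deletion diagnostic, deleted bp ≈ w·(1 − x/μ) for a
  single low window, is exposed for interpreting one-window depth dips;
  it assumes the reduction is entirely due to deletion within that
  window.

## Known limitations

* Breakpoints are window-quantized; no split-read refinement.
* Duplication sizes are underestimated and counts overestimated by the
  threshold effect described above; the spacing diagnostic quantifies,
  but does not undo, this.
* The saturation model ignores event clustering and sibling sharing.
* The marker screen cannot see hemizygous deletions at all, and single
  deleted markers only as annotations.
* p is assumed uniform along the track within a line and class;
  regional error-rate variation (e.g. repeat-dense regions) would
  locally miscalibrate E.
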