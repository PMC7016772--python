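# Methods

This note records the statistical procedures `gclens` implements, the
defaults and why, what the simulator does and does not emulate, and the
numerical choices that matter when reproducing results.

## Coverage and windowing

Internal coordinates are 0-based, half-open everywhere; the 1-based
per-base depth TSV dialect (as emitted by standard depth tools with
all-positions output) is converted at the parsing boundary. Depth from
alignments counts only primary records (secondary 0x100 and supplementary
0x800 flags excluded, unmapped ignored); reference positions under a read
deletion gain no depth, matching the pileup semantics of the common depth
tools. No duplicate-marking or mappability masking is applied.

Windows tile each contig from position 0 with stride equal to the window
width by default (non-overlapping), discarding a trailing partial window.
Non-overlapping windows keep per-bin standard deviations meaningful, since
overlapping windows would be strongly autocorrelated; `--stride` allows
overlap for users who want the fully sliding picture (the per-base track
export uses stride 1). GC is computed over unambiguous (A/C/G/T) bases
only, and windows with under 90% unambiguous bases are dropped
(`--min-unambiguous-frac`), so N-rich stretches of draft assemblies cannot
leak into the GC axis. Window mean depth averages over the full window
including N positions. A window's 1%-wide GC bin is the nearest integer
(half up), centring bins on integers so a 49.0%-GC window lands in the
normalization anchor bin.

## Contig filtering (genome mode)

Multicopy plasmids, prophages and collapsed repeats violate the
equal-abundance assumption, so before genome-mode analysis contigs are
filtered: length < 10 kb dropped (`--min-contig-length`; raise it for
assemblies with erratic coverage in mid-sized contigs), an explicit
exclude list for known plasmids, then a two-sided modified z-score on mean
per-base depth with threshold 10 (`--z-threshold`). The modified z-score
is 0.6745·(x − median)/MAD; when the MAD is zero it falls back to
(x − median)/(1.253314·meanAD), and to all-zero scores when even the mean
absolute deviation vanishes. The statistic is affine-invariant, so
filtering decisions do not depend on sequencing effort. Two-sided
filtering removes both over-covered (repeats, phage) and under-covered
(contaminant, degraded) contigs; the per-contig summary used is the mean
depth.

## Genome-mode bias curve

Windows are binned by GC; every window's depth is divided by the
arithmetic mean depth of the windows in the reference bin (default 49%,
`--reference-gc-bin`), chosen because genomes across a wide GC range all
populate it; bins with fewer than 3 windows are discarded
(`--min-bin-windows`). The per-bin summary is the arithmetic mean of
normalized coverage in linear space with the log taken afterwards — not
the mean of logs — together with the sample standard deviation (n−1).

The bias curve is a degree-2 weighted least-squares fit of log₁₀ per-bin
mean on GC percent with weights equal to the bin window counts,
implemented as a square-root-weighted `lstsq` and verified in the tests
against the closed-form normal equations. R² is computed with the same
weights about the weighted mean. Coefficient standard errors use the WLS
covariance (X′WX)⁻¹·σ̂² with σ̂² from the weighted residuals on n_bins − 3
degrees of freedom. With normalization on, the entire fit is invariant to
uniform depth rescaling. Quadratics are descriptive summaries, not
mechanistic models: real workflows deviate from them at GC extremes, and
the package deliberately offers no higher-order model selection or bias
*correction*.

The feature/background ratio is the mean per-base depth over the union of
the supplied intervals divided by the mean depth over all remaining
positions of the same contigs (contigs without features contribute
nothing). The two-amplicon read ratio counts primary alignments per
reference and reports their quotient, with an infinite ratio (plus
warning) on an empty denominator.

## Metagenome-mode ratio matrix

Contigs pass only the length cutoff — no coverage-based filtering, because
each contig is an independent genetic element of unknown abundance.
Within each contig, windows are binned by GC and per-bin mean depths
computed (bins with zero mean are excluded; the per-contig minimum windows
per bin defaults to 1, `--min-bin-windows-meta`). For every ordered pair
of bins present in a contig the coverage ratio is formed, ratios are
averaged arithmetically across all contigs containing both bins, and the
log₁₀ of the average is stored with the supporting contig count. Diagonal
entries are identically 0.

Arithmetic averaging of ratios makes the matrix asymmetric for more than
one contig: by AM–GM, M[i,j] + M[j,i] ≥ 0, with equality only when the
pair's ratio is identical in every contributing contig; the property tests
assert exactly this. `--geometric-mean` averages log-ratios instead, which
restores exact antisymmetry (enforced structurally, to the last bit, as is
single-contig antisymmetry). The export is a long-format TSV plus a static
heatmap whose cells fade with low contig support; entries backed by few
contigs should be read with caution.

## Read-quality diagnostics

Per-read GC is computed over unambiguous bases; the median Phred is over
all bases (mean of the central pair for even lengths). Percentiles for the
per-bin boxplot statistics (median, quartiles, 10th/90th) use linear
interpolation between order statistics. The filtering diagnostic compares
two read sets — normally produced upstream by a trimming tool with and
without quality filtering — as per-bin proportions of each set, reporting
their ratio; bins holding at least 0.1% of the unfiltered reads are
flagged abundant, since sparse bins give noisy ratios. A convenience
median-Phred threshold filter exists for simulation-driven comparisons
only; it is not a substitute for a real trimmer.

## Simulator

The simulator is the package's ground truth. Genomes are drawn with i.i.d.
bases per segment at a target GC (split evenly G/C and A/T), with optional
islands redrawn at their own GC overwriting their intervals. The canned
shapes reflect the study conditions the package is designed around: a
2 Mb chromosome sweeping 30–70% GC in 40 segments (bias-curve work), a
GC-poor (29%) chromosome with nine 5-kb GC-balanced (55%) islands
emulating rRNA loci in a GC-poor bacterium, and a mock metagenome of
30-kb contigs whose mean GCs spread over 25–75% with ±4% internal
structure so several bins populate each contig.

Sequencing is modelled as fragment selection: fragment start positions are
sampled with probability proportional to 10^e(g), where g is the
*fragment's* GC percent and e is the injected log₁₀ relative efficiency —
`none` (e ≡ 0), `quadratic` (a·g² + b·g + c, with c fixed so the maximum
efficiency over 0–100% GC is exactly 1), or `table` (an explicit
gc-bin → efficiency step function; a fragment uses the nearest listed
bin). The fragment count is set so the unbiased expectation of depth
equals the requested mean depth; multinomial placement then produces
Poisson-like per-window noise. All randomness flows through numpy's
seeded PCG64 generator, so outputs are byte-identical across runs and
platforms. Simulated reads carry Phred scores drawn per base around a
centre that is flat (default 38) up to a GC threshold (default 65%) and
falls by a slope (default 5 Phred units per GC point) above it, with
Gaussian noise (sd 3) and clipping to [2, 41] — a deliberately sharp
rendition of the empirical pattern that base quality collapses in GC-rich
reads, chosen so the interaction with median-Phred filtering is
unambiguous in tests.

Because bias acts on fragment GC while the analysis observes window GC,
the window-level curve is a smoothed version of the injected one: with
150-nt fragments and 500-nt windows the fitted quadratic is flattened by
roughly 9% (Jensen averaging of 10^e over the fragment-GC binomial spread,
plus window-GC measurement noise around segment GC). This is a property of
fragment-level selection, not an estimator defect — the same smoothing
affects real data. Parameter-recovery validation therefore uses 2000-nt
fragments and 5000-nt windows (window widths of 50–5000 nt all yield the
same qualitative curve; the trend-invariance test asserts sign agreement
of the curvature across 50/500/5000-nt windows), where the smoothing is
under 1% and the injected coefficients are recovered within statistical
error.

What the simulator does **not** emulate: platform error profiles, indels,
paired-end insert-size structure, reverse-strand sampling, duplicate
reads, mappability artefacts, and replication-origin coverage waves.
Passing recovery tests therefore demonstrates correctness of the
statistics under clean fragment-selection bias, not robustness to every
artefact of real libraries.

## Problem sizes and determinism

The validation experiments run at desk scale by design: 2 Mb genomes at
50× for the flatness null and parameter recovery, 500 kb with four 10-kb
islands at 30× for the island over-coverage ratio (expected 10-fold from
the 0.1 vs 1.0 efficiency table; island-edge fragments of mixed GC leave a
~1% downward edge effect), a 40-contig × 30-kb metagenome at 30×, and
20 000 simulated reads for the quality-filter interaction. All are fixed
by seeds; `scripts/acceptance.py` re-derives every number from a single
command-line seed.

## Known limitations

- The 49%-bin anchor requires the assembly to populate that bin; genomes
  with extreme global GC may need a different `--reference-gc-bin` (the
  error message lists viable candidates), and results are then relative to
  that bin instead.
- Arithmetic ratio averaging (metagenome mode) is upward-biased for noisy
  ratios (AM ≥ GM); the geometric option trades the literal definition for
  symmetry.
- Quadratic fits extrapolate poorly beyond the observed GC range; the
  vertex is meaningful only when it lies inside it.
- No GC-bias correction of abundances is attempted — the package measures
  bias; correcting for it is out of scope.
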