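# Methods

## Coordinate conventions

All intervals are 0-based half-open (BED). Overlap is "shares at least one
base": a read `[s, e)` overlaps a locus `[a, b)` iff `s < b` and `e > a`, so
abutting features never overlap. Overlap counting uses per-chromosome sorted
start/end arrays: the number of reads overlapping `[a, b)` equals
`#(starts < b) − #(ends ≤ a)` (the two excluded sets are disjoint), giving
O((n+m) log n) counting that is brute-force-oracle-tested.

## Locus preparation

Enhancer loci carry an **anchor** — the binding summit of the factor that
defines them — defaulting to the interval midpoint. Loci narrower than
`min_width` (default 600 bp) are extended to exactly `min_width`: the width
deficit is split floor/ceil left/right, and bases lost to clipping at
position 0 or the chromosome end are pushed to the other side, so output
width equals `min_width` whenever the chromosome permits. Anchors never
move, and the operation is idempotent. Extension uses the pad-split rule
around the existing interval; with midpoint anchors (the default and the
generated-data case) this is identical to centering on the anchor, which is
the intent — occupancy is assessed around the binding site. rpk always uses
the post-extension width.

Gene linkage assigns each locus the gene minimizing |TSS − anchor| on the
same chromosome. The anchor, not the interval edge, is the reference point
because it is the defined functional center. Exact-distance ties go to the
lexicographically smallest gene id — a documented convention, since real
annotations can put bidirectional promoters at equal distance. Loci on
chromosomes without any TSS are left unlinked with a warning rather than
failing the run.

## Spike-in normalization

For sample *s*, `H_s` is its target-genome read count and `S_s` its spike
count (recognized by chromosome prefix, default `dm6_`). Because every
sample received the same exogenous chromatin per cell, `S_s` estimates the
sample's library-depth × IP-efficiency scale. Normalization downsamples
target reads by `f_s = min_t(S_t) / S_s` (depth mode: `min_t(H_t) / H_s`):
this equalizes retained target reads per spike read across the group while
only ever removing reads, and leaves the shallowest sample intact. The
per-million spike scale `γ_s = 10⁶ / S_s` is reported for reference.
Downsampling is per-read Bernoulli from a named PCG64 generator seeded by a
user flag (default 1), bit-reproducible; when read names are present
(paired-end SAM), mates sharing a name get a single keep/drop draw.

## Quantification and filtering

Signal per locus is **rpk** — overlapping target reads divided by locus
width in kb — strand-agnostic (library strandedness of ribo-depleted eRNA
data is not assumed) and with each alignment counted once at its mapped
interval (no fragment extension). Control/treatment comparisons exclude a
locus only when *both* samples are below the assay floor — 30 rpk for ChIP,
10 rpk for eRNA, where detectable signal is intrinsically low; retained loci
keep raw values. Fold change is `log2((t + pc)/(c + pc))` with pseudocount
`pc = 1 rpk`, chosen so loci passing the OR-filter with one zero side still
get a finite, bounded estimate. Fold-change output covers the full locus
universe with a `passed_filter` flag (excluded loci carry NaN log2fc) so the
filter's effect stays visible.

Tornado matrices count reads per `b`-bp bin (default 50) over ±`W` (default
3000) around each anchor, scaled to reads per 10 million target reads; bins
beyond the chromosome start are zero. Rows can be ordered by total signal
for display.

## Sensitivity classification

Downregulated genes satisfy `log2FC < −0.5` **and** `FDR < 0.05`, both
strict, matching the printed thresholds; boundary values are excluded.
Genes with missing adjusted p (e.g. independent-filtering NAs) are retained
but never significant. A sensitive gene is a downregulated gene linked to at
least one enhancer; all enhancers of a sensitive gene are sensitive
(a gene may legitimately own several). Set overlaps report both
percentage directions so either set can serve as denominator.

## Statistics

Mann–Whitney U uses midranks; the p-value is exact (full enumeration of the
permutation null) when `n₁ + n₂ ≤ 12` with no ties, else the normal
approximation with tie and continuity corrections. Kruskal–Wallis uses the
tie-corrected H with a χ²(k−1) p-value; the all-identical degenerate case
returns H = 0, p = 1. These wrap scipy's implementations behind that
contract; the test suite cross-checks the exact path against an independent
enumeration oracle. BH-FDR is the standard step-up adjustment
(statsmodels). Tests are two-sided by default.

Bliss synergy: for observed single-agent inhibitions `E_a`, `E_b` in [0, 1]
(the dose-0 margins of the grid), the independence expectation at a
combination is `E_a + E_b − E_a·E_b`, and the score is
`100 × (observed − expected)` — percentage points, the SynergyFinder
convention, so "scores between 0 and 10" reads directly. Both the full score
matrix and its mean over true combinations (both doses > 0) are returned;
inhibitions outside [0, 1] are an error unless clipping is requested.

## Synthetic data

The generator emulates the study design, not sequence content (no bases, no
aligner round-trip). One target chromosome is tiled into equal blocks, one
locus per block center, widths uniform on 300–1200 bp so the 600 bp
extension is exercised. Each locus's designated gene gets a TSS 5–50 kb from
the anchor; one decoy TSS per block sits 60–90 kb out. Block size (200 kb at
the default 300 loci / 60 Mb) guarantees the designated TSS is provably
nearest to its own anchor, so linkage ground truth is exact by construction.

Reads are single-end 75 nt. Background is uniform at 20 reads/kb; each locus
receives Poisson extra reads bringing expected coverage to 10× background
(ChIP-scale enrichment), halved (`depletion = 0.5`) at a planted sensitive
subset (10% of loci) in the treatment condition. Poisson counts (not
negative-binomial) suffice because the downstream statistics are rank-based;
overdispersion would widen nulls the pipeline never tests per-locus. Spike
reads land on a dedicated prefixed chromosome with expectation
`0.25 × (untreated expected target total)` — the 1:4 cell-mixing design.
The spike expectation is deliberately condition-independent: exogenous
chromatin per cell does not shrink when treatment depletes target signal,
which is precisely why spike normalization can detect global loss. Each
sample draws one depth multiplier uniform on 1 ± 0.2 scaling both target and
spike expectations, emulating library-depth/IP-efficiency variation at a
fixed cell ratio; spike-mode factors must (and do) cancel it.

DE tables plant sensitive genes at `log2fc ~ N(−1.5, 0.3)`,
`padj = 10^−U(3,8)` against a `N(0, 0.2)`, `padj ~ U(0.2, 1)` null — the
null is never callable at the −0.5/0.05 thresholds, so end-to-end
classification recovery isolates linkage and set logic. Peak sets place one
peak inside each of `round(coverage × n)` uniformly chosen loci plus decoy
peaks that never touch loci. Dose grids use unit-slope Hill margins with
combinations at the Bliss expectation plus a configurable exact excess.

All randomness flows through PCG64 generators seeded from the config seed
plus fixed per-stage stream ids and CRC32 of sample ids: same config, same
bytes, any platform.

**What passing synthetic tests does not show:** real data have mappability
and GC structure, fragment-length effects, overdispersed counts, correlated
replicates, imperfect enhancer–gene assignment and DE tables estimated with
error. Recovery here validates the pipeline's arithmetic and logic under
the stated model, not biological discovery performance.

## Problem sizes and numerical choices

The packaged property checks run at: ≥ 2000 random instances for
interval-arithmetic oracles; 4 samples × ~1.6 M reads for normalization
recovery (CV of per-spike-read depth, observed ≈ 0.1%, bound 2%); 400 loci
(200 depleted) for fold-change recovery (medians within ±0.15 of −1 and 0
— the residual ≈ 0.03 offset at depleted loci comes from background reads
over extension flanks, which are not depleted); the default 300-locus study
for end-to-end precision/recall (≥ 0.95); 2000 null replicates at n = 50 per
group for type-I calibration ([0.04, 0.06] at α = 0.05); and 200 seeds for
downsampling's binomial law (≈ 99% inside the central 99% interval). These
sizes make the full suite run in well under a minute while leaving every
bound comfortably resolved.

Degenerate inputs are errors, not silent defaults: zero spike counts in
spike mode, zero-variance correlation columns, inverted intervals,
out-of-range p-values or inhibitions, unknown config keys, duplicate
gene/locus/sample ids.

## Known limitations

- One control/treatment pair per run config; replicate-aware designs are
  composed by running groups separately.
- No blacklist filtering, duplicate marking, or fragment-model options.
- `peak_signal_at_loci` (max overlapping signalValue) is quadratic in a
  naive loop — adequate for peak sets at enhancer scale, not genome-wide.
- The exact Mann–Whitney path is limited to n₁ + n₂ ≤ 12; larger samples use
  the corrected normal approximation, which is the regime the pipeline's
  group comparisons (hundreds of loci) always occupy.
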