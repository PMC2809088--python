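# Methods

`tilepath` reimplements, end to end and on synthetic data, a design-and-
analysis workflow for promoter-focused ChIP-chip on a draft genome:
isothermal tiling-probe selection, sliding-window enrichment detection
with a randomization-calibrated false discovery rate, assembly of a
promoter tile-path array under a probe budget, and downstream peak
annotation including EST-based linkage of promoter peaks to gene bodies
stranded on other assembly scaffolds.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); GFF3's
1-based closed coordinates are converted at the reader boundary. The
repeat mask is the union of soft-masked (lowercase) FASTA runs and any
explicit BED mask. Probe signal is exchanged as a plain tab-delimited
table (`probe_id, scaffold, start, end, <array>...`) holding
pre-normalized log2(ChIP/input) ratios; the package deliberately takes
no position on ratio normalization, which sits upstream of everything
implemented here.

## Isothermal probe tiling

Tiling arrays equalize hybridization behaviour by varying probe length
(50–75 bp) so that every probe's predicted melting temperature is as
close as possible to a common target (76 °C). Probes are anchored on a
fixed grid, one anchor every `spacing` bp (default 100) within each
unmasked run, so the mean start-to-start distance on unmasked sequence
equals the nominal spacing exactly. At each anchor the candidate length
minimizing |Tm − target| is kept; ties break to the shorter probe
(deterministic, and shorter oligos synthesize more reliably). A
candidate that crosses the mask, contains N, or runs off the scaffold is
discarded; an anchor with no valid candidate emits nothing.

Tm is the unified nearest-neighbor model:

    Tm(K) = 1000·ΔH / (ΔS + 0.368·(L−1)·ln[Na+] + R·ln(C/4))

with ΔH (kcal/mol) and ΔS (cal/mol·K) summed over dinucleotide stacks
plus terminal initiation terms, R = 1.987 cal/mol·K, monovalent salt
[Na+] = 0.05 M and total probe concentration C = 250 nM (C/4 for
excess-probe hybridization of non-self-complementary duplexes). The
tiler evaluates this vectorized via cumulative stack sums, which the
test suite pins to the scalar formula and to an independent
implementation of the same published parameter table.

Uniqueness is exact-match counting of each probe and its reverse
complement over both strands of the whole genome (overlapping
occurrences count); only probes with exactly one match survive
`filter_multimapping`. Near-exact (mismatched) repeats are not
considered — this mirrors the analysis-side filter, not a vendor
cross-hybridization model.

## Sliding-window peak detection and FDR calibration

The detector scans runs of consecutive probes on one scaffold; a run
breaks wherever adjacent probe starts are more than `max_probe_gap`
apart (default 500 bp), so windows never straddle masked deserts. A
window of `window_len` consecutive probes qualifies when **every** probe
value meets the threshold; overlapping qualifying windows union into one
peak spanning first probe start to last probe end. Three window lengths
(3, 4, 5 probes) with independent thresholds are scanned so that small
sharp peaks and broader, lower plateaus are both caught; peaks from
different windows that overlap are merged and their statistics
(n_probes, mean, max) recomputed from the constituent probes.

Thresholds are calibrated per array and window length against a
randomized control: the array's values are permuted once across probe
positions (coordinates untouched, seed-fixed), detection is repeated on
real and randomized data over an increasing threshold grid (default 0.1
to 4.0 log2 units in 0.1 steps), and the smallest threshold whose
randomized/real peak-count ratio — the *theoretical FDR* — falls below
the target (default 10%) is kept, together with the full trace.
Calibration fails loudly (with the best ratio reached) if the real peak
count hits zero first or the grid is exhausted.

Post-processing follows detection: peaks supported by a single probe are
removed, and peaks on one scaffold within 1.5 kb (inclusive) of each
other are merged transitively, summing probe counts and probe-weighting
means. Replicate consensus (`consensus_peaks`) averages probe values
across the named arrays before detection — a deliberately transparent
substitute for HMM-based joint replicate modeling, which is outside this
package's scope.

A note on monotonicity: the set of probes inside peaks shrinks (and
peaks nest) as the threshold rises, but the peak *count* can transiently
rise when one broad peak splits; the count is monotone in window length,
since peaks are maximal passing runs. The tests assert exactly these
properties.

## Promoter tile-path assembly

Design regions come from three partially overlapping sources: enriched
regions from an inclusive peak call, gene 5′ ends, and pre-computed
EST-derived TSS clusters — each widened by 2 kb per side, clipped to the
scaffold, and merged (touching regions merge; merged regions concatenate
their source tags). Whole background scaffolds can be added for
genomic-background estimation in later peak calling. The merged regions
are tiled with the isothermal tiler (anchors restart at each region) and
multi-mapping probes are dropped. If the result exceeds the probe budget
(default 2.1 million, one high-density array), assembly raises an
explicit budget error carrying the overshoot and a per-source probe
breakdown rather than trimming silently; `check_budget` reports headroom
and a relaxation direction. With isolated narrow seeds the median region
length is 2·extend plus the median seed width, ≈ 4 kb at defaults.

## Annotation

Distances are edge-to-edge gaps on half-open intervals (a peak [s, e)
and TSS t are 0 apart when s ≤ t < e, else t − e or s − t); "within
1 kb" is inclusive. Peak-gene association supports two anchors, because
the two summary statistics differ: distance to the TSS point (for
"within 1 kb of the TSS") and distance to the whole gene interval (for
"within 1 kb of genes"). Overlap between peak sets uses the ≥1 bp rule
against the union of the reference set. Overlap significance is a
permutation test: query peaks are re-placed uniformly within their own
scaffolds (lengths and scaffold assignment preserved, mutual overlap
allowed), and p = (1 + #perm ≥ observed)/(1 + n_perm); this conditions
on the observed length and scaffold distribution and is implemented with
vectorized coverage arithmetic so thousands of permutations are cheap.
The p-value is valid (super-uniform) but discrete; with few query peaks
it is conservative.

Per-peak mean signal averages the probes whose midpoints fall inside the
peak (probe-less peaks are flagged and excluded from correlations).
Correlations (Pearson/Spearman with two-sided p) are delegated to scipy.
TSS meta-profiles bin probe midpoints by offset from the TSS, negate
offsets on − strand genes so positive offsets always point downstream,
average within gene and then across genes, and report the gene count per
bin.

EST-based scaffold linkage applies two filters: an EST must align to
exactly two scaffolds, and an enrichment peak must lie within 1 kb
(edge-to-edge, per aligned block) of the EST on at least one of them.
Unordered scaffold pairs supported by at least two passing ESTs become
links; the nearest qualifying peak and its side are recorded.

## Synthetic data

The generator emulates the statistical structure of the real data
regime, not its sequence content: i.i.d. bases at GC 0.40, a random
repeat mask covering 10% of each scaffold, non-overlapping 2–8 kb genes
on both strands, probe log2 ratios that are Normal(0, 0.5) background
with flat Normal(2.0, 0.5) plateaus of 1 kb centered on the TSSs of a
random half of the genes, replicate arrays adding independent
Normal(0, 0.25), and split ESTs whose 5′ block sits at an enriched TSS
while the 3′ block lands on a different scaffold, mixed with one- and
three-scaffold decoys. Defaults are 4 scaffolds × 200 kb and 100 genes;
the acceptance script scales to 2 scaffolds × 5 Mb with 500 planted
regions. Everything is deterministic under the seed.

What this does *not* model: probe-sequence-dependent affinity, dye bias,
spatial artifacts, shoulder decay of enrichment, correlated noise, or
real repeat structure. Passing tests therefore demonstrate correctness
of the algorithms and their calibration behaviour under the stated noise
model — not performance on real arrays, whose headline numbers require
the original data.

## Numerical choices and limitations

Threshold comparisons use ≥ with no epsilon; values are taken as given.
One randomization per calibration, reused across the grid, keeps the FDR
trace comparable across thresholds. Fractions are reported alongside
exact rationals. Probe ids are coordinate-derived
(`scaffold:start-end`), making probe lists byte-reproducible. Problem
sizes in the test suite and acceptance script (tens of kb to a few Mb,
10²–10⁵ probes) were chosen so the full suite completes in a couple of
minutes on one CPU while keeping every statistical check well-powered.
Known limitations: exact-match-only uniqueness, value permutation (not
probe-position permutation — equivalent under fixed coordinates) for the
randomized control, and no automatic budget-overflow trimming.
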