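# Methods

This note documents the statistical model behind `damidtile`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Signal model and peak calling

DamID contrasts Dam-fusion samples against Dam-only controls on a
promoter tiling array. The processing chain is:

**Quantile normalization.** All sample columns are forced onto the
common distribution of per-rank cross-sample means. Ties within a column
receive the mean of the reference values over their rank range; as a
consequence the "sorted columns identical" property is exact only for
tie-free columns (ties necessarily average across ranks).

**Probe statistic.** A shrunken two-sample *t* per probe:

    t̃_i = (mean_fusion,i − mean_dam,i) / sqrt( s̃_i² (1/n_f + 1/n_d) )
    s̃_i² = (1 − λ) · s²_pooled,i + λ · s₀²,   s₀² = median_i s²_pooled,i

with λ = 0.5 by default. The upstream tiling-array tool this stands in
for does not publish its internal statistic; variance shrinkage toward
the across-probe median is the standard remedy for unstable per-probe
variances at n = 3 + 3 and λ is exposed for sensitivity analysis.
λ = 0 is the plain pooled-variance *t*; λ = 1 uses a single global
variance. Probes with zero shrunken variance get t̃ = 0 and a warning.

**Moving average.** A centered window of 5 probes (odd by construction),
truncated at chromosome edges and wherever consecutive probes are more
than `max_gap_bp` = 300 bp apart. 300 bp is an order of magnitude above
the ~10 bp inter-probe gap within a promoter window and far below the
inter-window distance, so windows never leak across array gaps.

**Region detection.** Maximal runs of consecutive probes with moving
average ≥ 3.5 containing at least 8 probes become peaks (the published
defaults for this array design). The peak spans first-probe start to
last-probe end — no fragment-length extension — and the summit is the
median probe midpoint. Whether the original rule required 8 probes above
the cutoff or 8 probes in the detected region is ambiguous; the strict
reading (every counted probe above cutoff) is the default, and
`bridge_below_cutoff=True` switches to the permissive one. Note that the
peak *count* is not monotone in the cutoff — a run can split into two
valid sub-runs at a higher cutoff — though total peak-covered probes is.

**Permutation FDR.** All balanced relabelings of the fusion/Dam-only
sample labels except the identity (19 for 3 + 3) are enumerated,
shuffled under the seed and truncated to `n_permutations`; the
statistic → moving-average → region-detection chain is re-run per
relabeling. FDR(c) = mean permuted peak count at cutoff c / observed
count, capped at 1; each observed peak is annotated with the FDR at its
own maximum moving-average statistic. Per-cutoff counts above the base
cutoff use the distribution of run-maximum statistics from a single
peak-calling pass (run-splitting at higher cutoffs is ignored); at the
base cutoff the estimate is the exact permuted/observed count ratio.
With zero observed peaks the ratio is 0/0 and reported as 0. Balanced
relabelings that mix conditions inflate within-group variance wherever
true signal exists, so the null peak count is conservative in the
presence of signal.

## Interval algebra and randomized nulls

Coordinates are 0-based half-open everywhere (BED convention); 1-based
inputs must be converted at the parser boundary. Overlap means ≥ 1 bp
under half-open arithmetic by default (`min_bp` configurable).

The A/B/C decomposition between a wild-type and a mutant peak set is
per-side: a WT peak overlapping two mutant peaks is one B_wt peak, so
|A| + |B_wt| = |WT| and |B_mut| + |C| = |MUT| always. Both B percentages
(of WT and of mutant totals) are reported.

Overlap significance uses randomly generated peak sets: each null draw
matches the query set in peak count and individual peak lengths and
places each peak uniformly over all valid start positions within
territory blocks that can contain it. The territory is the merged
probe-covered region (probes within 300 bp merged into blocks — tiling
arrays cover only a few percent of the genome, so genome-wide placement
would be anti-conservative). Inter-peak spacing is not preserved, and
null peaks may overlap each other. Empirical p-values use the
add-one rule p = (1 + #{null ≥ observed}) / (n_iter + 1), so p is never
0 and is uniform on a discrete grid under the null.

Gene-set overlaps use the exact hypergeometric two-sided Fisher test
(scipy); the odds ratio is the sample (a·d)/(b·c) with a Haldane 0.5
correction applied to all cells when any cell is zero.

## Genome statistics

Word scanning is exact (no IUPAC codes, no PWMs), reports overlapping
occurrences, and searches both strands by default — minus-strand matches
are reported at their forward coordinates. A palindromic word at one
position counts once. Windows containing N never match an ACGT word.
Spacing statistics are start-to-start distances between consecutive
occurrences on a chromosome, pooled across chromosomes (the alternative,
gap length, would run ~k bp shorter; the choice is recorded in the
output metadata). On an i.i.d. uniform genome the expected spacing of a
non-self-overlapping k-mer counted on both strands is 4^k / 2 per
strand-pair — for GATC, which is its own reverse complement, occurrences
coincide on both strands and the expectation is 4^4 = 256 bp.
Nearest-site distances are midpoint-to-midpoint, with inclusive cutoffs
for "within d bp" fractions; queries on anchor-free chromosomes are
infinite and excluded from medians.

## Regulatory domains and TSS distances

Basal domain: TSS − 6500 … TSS + 2500 (strand-aware), assigned
regardless of neighbours. Each side extends outward up to 100 kb but
stops at the nearest neighbouring gene's basal-domain edge and at
chromosome boundaries. A peak is assigned to every gene whose extended
domain it overlaps by ≥ 1 bp (many-to-many); summit-only assignment is a
mode. Summit-to-TSS distances are signed in the gene's orientation
(negative = upstream), ties broken toward the smaller absolute distance
and then the lower TSS coordinate. The background gene universe for
gene-set statistics is the set of genes whose basal domain overlaps at
least one probe.

## Tissue-expression profiles

Replicates are collapsed on the linear scale and transformed to
log2(mean + 1) ("NME"; the pseudocount is configurable and not dictated
by the source procedure). The background profile draws 1000 genes
without replacement, takes per-tissue medians, and averages 100 such
draws. The relative profile is target-median / background per tissue —
the upstream description literally words the ratio the other way
(background/input), which would invert the expected reading that
target-enriched tissues rank highest; the implemented direction is
recorded in the output metadata. Target-vs-random expression in a single
cell type uses the two-sided Mann–Whitney rank-sum test (exact null for
n ≤ 20 per group).

## Synthetic-data generator

The generator's defaults are the stated world of the package's
verification: 2 Mb of i.i.d. uniform ACGT sequence on 2 chromosomes, 200
genes, 9 kb promoter windows tiled with 25 bp probes every 35 bp
(~51,000 probes), 100 planted peaks (A=40, B=30, C=30) of width uniform
400–1200 bp each spanning ≥ 8 probes, log2 effect size 2.0, probe noise
SD 0.5, baseline N(8, 1) drawn once per probe and shared across all
samples, and 3 fusion + 3 Dam-only replicates. B peaks are planted as
overlapping-but-jittered WT/mutant pairs (shift up to ±width/3 inside
the window). The signal is a flat plateau over the peak span (a
triangular kernel is available via `signal_shape="triangular"`); peak
effects enter only fusion samples — Dam-only samples carry baseline and
noise only.

Because promoter windows cover 90% of the default genome, gene placement
uses sequential random-gap allocation (the slack outside the windows is
split uniformly at random into inter-window gaps) rather than rejection
sampling; it always succeeds when the windows fit and errors with a
suggestion to enlarge the genome otherwise.

**Motif planting is controlled presence.** A short word such as the
5-mer NKE occurs by chance in the large majority of kb-scale random
regions, so naively adding words cannot realise a target presence
fraction below the background (~0.79 for a 5-mer in these peak widths).
The generator therefore first scrubs chance occurrences of every
rate-configured word inside all planted regions (re-randomizing the
middle base of each occurrence until clean), then writes the word — on a
random strand, at a uniform-random offset avoiding previously planted
words — into a Bernoulli(rate) subset of planted loci. B pairs receive a
single draw with the word placed in the WT/mutant intersection so both
factors observe the same rate. The configured rate is thus exactly the
expected fraction of that factor's true peaks *containing* the word
(default: NKE at 0.79, the observed fraction in wild-type NKX2-5 peaks).
Words without a configured rate are untouched and sit at their
random-sequence background frequency.

What the generator does **not** emulate: PCR amplification bias, probe
GC/affinity effects, fragment-size distributions (plateau edges are
sharp), chromatin accessibility structure, non-uniform genomic base
composition, and correlated probe noise. A green test therefore
establishes that the algorithms are implemented correctly and are
well-calibrated in an idealised world — not that the defaults are
optimal for any particular real array.

## Determinism and seeds

Every stochastic component takes an explicit seed and uses
`numpy.random.default_rng`. The generator is byte-deterministic under a
fixed configuration. The pipeline derives per-stage seeds from one
global seed via `SeedSequence` (all below 2^31); fixed seed implies
bit-identical outputs, including the permutation order of the FDR and
all null draws.

## Known limitations

- The FDR curve above the base cutoff ignores run-splitting (see above);
  per-peak FDRs are monotone in the peak statistic by construction.
- `random_peak_null` requires every query peak to fit inside some
  territory block; studies whose peaks exceed the largest block error
  out rather than silently truncating.
- The empirical word-enrichment test replaces a model-based known-motif
  scorer; with words whose background presence is already near 1 (short
  words in wide peaks) it has little power by construction.
- Real-data use starts at probe-level intensity tables; array-image
  processing, probe remapping and de novo motif discovery are outside
  the package.
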