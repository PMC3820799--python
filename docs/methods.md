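# Methods

## Scope and data model

The package operates on four external inputs: a genome FASTA (used only for
cytosine-context classification), per-cytosine methylation count tables
(TSV: chrom, 1-based position, strand, context, methylated count, total
count), aligned-read interval sets (BED6, with the name column carrying a
U/M uniqueness flag and the score column a multiplicity), and gene
annotation (GFF3 gene features). Internally all coordinates are 0-based
half-open; 1-based conventions exist only at the TSV/GFF3 boundary. A
cytosine's context is decided solely by the two bases downstream on its own
strand: CG if the next base is G, CHG if the base after next is G, CHH
otherwise; sites with fewer than two downstream bases (chromosome ends) are
classified "incomplete" and excluded. Parsers reject invariant violations
(duplicate sites, methylated > total, inverted intervals) rather than
repairing them; the two documented drop-with-warning cases are
methylated > total TSV rows and inverted BED rows.

## DMR calling

One mutant methylome is tested against a WT replicate group (default four
replicates, matching the usual replication of wild-type methylomes in this
design).

**Coverage filter.** A CHH site is assayed iff its total count is
≥ `min_cov` (default 2) in a *strict majority* of WT libraries and in the
mutant. With four WT libraries a majority is three.

**Smoothing.** Raw per-site proportions are smoothed with a tricube kernel
(weight (1−u³)³, u = distance/half-width) over ±`half_width` (default
500 bp). Where fewer than `min_smooth_sites` (default 10) assayed sites fall
in the window, the half-width expands to the distance of the 10th-nearest
site plus 0.5 bp — the +0.5 keeps the boundary site's weight positive while
leaving dense regions untouched. Chromosomes with fewer than 10 assayed
sites are emitted unsmoothed with a warning. The WT group track smooths the
per-site mean of replicate proportions over replicates with nonzero
coverage; each replicate is also smoothed individually, and σ̂ at a site is
the across-replicate sample SD (ddof 1) of those smoothed replicate values.
This treats replicate-to-replicate disagreement of the *local* methylation
level as the noise scale, which is what the site statistic should be
calibrated against.

**Site statistic.** t = (μ̂_WT − μ̂_mut)/max(σ̂, σ_floor), with σ_floor the
genome-wide median of σ̂. The floor prevents division blow-ups where
replicates agree exactly (common in fully unmethylated stretches); the
median is a robust scale that leaves genuinely variable regions unaffected.
Positive t marks mutant hypomethylation; swapping the group roles negates
every t.

**Segmentation.** Candidates are maximal runs of consecutive assayed sites
with |t| > `t_cut` (default 2), uniform sign, and inter-site gaps ≤
`max_gap` (default 300 bp). An assayed site failing the cut breaks a run.
The candidate interval spans first to last member site (end exclusive).

**Filter cascade.** A candidate is a DMR iff it has ≥ `min_sites` (20)
member CHH sites, |mean difference| ≥ `min_meandiff` (0.1), and
|area| = |Σt| ≥ `min_area` (100). The mean difference is computed on *raw*
(unsmoothed) per-site proportions — the filter should measure effect size,
not smoother output. Ties at thresholds are retained (≥ semantics). Only
hypomethylation DMRs are emitted by default; the hyper direction is
available behind a flag. Note that with ≥ 20 sites all beyond |t| > 2 the
area magnitude already exceeds 40, so the area filter only binds through its
larger threshold — an invariant the audit asserts on every output.

**Audit.** `audit_dmrs` recomputes every clause for every emitted DMR from
the raw inputs (n sites, mean difference, area, per-site |t| > 2, sign
uniformity) and reports per-clause booleans; the pipeline requires a 100%
pass rate on its own output.

Open choices made here and why: bisulfite smoothing pipelines in this field
typically delegate the smoother to external code whose CHH-specific
bandwidth is not pinned down, so the kernel, bandwidth and segmentation gap
were genuinely open; tricube/500 bp/gap 300 were fixed once as a
deterministic, documented approximation of local-likelihood smoothing and
are exercised by the constant-track, step-monotonicity and
threshold-nesting properties. Computing the mean difference on smoothed
rather than raw values would also have been defensible; raw was chosen as
the more conservative effect-size measure.

## Region analysis

Interval overlap is ≥ 1 bp under half-open arithmetic everywhere. Venn
classes assign each DMR of each labeled set to the full set of labels it
overlaps; counts are reported per source set, so they partition each set
(two identical sets each report |A| in the shared class). Distance to the
nearest protein-coding gene is edge-to-edge, 0 when overlapping; DMRs on
gene-less chromosomes are reported missing and excluded from tests. The
distance comparison uses Welch's unequal-variance t test with
Welch–Satterthwaite degrees of freedom (two-sided). TSS-relative DMR
abundance is mean per-base DMR coverage in strand-oriented 100-bp bins
within ±2 kb of the TSS, divided by the number of DMRs in thousands —
invariant under duplicating the DMR set. The profile uses absolute bp around
the TSS (not gene-length scaling). Heat-map row ordering uses hierarchical
clustering with euclidean metric and average linkage (scipy), deterministic
for a fixed input order.

## Signal quantification

Read identity for duplicate collapsing is (chrom, start, end, strand);
length is implied by the coordinates, so per-position and per-region capping
coincide. ChIP/mRNA collapse to multiplicity 1; sRNA reads keep up to 100
identical copies, any excess flattened to the cap. The normalization total
(`total_mapped`) is the post-cap sum of multiplicities over all reads,
unique *and* non-unique; RPKM numerators count unique reads only, assigned
to a window by ≥ 1 bp overlap of the full read interval:
RPKM = unique multiplicity × 10⁹ / (window bp × total). DMR windows are
midpoint ± 500 bp (midpoint floors for odd lengths), clipped at chromosome
bounds with the denominator corrected to the realized length. Metaplots
scale each region body to 20 bins with 10 absolute-bp flank bins per side;
regions shorter than the bin count contribute through fractional bin
boundaries; every region carries equal weight. The Mann-Whitney U test uses
midrank ties; the p value is exact by full enumeration when n₁+n₂ ≤ 12
without ties, otherwise a normal approximation with tie and continuity
corrections (the tests document |p_exact − p_approx| < 0.06 at n = 8).
Tests are two-sided by default with the direction recoverable from the
reported statistic. The weighted-change table pairs each DMR's ChIP window
RPKM change (mutant − WT) with its weighted CHH methylation change
(pooled-WT Σm/Σt minus mutant) and reports their Spearman correlation.

## Expression

A promoter is the strand-oriented kilobase immediately 5′ of the TSS (a
common convention for the compact Arabidopsis genome; configurable), clipped
at chromosome bounds. Gene counts use unique reads with ≥ 1 bp overlap of
the gene interval — exon-level resolution is unnecessary because the
generator confines mRNA reads to gene bodies. Expression ratios are
log2((mutant CPM + 1)/(WT CPM + 1)) on per-million-normalized counts; the
pseudocount of 1 CPM keeps zero-count genes defined (ratio 0) and the
per-million normalization makes ratios invariant to library-size scaling.

## The synthetic generator

The generator defines the study conditions the pipeline is validated under.
Defaults: one 2-Mb uniform-random chromosome; 50 non-overlapping 1-kb
implants, each required to hold ≥ 30 CHH sites, pairwise separated by
≥ 2 kb and kept clear of chromosome ends by a margin that guarantees a
companion gene can always be placed; per-library per-site coverage
Poisson(8); site-level methylation proportions Beta-distributed around
regional means with concentration 20 (beta-binomial counts reproduce the
overdispersion real methylomes show, which the variance estimation must
tolerate); background levels CG 0.25, CHG 0.10, CHH 0.05; WT CHH level
inside implants 0.4, mutant level 0.4 − Δ with Δ = 0.3 by default. WT
replicates and the mutant share the per-site p everywhere except inside
implants, so the only genotype difference is the implanted one and a Δ = 0
mutant is exchangeable with a WT replicate. Annotation places a configurable
fraction of implants within ≤ 200 bp of a companion gene oriented so the
implant sits 5′ of the TSS (inside promoter space); remaining genes are
uniform, and genes never overlap implants or each other. ChIP reads mix a
uniform background with a 5′-gene component (starts within 500 bp downstream
of the TSS); the mutant adds Poisson extra reads inside implants to raise
local density `h3k4_gain`-fold over background. sRNA reads are 18–28 nt with
a 24-nt mode, mostly clustered uniformly on implants (background reads avoid
implants so that full depletion empties them exactly), with geometric
multiplicities (heavy right tail) and a configurable non-unique fraction;
the mutant thins cluster reads by `srna_depletion`. mRNA reads fall only
inside gene bodies at per-gene lognormal rates drawn from a
genotype-independent stream, so wild type and mutant differ only by
sampling noise. Everything is keyed off one integer seed through fixed
sub-streams; a fixed seed reproduces byte-identical outputs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: sequencing error and bisulfite-conversion
failure; mappability structure (uniqueness is a coin flip, not a genome
property); realistic genome composition (no repeats, no methylation
autocorrelation beyond the implants, uniform base composition); partial or
heterogeneous effects across cells; and combinatorial genotypes, which are
emulated only as larger effects at shared implants. Recovery at 100%
sensitivity on the defaults says the caller detects clean 0.3-effect,
1-kb regions at coverage 8 — not that it would do so on noisy field data.

## Problem sizes and runtimes

The test suite's recovery checks run the full reference scale (2 Mb,
~560,000 catalogued CHH sites, five libraries) in roughly half a minute per
scenario; integration analogues reuse the same genome with 100–200 implants
and 10⁵–2×10⁵ reads per assay. `scripts/acceptance.py` repeats all of it
from scratch in under a minute. The smoother is evaluated with a vectorized
offset-accumulation scheme (O(sites × mean window occupancy)) rather than a
per-site loop, which is what keeps whole-genome smoothing tractable in
numpy.

## Known limitations

Only CHH hypomethylation calling is implemented (CG/CHG calling and
hypermethylation analyses are out of scope; the hyper direction exists
behind a flag for symmetry checks). The caller assumes all libraries share
one site catalogue and errors otherwise, rather than intersecting
catalogues. Venn classes are reported per source set, not over a merged
union partition. The CLI consumes whole files into memory; chromosomes of
hundreds of Mb would need chunked IO that this package does not provide.
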