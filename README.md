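# rddm

Smoothing-based calling of CHH-context DNA hypomethylation regions and
multi-assay integration over those regions — H3K4m2/m3 ChIP-seq density,
24-nt siRNA abundance, and mRNA expression — packaged with a seeded
synthetic-data generator so the whole pipeline can be validated end to end
against a known ground truth.

## The problem

In *Arabidopsis thaliana*, RNA-directed DNA methylation (RdDM) deposits
cytosine methylation in all sequence contexts at transposons and other
repeats; the CHH context (C followed by two non-G bases) is its most
diagnostic readout. Histone H3K4 di-/trimethylation is an active chromatin
mark that antagonizes RdDM, and mutants of H3K4 demethylases lose CHH
methylation at a subset of RdDM targets — preferentially those close to
protein-coding genes — while gaining H3K4m2/m3 and losing 24-nt siRNAs, all
without transcriptional de-repression. Testing that chain of observations
requires a specific computational pipeline: a differentially-methylated-
region (DMR) caller with an explicit filter cascade, interval comparisons
against gene annotation, and normalized read-density quantification for
ChIP, small-RNA and mRNA libraries over DMR-anchored windows. This package
implements that pipeline as a tested, reusable library for anyone analysing
plant methylomes with matched chromatin and small-RNA data.

## The method

**DMR calling** compares one mutant methylome against a group of wild-type
replicates (four by default):

1. *Coverage filter*: keep CHH sites with total coverage ≥ 2 in a strict
   majority of the WT libraries **and** in the mutant library.
2. *Smoothing*: at each retained site, μ̂ is the tricube-kernel weighted
   mean of raw per-site methylation proportions within ±500 bp, the window
   expanding symmetrically until ≥ 10 sites are included. The WT group track
   smooths the per-site mean of replicate proportions; σ̂ is the
   across-replicate SD of the per-replicate smoothed tracks, floored at its
   genome-wide median.
3. *Site statistic*: t = (μ̂_WT − μ̂_mut) / max(σ̂, σ_floor); positive t
   means mutant hypomethylation.
4. *Segmentation and filters*: maximal same-sign runs of |t| > 2 with
   inter-site gaps ≤ 300 bp become candidates; a candidate is a DMR iff it
   covers ≥ 20 assayed CHH cytosines, its mean raw methylation difference is
   ≥ 0.1, and its area statistic |Σ t| ≥ 100. Ties at thresholds are kept.

**Quantification** follows the matching read-retention rules: identical
ChIP/mRNA reads collapse to one (PCR duplicates), identical sRNA reads are
kept up to a cap of 100; sRNA reads are retained at 18–28 nt with an exact
24-nt class for siRNA work; RPKM uses unique reads in the numerator and the
unique+non-unique total as denominator; a DMR's window is its midpoint
± 500 bp; every overlap question is ≥ 1 bp of half-open intervals. Group
comparisons use Welch's t test (nearest-gene distances) and the
Mann-Whitney U test (window densities).

**The generator** emulates the study design: beta-binomial methylomes with
implanted CHH-hypomethylated regions (WT level 0.4, mutant loss Δ), genes
with 5′-enriched ChIP signal and mutant-specific gains at implants,
24-nt-dominant siRNA clusters on the implants depleted in the mutant, and
gene-body-confined mRNA at genotype-identical rates. A truth file records
every implant so recovery can be scored.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
reference synthetic design (2-Mb genome, 4 WT replicates + 1 mutant at mean
coverage 8, 50 implanted 1-kb regions with effect 0.3). For example:

```sh
$ python analysis/02_call_dmrs.py
called 50 DMRs against 50 implants: sensitivity 1.00, FDP 0.00, audit pass 1.00
null mutant (no implanted effect) produced 0 DMR calls

$ python analysis/04_signal_quantification.py
H3K4 window RPKM: wt 305.6 -> mut 822.1 (MWU p = 2.46e-34)
24-nt siRNA RPKM: wt 6441.5 -> mut 2256.9 (MWU p = 2.52e-34)
per-region ChIP gain vs CHH loss: Spearman rho = -0.136 (uniform implanted
effects leave no across-region gradient)
```

Reading the numbers: every implanted hypomethylated region is recovered with
no false calls and the post-hoc audit re-verifies each filter clause; with a
3-fold implanted ChIP gain the mutant's window density roughly triples
(log2 ≈ 1.4) and with 0.9 siRNA depletion the 24-nt density drops, both at
vanishing Mann-Whitney p; the Spearman correlation between per-region ChIP
gain and methylation loss is near zero here because the generator implants
the *same* effect size everywhere — the statistic is exercised, the gradient
is absent by design. Each script writes its tables under `results/`.

The same pipeline runs from the shell on files (`rddm simulate`,
`rddm call-dmrs`, `rddm compare-dmrs`, `rddm quantify`, `rddm expression`,
`rddm run --config config.yaml --outdir out`), consuming methylation TSVs,
BED6 read sets, GFF3 annotation and FASTA genomes (all gzip-transparent).

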