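"""Transcription at DMRs and expression ratios of promoter-overlapping genes.

The promoter is the strand-oriented kilobase immediately 5' of the TSS
(clipped at chromosome bounds); gene counts use unique reads overlapping the
gene interval by >= 1 bp; expression ratios are log2 of per-million
normalized counts with a pseudocount so every gene has a defined ratio.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DMR, GeneModel, GenomicInterval, intervals_overlap
from .signal import CollapsedReadSet, SignalProfile, build_read_index, count_overlapping, metaplot


def promoter_of(gene: GeneModel, upstream: int = 1000,
                chrom_sizes: Mapping[str, int] | None = None) -> GenomicInterval | None:
    """Strand-oriented promoter: up to ``upstream`` bp immediately 5' of the TSS.

    Clipped at chromosome bounds; returns None for a gene whose promoter
    space has zero length (gene starting at the chromosome edge).
    """
    iv = gene.interval
    if iv.strand == "+":
        start, end = max(0, iv.start - upstream), iv.start
    else:
        start = iv.end
        end = iv.end + upstream
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def genes_with_dmr_promoters(genes: Sequence[GeneModel],
                             dmrs: Sequence[DMR | GenomicInterval],
                             upstream: int = 1000,
                             chrom_sizes: Mapping[str, int] | None = None
                             ) -> list[GeneModel]:
    """Genes whose promoter overlaps >= 1 bp with any DMR.

    Monotone in the DMR set: adding DMRs never removes genes.
    """
    intervals = [d.interval if isinstance(d, DMR) else d for d in dmrs]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for gene in genes:
        prom = promoter_of(gene, upstream=upstream, chrom_sizes=chrom_sizes)
        if prom is None:
            continue
        if any(intervals_overlap(prom, iv) for iv in by_chrom.get(prom.chrom, ())):
            out.append(gene)
    return out


def gene_counts(genes: Sequence[GeneModel], reads: CollapsedReadSet) -> np.ndarray:
    """Unique-read counts per gene (>= 1 bp overlap with the gene interval)."""
    index = build_read_index(reads)
    out = np.empty(len(genes))
    for i, gene in enumerate(genes):
        iv = gene.interval
        out[i] = count_overlapping(index, iv.chrom,
                                   np.array([iv.start]), np.array([iv.end]))[0]
    return out


def log2_expression_ratio(counts_mut: np.ndarray, counts_wt: np.ndarray,
                          total_mut: int, total_wt: int,
                          pseudocount: float = 1.0) -> np.ndarray:
    """log2((mut_cpm + pseudocount) / (wt_cpm + pseudocount)).

    Counts are normalized per million mapped reads before the pseudocount is
    added, so scaling a library's counts and total together leaves the ratio
    unchanged, and genes with zero counts in both libraries get ratio 0.
    """
    if total_mut <= 0 or total_wt <= 0:
        raise ValueError("library totals must be positive")
    norm_mut = np.asarray(counts_mut, dtype=float) * 1e6 / total_mut
    norm_wt = np.asarray(counts_wt, dtype=float) * 1e6 / total_wt
    return np.log2((norm_mut + pseudocount) / (norm_wt + pseudocount))


def expression_table(genes: Sequence[GeneModel], mrna_wt: CollapsedReadSet,
                     mrna_mut: CollapsedReadSet, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene counts, per-million values and log2 mutant/WT ratios."""
    counts_wt = gene_counts(genes, mrna_wt)
    counts_mut = gene_counts(genes, mrna_mut)
    ratio = log2_expression_ratio(counts_mut, counts_wt,
                                  mrna_mut.total_mapped, mrna_wt.total_mapped,
                                  pseudocount=pseudocount)
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "count_wt": counts_wt,
        "count_mut": counts_mut,
        "cpm_wt": counts_wt * 1e6 / mrna_wt.total_mapped,
        "cpm_mut": counts_mut * 1e6 / mrna_mut.total_mapped,
        "log2_ratio": ratio,
    })


def dmr_transcription_profile(dmrs: Sequence[DMR | GenomicInterval],
                              mrna_by_genotype: Mapping[str, CollapsedReadSet],
                              n_body_bins: int = 20, flank: int = 1000,
                              flank_bins: int = 10) -> dict[str, SignalProfile]:
    """mRNA metaplot over DMRs, one profile per genotype on identical regions.

    Delegates to the signal-quantification metaplot; per-million
    normalization is inherent in the RPKM scaling there.
    """
    intervals = [d.interval if isinstance(d, DMR) else d for d in dmrs]
    return {
        genotype: metaplot(intervals, reads, n_body_bins=n_body_bins,
                           flank=flank, flank_bins=flank_bins)
        for genotype, reads in mrna_by_genotype.items()
    }
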