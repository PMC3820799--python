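"""Comparisons between DMR sets and gene annotation.

Overlap is always >= 1 bp of half-open intervals. Distances to genes are
edge-to-edge (0 when overlapping). Group-location tests are the field's
standard ones: Welch's unequal-variance t test for distance comparisons and
hierarchical clustering (euclidean, average linkage) for heat-map row order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .core import GeneModel, GenomicInterval, TestResult, intervals_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "intervals_overlap", "venn_counts", "OverlapReport",
    "distance_to_nearest_gene", "welch_t_test", "tss_relative_abundance",
    "cluster_rows",
]


@dataclass
class OverlapReport:
    """Venn classification of 2-3 labeled DMR sets.

    ``per_set[label]`` maps a membership class (a sorted tuple of set labels)
    to the number of ``label``'s DMRs assigned to that class; every DMR is
    assigned to exactly one class (the full set of labels it overlaps), so
    the counts for a set partition it.
    """

    labels: tuple[str, ...]
    per_set: dict[str, Counter] = field(default_factory=dict)

    def class_count(self, source: str, members: Sequence[str]) -> int:
        return self.per_set[source][tuple(sorted(members))]


def _check_internally_disjoint(label: str, intervals: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"set {label!r} contains internally overlapping intervals; "
                    "merge them before computing Venn classes"
                )


def venn_counts(dmr_sets: Mapping[str, Sequence[GenomicInterval]],
                min_bp: int = 1) -> OverlapReport:
    """Assign each DMR to the class of sets it overlaps (>= ``min_bp`` bp).

    Requires 2-3 labeled, internally non-overlapping sets. A DMR overlapping
    several intervals of another set is still counted once.
    """
    labels = tuple(dmr_sets)
    if not (2 <= len(labels) <= 3):
        raise ValueError("venn_counts expects 2 or 3 labeled sets")
    for label, ivs in dmr_sets.items():
        _check_internally_disjoint(label, ivs)
    report = OverlapReport(labels, {label: Counter() for label in labels})
    for label, ivs in dmr_sets.items():
        for iv in ivs:
            members = [
                other for other in labels
                if other == label or any(
                    intervals_overlap(iv, jv, min_bp) for jv in dmr_sets[other]
                )
            ]
            report.per_set[label][tuple(sorted(members))] += 1
    return report


def distance_to_nearest_gene(dmrs: Sequence[GenomicInterval],
                             genes: Sequence[GeneModel]) -> np.ndarray:
    """Edge-to-edge distance from each DMR to its nearest gene (0 if overlapping).

    DMRs on chromosomes with no genes get NaN (logged), to be excluded from
    downstream tests.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {g.interval.chrom for g in genes}:
        ivs = sorted((g.interval for g in genes if g.interval.chrom == chrom),
                     key=lambda iv: iv.start)
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])
    out = np.empty(len(dmrs))
    for i, dmr in enumerate(dmrs):
        if dmr.chrom not in starts:
            logger.warning("DMR %s:%d-%d on a chromosome with no genes; distance missing",
                           dmr.chrom, dmr.start, dmr.end)
            out[i] = np.nan
            continue
        s, e = starts[dmr.chrom], ends[dmr.chrom]
        # gap to genes entirely left / right of the DMR; 0 if any overlap
        gaps_right = s - dmr.end          # gene starts after DMR ends
        gaps_left = dmr.start - e         # gene ends before DMR starts
        if ((s < dmr.end) & (e > dmr.start)).any():
            out[i] = 0.0
        else:
            candidates = np.concatenate([gaps_right[gaps_right >= 0],
                                         gaps_left[gaps_left >= 0]])
            out[i] = float(candidates.min())
    return out


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sample t test, two-sided.

    Reports the t statistic, Welch-Satterthwaite degrees of freedom and the
    two-sided p value. Degenerate samples (n < 2, or both variances zero)
    raise with the offending sample named.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    for name, arr in (("x", x), ("y", y)):
        if len(arr) < 2:
            raise ValueError(f"sample {name} has fewer than 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            # identical constant samples: no evidence of any difference
            return TestResult("welch_t", 0.0, 1.0, len(x), len(y),
                              method="welch-satterthwaite")
        raise ValueError("both samples have zero variance (x and y degenerate)")
    res = sps.ttest_ind(x, y, equal_var=False)
    # Welch-Satterthwaite df, recorded with the result
    se2x, se2y = vx / len(x), vy / len(y)
    df = (se2x + se2y) ** 2 / (se2x ** 2 / (len(x) - 1) + se2y ** 2 / (len(y) - 1))
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      len(x), len(y), method=f"welch-satterthwaite df={df:.4g}")


def welch_df(x: Sequence[float], y: Sequence[float]) -> float:
    """Welch-Satterthwaite degrees of freedom for two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    se2x = x.var(ddof=1) / len(x)
    se2y = y.var(ddof=1) / len(y)
    return float((se2x + se2y) ** 2
                 / (se2x ** 2 / (len(x) - 1) + se2y ** 2 / (len(y) - 1)))


def tss_relative_abundance(dmrs: Sequence[GenomicInterval],
                           genes: Sequence[GeneModel],
                           flank: int = 2000, bin_width: int = 100) -> pd.DataFrame:
    """Relative DMR abundance in strand-oriented bins around gene TSSs.

    Each bin's value is the mean per-base DMR coverage over all genes,
    divided by the number of DMRs in thousands, so the profile is invariant
    to duplicating the DMR set. Returns a frame with the bin midpoint
    (bp relative to the TSS, negative = upstream) and the value.
    """
    if len(dmrs) == 0:
        raise ValueError("tss_relative_abundance requires at least one DMR")
    n_bins = 2 * flank // bin_width
    # per-base DMR coverage, computed per chromosome via a difference array
    cov: dict[str, np.ndarray] = {}
    chrom_max: dict[str, int] = {}
    for iv in dmrs:
        chrom_max[iv.chrom] = max(chrom_max.get(iv.chrom, 0), iv.end)
    for g in genes:
        chrom_max[g.interval.chrom] = max(chrom_max.get(g.interval.chrom, 0),
                                          g.tss + flank + 1)
    for chrom, m in chrom_max.items():
        cov[chrom] = np.zeros(m + 1)
    for iv in dmrs:
        cov[iv.chrom][iv.start] += 1
        cov[iv.chrom][iv.end] -= 1
    for chrom in cov:
        cov[chrom] = np.cumsum(cov[chrom])[:-1]

    acc = np.zeros(n_bins)
    for g in genes:
        c = cov[g.interval.chrom]
        tss = g.tss
        # window of 2*flank bases centered on the TSS, 5'->3' of the gene
        if g.interval.strand == "+":
            lo = tss - flank
            window = np.zeros(2 * flank)
            src_lo, src_hi = max(lo, 0), min(tss + flank, len(c))
            if src_hi > src_lo:
                window[src_lo - lo : src_hi - lo] = c[src_lo:src_hi]
        else:
            lo = tss - flank + 1
            window = np.zeros(2 * flank)
            src_lo, src_hi = max(lo, 0), min(tss + flank + 1, len(c))
            if src_hi > src_lo:
                window[src_lo - lo : src_hi - lo] = c[src_lo:src_hi]
            window = window[::-1]
        acc += window.reshape(n_bins, bin_width).mean(axis=1)

    profile = acc / len(genes) / (len(dmrs) / 1000.0)
    midpoints = (np.arange(n_bins) - n_bins // 2) * bin_width + bin_width // 2
    return pd.DataFrame({"bin_midpoint": midpoints, "value": profile})


def cluster_rows(matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of rows (euclidean metric, average linkage).

    Returns (row order, linkage matrix). Deterministic for a fixed input
    order; scipy breaks distance ties by merge index. Rows with missing
    values are rejected — impute or drop upstream.
    """
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("cluster_rows requires a 2-D matrix with >= 2 rows")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains missing/non-finite values; "
                         "impute or remove those rows first")
    linkage = hierarchy.linkage(values, method="average", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return order, linkage
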