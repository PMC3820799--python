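"""Read-density quantification over DMR windows and scaled metaplot regions.

Retention rules follow the study design the caller implements: identical
reads are collapsed to one for ChIP/mRNA (cap 1) while up to 100 identical
small-RNA reads are kept as distinct (cap 100); sRNA reads are retained at
18-28 nt with an optional exact size class (24 nt for siRNA work); density
numerators use unique reads only, with the unique+non-unique total as the
normalization denominator; reads are assigned to a window by >= 1 bp overlap
of the full read interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DMR, GenomicInterval, MethylomeTable, ReadSet, TestResult
from .dmr import weighted_methylation


class CollapsedReadSet(ReadSet):
    """A ReadSet after duplicate collapsing/capping, with its normalizer.

    ``total_mapped`` is the sum of retained multiplicities over all reads,
    unique and non-unique; RPKM numerators use unique reads only.
    """

    def __init__(self, df: pd.DataFrame, cap: int, total_mapped: int, assay: str = ""):
        super().__init__(df, assay=assay)
        if len(df) and (df["multiplicity"] > cap).any():
            raise ValueError("multiplicity exceeds the collapse cap")
        self.cap = cap
        self.total_mapped = int(total_mapped)


def collapse_duplicates(reads: ReadSet, cap: int) -> CollapsedReadSet:
    """Collapse identical reads and cap their multiplicity.

    Read identity is (chrom, start, end, strand) — length is implied by the
    coordinates, so per-position and per-region capping coincide. The output
    multiplicity of an identity class is min(summed multiplicity, cap).
    Idempotent and order-independent.
    """
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    df = reads.df
    if len(df) == 0:
        return CollapsedReadSet(df.copy(), cap, 0, assay=reads.assay)
    grouped = (
        df.groupby(["chrom", "start", "end", "strand", "unique"], as_index=False, sort=True)
        ["multiplicity"].sum()
    )
    grouped["multiplicity"] = np.minimum(grouped["multiplicity"], cap)
    grouped = grouped[["chrom", "start", "end", "strand", "unique", "multiplicity"]]
    total = int(grouped["multiplicity"].sum())
    return CollapsedReadSet(grouped.reset_index(drop=True), cap, total, assay=reads.assay)


def select_srna(reads: ReadSet, min_len: int = 18, max_len: int = 28,
                size_class: int | None = None) -> ReadSet:
    """Retain sRNA reads by length: ``min_len <= length <= max_len``, or the
    exact ``size_class`` when given. Uniqueness flags are preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lengths = reads.df["end"] - reads.df["start"]
    if size_class is not None:
        keep = lengths == size_class
    else:
        keep = (lengths >= min_len) & (lengths <= max_len)
    return ReadSet(reads.df[keep].reset_index(drop=True), assay=reads.assay)


# ---------------------------------------------------------------------------
# fast >=1 bp overlap counting
# ---------------------------------------------------------------------------

@dataclass
class _ChromReadIndex:
    """Sorted read starts/ends with cumulative multiplicities per chromosome.

    A read [rs, re) overlaps a window [s, e) iff rs < e and re > s; summing
    multiplicities of reads with rs < e and subtracting those with re <= s
    gives the overlap-weighted count in O(log n) per window.
    """

    starts: np.ndarray
    cum_by_start: np.ndarray
    ends: np.ndarray
    cum_by_end: np.ndarray

    def count(self, s: np.ndarray, e: np.ndarray) -> np.ndarray:
        lhs = self.cum_by_start[np.searchsorted(self.starts, e, side="left")]
        rhs = self.cum_by_end[np.searchsorted(self.ends, s, side="right")]
        return lhs - rhs


def build_read_index(reads: ReadSet, unique_only: bool = True) -> dict[str, _ChromReadIndex]:
    df = reads.df
    if unique_only:
        df = df[df["unique"]]
    index: dict[str, _ChromReadIndex] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mult = sub["multiplicity"].to_numpy(dtype=np.float64)
        so = np.argsort(starts, kind="stable")
        eo = np.argsort(ends, kind="stable")
        index[str(chrom)] = _ChromReadIndex(
            starts=starts[so], cum_by_start=np.r_[0.0, np.cumsum(mult[so])],
            ends=ends[eo], cum_by_end=np.r_[0.0, np.cumsum(mult[eo])],
        )
    return index


def count_overlapping(index: Mapping[str, _ChromReadIndex], chrom: str,
                      starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Summed multiplicity of indexed reads overlapping each window >= 1 bp."""
    if chrom not in index:
        return np.zeros(len(starts))
    return index[chrom].count(np.asarray(starts), np.asarray(ends))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def rpkm(reads: CollapsedReadSet, region: GenomicInterval,
         _index: Mapping[str, _ChromReadIndex] | None = None) -> float:
    """Reads per kb of region per million mapped reads.

    Numerator: summed multiplicity of *unique* reads overlapping the region
    by >= 1 bp. Denominator: region length (bp) times ``total_mapped``
    (unique + non-unique).
    """
    if reads.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPKM")
    index = _index if _index is not None else build_read_index(reads)
    n = count_overlapping(index, region.chrom,
                          np.array([region.start]), np.array([region.end]))[0]
    return float(n * 1e9 / (len(region) * reads.total_mapped))


def dmr_windows(dmrs: Sequence[DMR | GenomicInterval], flank: int = 500,
                chrom_sizes: Mapping[str, int] | None = None) -> list[GenomicInterval]:
    """Midpoint +/- ``flank`` windows for each DMR, clipped at chromosome bounds.

    The midpoint floors for odd-length regions.
    """
    out = []
    for d in dmrs:
        iv = d.interval if isinstance(d, DMR) else d
        mid = iv.midpoint
        start = max(0, mid - flank)
        end = mid + flank
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        out.append(GenomicInterval(iv.chrom, start, end))
    return out


def dmr_window_density(dmrs: Sequence[DMR | GenomicInterval], reads: CollapsedReadSet,
                       flank: int = 500,
                       chrom_sizes: Mapping[str, int] | None = None) -> np.ndarray:
    """Per-DMR RPKM over the midpoint +/- ``flank`` window.

    Clipped windows use their realized length in the denominator.
    """
    if reads.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPKM")
    windows = dmr_windows(dmrs, flank=flank, chrom_sizes=chrom_sizes)
    index = build_read_index(reads)
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        n = count_overlapping(index, w.chrom, np.array([w.start]), np.array([w.end]))[0]
        out[i] = n * 1e9 / (len(w) * reads.total_mapped)
    return out


@dataclass
class SignalProfile:
    """Mean normalized read density per bin over a set of regions.

    ``bin_label`` is the bin's coordinate: negative bp for the upstream
    flank, 0..1 fractional position for the scaled body, and positive bp
    beyond the region for the downstream flank.
    """

    df: pd.DataFrame  # columns: bin, kind, density
    n_regions: int


def metaplot(regions: Sequence[GenomicInterval], reads: CollapsedReadSet,
             n_body_bins: int = 20, flank: int = 1000,
             flank_bins: int = 10) -> SignalProfile:
    """Average RPKM profile over regions scaled to a common body length.

    Each region body is split into ``n_body_bins`` equal (possibly
    fractional-bp) bins; flanks are absolute-bp bins. Every region carries
    equal weight in the average, so duplicating the region set leaves the
    profile unchanged. Regions shorter than ``n_body_bins`` still contribute
    via fractional bin boundaries.
    """
    if len(regions) == 0:
        raise ValueError("metaplot requires at least one region")
    if reads.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for RPKM")
    index = build_read_index(reads)
    n_bins = n_body_bins + 2 * flank_bins
    flank_bin_width = flank / flank_bins
    acc = np.zeros(n_bins)
    for region in regions:
        bounds = np.concatenate([
            region.start - flank + np.arange(flank_bins) * flank_bin_width,
            region.start + np.arange(n_body_bins + 1) * (len(region) / n_body_bins),
            region.end + (1 + np.arange(flank_bins)) * flank_bin_width,
        ])
        starts, ends = bounds[:-1], bounds[1:]
        counts = count_overlapping(index, region.chrom, starts, ends)
        widths = ends - starts
        acc += counts * 1e9 / (widths * reads.total_mapped)
    densities = acc / len(regions)
    labels = np.concatenate([
        (np.arange(flank_bins) - flank_bins) * flank_bin_width + flank_bin_width / 2,
        (np.arange(n_body_bins) + 0.5) / n_body_bins,
        (np.arange(flank_bins)) * flank_bin_width + flank_bin_width / 2,
    ])
    kinds = ["upstream"] * flank_bins + ["body"] * n_body_bins + ["downstream"] * flank_bins
    return SignalProfile(
        pd.DataFrame({"bin": labels, "kind": kinds, "density": densities}),
        n_regions=len(regions),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   alternative: str = "two-sided",
                   exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U test with midrank tie handling.

    The p value is exact (full enumeration of arrangements) when
    ``len(x) + len(y) <= exact_max_n`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    Two-sided by default; the statistic reported is U of ``x``, so the
    direction of any shift is recoverable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_u requires nonempty samples")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if len(x) + len(y) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      len(x), len(y), method=method)


def mann_whitney_exact_enumeration(x: Sequence[float], y: Sequence[float],
                                   alternative: str = "two-sided") -> float:
    """Reference p value by full enumeration of group assignments.

    Enumerates all C(n+m, n) placements of the pooled values into the x
    group and counts arrangements with U as or more extreme than observed.
    Intended for small samples without ties (independent oracle for tests).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(ix: tuple[int, ...]) -> float:
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return float((xs[:, None] > ys[None, :]).sum()
                     + 0.5 * (xs[:, None] == ys[None, :]).sum())

    u_obs = u_of(tuple(range(n)))
    us = np.array([u_of(ix) for ix in combinations(range(len(pooled)), n)])
    mean_u = len(x) * len(y) / 2
    if alternative == "two-sided":
        p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    elif alternative == "greater":
        p = np.mean(us >= u_obs - 1e-12)
    else:
        p = np.mean(us <= u_obs + 1e-12)
    return float(p)


# ---------------------------------------------------------------------------
# weighted-change correlation
# ---------------------------------------------------------------------------

def weighted_change_correlation(
    dmrs: Sequence[DMR | GenomicInterval],
    chip_wt: CollapsedReadSet, chip_mut: CollapsedReadSet,
    meth_wt_tables: Sequence[MethylomeTable], meth_mut_table: MethylomeTable,
    flank: int = 500, chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation of per-DMR ChIP gain vs CHH methylation loss.

    For each DMR: delta RPKM = mutant - WT window density (midpoint +/-
    ``flank``), and delta methylation = pooled-WT weighted CHH methylation
    minus mutant weighted CHH methylation. Returns (rho, per-DMR table).
    """
    if len(dmrs) < 3:
        raise ValueError("weighted_change_correlation requires >= 3 DMRs")
    intervals = [d.interval if isinstance(d, DMR) else d for d in dmrs]
    d_rpkm = (dmr_window_density(intervals, chip_mut, flank, chrom_sizes)
              - dmr_window_density(intervals, chip_wt, flank, chrom_sizes))

    pooled = pd.concat([t.df for t in meth_wt_tables], ignore_index=True)
    pooled = pooled.groupby(["chrom", "pos", "strand", "context"], as_index=False)[["m", "t"]].sum()
    pooled_table = MethylomeTable("wt_pooled", pooled)
    d_meth = np.array([
        weighted_methylation(pooled_table, iv) - weighted_methylation(meth_mut_table, iv)
        for iv in intervals
    ])
    table = pd.DataFrame({
        "chrom": [iv.chrom for iv in intervals],
        "start": [iv.start for iv in intervals],
        "end": [iv.end for iv in intervals],
        "delta_rpkm": d_rpkm,
        "delta_chh": d_meth,
    })
    ok = np.isfinite(d_rpkm) & np.isfinite(d_meth)
    rho = float(sps.spearmanr(d_rpkm[ok], d_meth[ok]).statistic)
    return rho, table
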