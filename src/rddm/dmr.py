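"""CHH hypomethylation DMR calling: smoothing, site statistics, filter cascade.

One mutant methylome is compared against a group of wild-type replicate
methylomes. The stages are:

1. coverage filter — keep CHH sites with >= ``min_cov`` total reads in a
   strict majority of the WT libraries and in the mutant library;
2. smoothing — tricube-kernel weighted means of the raw per-site methylation
   proportions within +/- ``half_width`` bp, the window expanded
   symmetrically where fewer than ``min_sites`` retained sites fall inside;
3. signed site statistic t = (mu_WT - mu_mut) / max(sigma, sigma_floor),
   with sigma the across-replicate SD of the smoothed WT tracks and the
   floor the genome-wide median of those local SDs;
4. segmentation into maximal same-sign runs of |t| > ``t_cut`` with
   inter-site gaps <= ``max_gap``, then the filter cascade: >= ``min_sites``
   member CHH sites, |mean difference| >= ``min_meandiff`` on raw
   proportions, and |area| = |sum of t| >= ``min_area``.

Positive t / positive mean difference mark mutant hypomethylation; only
hypomethylated regions are emitted unless asked otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DMR, GenomicInterval, MethylomeTable

logger = logging.getLogger(__name__)


@dataclass
class DmrParams:
    """All thresholds of the caller with their standard defaults."""

    min_cov: int = 2
    half_width: int = 500
    min_smooth_sites: int = 10
    t_cut: float = 2.0
    max_gap: int = 300
    min_sites: int = 20
    min_meandiff: float = 0.1
    min_area: float = 100.0
    directions: tuple[str, ...] = ("hypo",)


@dataclass
class RetainedSites:
    """CHH sites passing the coverage filter, with aligned count matrices."""

    chrom: np.ndarray          # (n,) object
    pos: np.ndarray            # (n,) int64, sorted within chromosome
    wt_m: np.ndarray           # (n, k)
    wt_t: np.ndarray           # (n, k)
    mut_m: np.ndarray          # (n,)
    mut_t: np.ndarray          # (n,)

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class SmoothedTrack:
    """Smoothed WT/mutant methylation and local WT SD on retained CHH sites."""

    df: pd.DataFrame  # chrom, pos, mu_wt, mu_mut, sigma, raw_wt, raw_mut

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CandidateRegion:
    """A maximal same-sign run of sites with |t| above the cut."""

    chrom: str
    pos: np.ndarray
    t: np.ndarray
    raw_wt: np.ndarray
    raw_mut: np.ndarray

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, int(self.pos[0]), int(self.pos[-1]) + 1)

    @property
    def n_chh(self) -> int:
        return len(self.pos)

    @property
    def mean_diff(self) -> float:
        return float(np.mean(self.raw_wt) - np.mean(self.raw_mut))

    @property
    def area(self) -> float:
        return float(np.sum(self.t))


# ---------------------------------------------------------------------------
# stage 1: coverage filter
# ---------------------------------------------------------------------------

def coverage_filter(wt_tables: Sequence[MethylomeTable], mut_table: MethylomeTable,
                    min_cov: int = 2) -> RetainedSites:
    """Keep CHH sites covered >= ``min_cov`` x in a strict majority of WT
    libraries and in the mutant library.

    All tables must be on the same cytosine catalogue (same sites in the
    same order).
    """
    if len(wt_tables) == 0:
        raise ValueError("at least one wild-type library is required")
    mut = mut_table.subset_context("CHH")
    key = mut[["chrom", "pos", "strand"]].reset_index(drop=True)
    wt_ms, wt_ts = [], []
    for table in wt_tables:
        sub = table.subset_context("CHH").reset_index(drop=True)
        if len(sub) != len(key) or not (
            sub["pos"].to_numpy() == key["pos"].to_numpy()
        ).all() or not (sub["chrom"].to_numpy() == key["chrom"].to_numpy()).all():
            raise ValueError(
                f"library {table.library_id!r} is not on the same site catalogue "
                f"as {mut_table.library_id!r}"
            )
        wt_ms.append(sub["m"].to_numpy())
        wt_ts.append(sub["t"].to_numpy())
    wt_m = np.column_stack(wt_ms)
    wt_t = np.column_stack(wt_ts)
    mut_m = mut["m"].to_numpy()
    mut_t = mut["t"].to_numpy()

    n_wt = wt_t.shape[1]
    majority = (wt_t >= min_cov).sum(axis=1) * 2 > n_wt  # strictly more than half
    keep = majority & (mut_t >= min_cov)
    return RetainedSites(
        chrom=key["chrom"].to_numpy()[keep],
        pos=key["pos"].to_numpy()[keep],
        wt_m=wt_m[keep],
        wt_t=wt_t[keep],
        mut_m=mut_m[keep],
        mut_t=mut_t[keep],
    )


# ---------------------------------------------------------------------------
# stage 2: smoothing
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    return np.where(np.abs(u) <= 1.0, w, 0.0)


def _smooth_columns(pos: np.ndarray, values: np.ndarray, valid: np.ndarray,
                    half_width: float, min_sites: int) -> np.ndarray:
    """Tricube-weighted running mean of each column of ``values``.

    ``values`` is (n, C) with NaN where invalid; ``valid`` the matching mask.
    Sites with fewer than ``min_sites`` retained sites within the window get
    their window expanded symmetrically to the ``min_sites``-th nearest site.
    """
    n, n_cols = values.shape
    v = np.where(valid, values, 0.0)
    m = valid.astype(np.float64)
    num = v.copy()
    den = m.copy()
    h = float(half_width)
    # accumulate neighbor contributions offset by offset (vectorized over sites)
    for k in range(1, n):
        d = (pos[k:] - pos[:-k]).astype(np.float64)
        if d.min() > h:
            break
        w = _tricube(d / h)[:, None]
        num[:-k] += w * v[k:]
        den[:-k] += w * m[k:]
        num[k:] += w * v[:-k]
        den[k:] += w * m[:-k]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den

    # windows too sparse for min_sites: expand symmetrically (rare; per-site)
    lo = np.searchsorted(pos, pos - half_width, side="left")
    hi = np.searchsorted(pos, pos + half_width, side="right")
    sparse = np.nonzero(hi - lo < min_sites)[0]
    for i in sparse:
        d_all = np.abs(pos - pos[i]).astype(np.float64)
        r = np.partition(d_all, min_sites - 1)[min_sites - 1]
        h_eff = max(h, r) + 0.5
        w = _tricube(d_all / h_eff)[:, None]
        num_i = (w * v).sum(axis=0)
        den_i = (w * m).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = num_i / den_i
    return out


def smooth_track(sites: RetainedSites, half_width: int = 500,
                 min_sites: int = 10) -> SmoothedTrack:
    """Smooth WT group mean, mutant level and per-replicate WT tracks.

    The WT group input is the per-site mean of replicate proportions over
    replicates with nonzero coverage; sigma is the across-replicate sample
    SD of the per-replicate smoothed tracks. Chromosomes with fewer than
    ``min_sites`` retained sites are emitted unsmoothed with a warning.
    """
    if len(sites) == 0:
        return SmoothedTrack(pd.DataFrame(
            columns=["chrom", "pos", "mu_wt", "mu_mut", "sigma", "raw_wt", "raw_mut"]))

    n, k = sites.wt_m.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        rep_prop = np.where(sites.wt_t > 0, sites.wt_m / np.maximum(sites.wt_t, 1), np.nan)
        mut_prop = np.where(sites.mut_t > 0, sites.mut_m / np.maximum(sites.mut_t, 1), np.nan)
    raw_wt = np.nanmean(rep_prop, axis=1)

    # columns: raw WT group mean, mutant, then the k replicate tracks
    values = np.column_stack([raw_wt, mut_prop, rep_prop])
    valid = ~np.isnan(values)

    out_frames = []
    order = np.argsort(sites.chrom, kind="stable")  # within-chrom order preserved
    chrom_sorted = sites.chrom[order]
    boundaries = np.nonzero(np.r_[True, chrom_sorted[1:] != chrom_sorted[:-1]])[0]
    for b0, b1 in zip(boundaries, np.r_[boundaries[1:], len(order)]):
        idx = order[b0:b1]
        pos = sites.pos[idx]
        vals = values[idx]
        msk = valid[idx]
        if len(idx) < min_sites:
            logger.warning("chromosome %s has %d retained sites (< %d); emitted unsmoothed",
                           chrom_sorted[b0], len(idx), min_sites)
            smoothed = np.where(msk, vals, np.nan)
        else:
            smoothed = _smooth_columns(pos, vals, msk, half_width, min_sites)
        rep_smooth = smoothed[:, 2:]
        with np.errstate(invalid="ignore"):
            sigma = np.nanstd(rep_smooth, axis=1, ddof=1)
        out_frames.append(pd.DataFrame({
            "chrom": chrom_sorted[b0],
            "pos": pos,
            "mu_wt": smoothed[:, 0],
            "mu_mut": smoothed[:, 1],
            "sigma": sigma,
            "raw_wt": raw_wt[idx],
            "raw_mut": mut_prop[idx],
        }))
    df = pd.concat(out_frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SmoothedTrack(df)


# ---------------------------------------------------------------------------
# stage 3: site statistics
# ---------------------------------------------------------------------------

def sigma_floor(track: SmoothedTrack) -> float:
    """Genome-wide median of the local WT SDs (prevents division blow-ups)."""
    sig = track.df["sigma"].to_numpy()
    if len(sig) == 0 or not np.isfinite(sig).any():
        return 1e-8
    med = float(np.nanmedian(sig))
    return max(med, 1e-8)


def site_statistics(track: SmoothedTrack, floor: float | None = None) -> pd.DataFrame:
    """Signed site statistic t = (mu_WT - mu_mut) / max(sigma, floor).

    Positive t means the mutant is hypomethylated. Swapping the WT and
    mutant roles negates every t.
    """
    if floor is None:
        floor = sigma_floor(track)
    if floor <= 0:
        raise ValueError("sigma floor must be positive")
    df = track.df.copy()
    denom = np.maximum(df["sigma"].to_numpy(), floor)
    t = (df["mu_wt"].to_numpy() - df["mu_mut"].to_numpy()) / denom
    df["t"] = np.where(np.isfinite(t), t, 0.0)
    return df


# ---------------------------------------------------------------------------
# stage 4: segmentation and filters
# ---------------------------------------------------------------------------

def segment_candidates(stats: pd.DataFrame, t_cut: float = 2.0,
                       max_gap: int = 300) -> list[CandidateRegion]:
    """Maximal runs of consecutive retained sites with |t| > ``t_cut``,
    uniform sign, and inter-site gaps <= ``max_gap`` bp.

    A retained site failing the cut breaks a run; the candidate interval
    spans the first to last member site (end exclusive = last site + 1).
    """
    if len(stats) == 0:
        return []
    t = stats["t"].to_numpy()
    pos = stats["pos"].to_numpy()
    chrom = stats["chrom"].to_numpy()
    keep_idx = np.nonzero(np.abs(t) > t_cut)[0]
    if len(keep_idx) == 0:
        return []
    kept_pos = pos[keep_idx]
    kept_chrom = chrom[keep_idx]
    kept_sign = np.sign(t[keep_idx])
    # a new run starts when indices are non-consecutive, the chromosome
    # changes, the gap exceeds max_gap, or the sign flips
    brk = (
        (np.diff(keep_idx) != 1)
        | (kept_chrom[1:] != kept_chrom[:-1])
        | ((kept_pos[1:] - kept_pos[:-1]) > max_gap)
        | (kept_sign[1:] != kept_sign[:-1])
    )
    starts = np.r_[0, np.nonzero(brk)[0] + 1]
    ends = np.r_[starts[1:], len(keep_idx)]
    out = []
    raw_wt = stats["raw_wt"].to_numpy()
    raw_mut = stats["raw_mut"].to_numpy()
    for a, b in zip(starts, ends):
        members = keep_idx[a:b]
        out.append(CandidateRegion(
            chrom=str(chrom[members[0]]),
            pos=pos[members],
            t=t[members],
            raw_wt=raw_wt[members],
            raw_mut=raw_mut[members],
        ))
    return out


def filter_dmrs(candidates: Sequence[CandidateRegion], min_sites: int = 20,
                min_meandiff: float = 0.1, min_area: float = 100.0,
                directions: Sequence[str] = ("hypo",)) -> list[DMR]:
    """Apply the cascade: >= ``min_sites`` CHH sites, |mean difference| >=
    ``min_meandiff``, |area| >= ``min_area`` (ties at thresholds retained).

    Direction is hypo when the mean difference (WT - mutant) is positive.
    """
    out = []
    for cand in candidates:
        if cand.n_chh < min_sites:
            continue
        md = cand.mean_diff
        if abs(md) < min_meandiff:
            continue
        area = cand.area
        if abs(area) < min_area:
            continue
        direction = "hypo" if md > 0 else "hyper"
        if direction not in directions:
            continue
        out.append(DMR(cand.interval, cand.n_chh, md, area, direction))
    return out


# ---------------------------------------------------------------------------
# orchestrator + audit
# ---------------------------------------------------------------------------

def call_chh_dmrs(wt_tables: Sequence[MethylomeTable], mut_table: MethylomeTable,
                  params: DmrParams | None = None) -> list[DMR]:
    """Run the full caller: coverage filter, smoothing, t, segmentation, filters."""
    params = params or DmrParams()
    sites = coverage_filter(wt_tables, mut_table, min_cov=params.min_cov)
    track = smooth_track(sites, half_width=params.half_width,
                         min_sites=params.min_smooth_sites)
    stats = site_statistics(track)
    candidates = segment_candidates(stats, t_cut=params.t_cut, max_gap=params.max_gap)
    return filter_dmrs(candidates, min_sites=params.min_sites,
                       min_meandiff=params.min_meandiff, min_area=params.min_area,
                       directions=params.directions)


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """Tabulate DMRs (chrom, start, end, n_chh, mean_diff, area, direction)."""
    return pd.DataFrame(
        [(d.interval.chrom, d.interval.start, d.interval.end,
          d.n_chh, d.mean_diff, d.area, d.direction) for d in dmrs],
        columns=["chrom", "start", "end", "n_chh", "mean_diff", "area", "direction"],
    )


def audit_dmrs(dmrs: Sequence[DMR], wt_tables: Sequence[MethylomeTable],
               mut_table: MethylomeTable, params: DmrParams | None = None) -> pd.DataFrame:
    """Re-verify every filter clause of each DMR from the raw inputs.

    Recomputes the smoothed track and site statistics from scratch, then for
    each DMR recounts its member sites and re-evaluates n_chh, mean
    difference, area, the per-site |t| > t_cut requirement and sign
    uniformity. Returns one row per DMR with a boolean per clause and the
    failing clause names.
    """
    params = params or DmrParams()
    sites = coverage_filter(wt_tables, mut_table, min_cov=params.min_cov)
    track = smooth_track(sites, half_width=params.half_width,
                         min_sites=params.min_smooth_sites)
    stats = site_statistics(track)
    chrom = stats["chrom"].to_numpy()
    pos = stats["pos"].to_numpy()
    t = stats["t"].to_numpy()
    raw_wt = stats["raw_wt"].to_numpy()
    raw_mut = stats["raw_mut"].to_numpy()

    rows = []
    for d in dmrs:
        sel = (chrom == d.interval.chrom) & (pos >= d.interval.start) & (pos < d.interval.end)
        n_chh = int(sel.sum())
        if n_chh == 0:
            rows.append({"chrom": d.interval.chrom, "start": d.interval.start,
                         "end": d.interval.end, "n_chh": 0, "mean_diff": np.nan,
                         "area": np.nan, "pass_n_chh": False, "pass_meandiff": False,
                         "pass_area": False, "pass_t": False, "pass_sign": False,
                         "ok": False, "failed": "no_assayed_sites"})
            continue
        md = float(np.mean(raw_wt[sel]) - np.mean(raw_mut[sel]))
        area = float(np.sum(t[sel]))
        checks = {
            "pass_n_chh": n_chh >= params.min_sites,
            "pass_meandiff": abs(md) >= params.min_meandiff,
            "pass_area": abs(area) >= params.min_area,
            "pass_t": bool((np.abs(t[sel]) > params.t_cut).all()),
            "pass_sign": len(set(np.sign(t[sel]))) == 1,
        }
        failed = ",".join(k.removeprefix("pass_") for k, v in checks.items() if not v)
        rows.append({"chrom": d.interval.chrom, "start": d.interval.start,
                     "end": d.interval.end, "n_chh": n_chh, "mean_diff": md,
                     "area": area, **checks, "ok": all(checks.values()),
                     "failed": failed})
    return pd.DataFrame(rows)


def weighted_methylation(table: MethylomeTable, interval: GenomicInterval,
                         context: str = "CHH") -> float:
    """Coverage-weighted methylation over a region: sum(m) / sum(t).

    Returns NaN when the region has no covered sites of the context.
    """
    df = table.subset_context(context)
    sel = df[(df["chrom"] == interval.chrom) & (df["pos"] >= interval.start)
             & (df["pos"] < interval.end)]
    total = sel["t"].sum()
    if total == 0:
        return float("nan")
    return float(sel["m"].sum() / total)
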