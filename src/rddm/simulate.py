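"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline was built for: four
wild-type replicate methylomes plus mutant methylomes carrying implanted
CHH-context hypomethylated regions; genes with 5'-enriched H3K4 ChIP signal
and mutant-specific H3K4 gains at the implants; 24-nt-dominant small-RNA
clusters (lengths 18-28 nt, duplicated reads) sitting on the implants and
depleted in the mutant; and mRNA reads confined to gene bodies at per-gene
rates identical between genotypes.

Counts are simulated directly (no read-level bisulfite sequence simulation):
per-site coverage is Poisson, per-site methylation proportions are
beta-distributed around regional means (so counts are beta-binomial, giving
the overdispersion real methylomes show), and inside an implanted region the
mutant regional CHH mean is the wild-type mean minus the configured effect.

Everything is keyed off a single integer seed; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, MethylomeTable, ReadSet
from .io import catalogue_cytosines, write_bed_reads, write_fasta, write_gff_genes, write_methylome_tsv

# fixed sub-stream ids so every generator draws from its own reproducible stream
_STREAMS = {
    "genome": 1,
    "implants": 2,
    "meth_wt": 3,
    "meth_mut": 100,
    "annotation": 10,
    "gene_rates": 11,
    "chip_wt": 20,
    "chip_mut": 21,
    "srna_wt": 22,
    "srna_mut": 23,
    "mrna": 24,
}

ASSAYS = ("chip_wt", "chip_mut", "srna_wt", "srna_mut", "mrna")

# sRNA length law: 18..28 nt with a clear 24-nt mode
SRNA_LENGTHS = np.arange(18, 29)
_SRNA_WEIGHTS = np.array([2.0, 2.0, 3.0, 4.0, 8.0, 12.0, 50.0, 12.0, 6.0, 3.0, 2.0])
SRNA_LENGTH_PROBS = _SRNA_WEIGHTS / _SRNA_WEIGHTS.sum()


@dataclass(frozen=True)
class MutantSpec:
    """Effect sizes for one simulated mutant genotype.

    dmr_effect: drop in regional CHH methylation fraction inside implants.
    h3k4_gain: fold-increase in ChIP read rate inside implants.
    srna_depletion: fraction of implant-cluster sRNA reads lost.
    """

    label: str
    dmr_effect: float = 0.3
    h3k4_gain: float = 3.0
    srna_depletion: float = 0.9


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the reference-scenario defaults."""

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 2_000_000
    n_wt_replicates: int = 4
    mutant_specs: tuple[MutantSpec, ...] = (MutantSpec("mut"),)

    # implanted DMRs
    n_dmrs: int = 50
    dmr_width: int = 1000
    dmr_min_gap: int = 2000
    min_chh_per_dmr: int = 30
    dmr_wt_level: float = 0.4  # WT regional CHH mean inside implants

    # background methylation by context
    background_chh_level: float = 0.05
    background_cg_level: float = 0.25
    background_chg_level: float = 0.10
    beta_concentration: float = 20.0  # site-level heterogeneity around regional means

    coverage_mean: float = 8.0

    # annotation
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (1000, 3000)
    near_gene_fraction: float = 0.5
    near_gene_max_offset: int = 200

    # read sets
    chip_n_reads: int = 200_000
    chip_read_length: int = 50
    chip_gene_fraction: float = 0.5  # fraction of ChIP reads from the 5'-gene component
    chip_tss_window: int = 500
    srna_n_reads: int = 100_000
    srna_cluster_fraction: float = 0.8
    srna_nonunique_fraction: float = 0.2
    srna_multiplicity_p: float = 0.4  # geometric law, heavy right tail
    mrna_n_reads: int = 200_000
    mrna_read_length: int = 50

    def validate(self) -> None:
        for name in ("dmr_wt_level", "background_chh_level", "background_cg_level",
                     "background_chg_level", "near_gene_fraction",
                     "chip_gene_fraction", "srna_cluster_fraction",
                     "srna_nonunique_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for spec in self.mutant_specs:
            if not (0.0 <= spec.dmr_effect <= 1.0):
                raise ValueError(f"dmr_effect={spec.dmr_effect} outside [0, 1]")
            if not (0.0 <= spec.srna_depletion <= 1.0):
                raise ValueError(f"srna_depletion={spec.srna_depletion} outside [0, 1]")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")


def _rng(config: SimulationConfig, stream: str, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream] + offset])


@dataclass
class Implant:
    """One implanted hypomethylated region with its per-mutant effect."""

    interval: GenomicInterval
    effects: dict[str, float]  # mutant label -> methylation drop
    wt_level: float


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator implanted."""

    implants: list[Implant]
    genes: list[GeneModel] = field(default_factory=list)
    assay_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def implant_intervals(self) -> list[GenomicInterval]:
        return [imp.interval for imp in self.implants]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "implants": [
                {
                    "chrom": imp.interval.chrom,
                    "start": imp.interval.start,
                    "end": imp.interval.end,
                    "effects": imp.effects,
                    "wt_level": imp.wt_level,
                }
                for imp in self.implants
            ],
            "genes": [
                {
                    "chrom": g.interval.chrom,
                    "start": g.interval.start,
                    "end": g.interval.end,
                    "strand": g.interval.strand,
                    "gene_id": g.gene_id,
                }
                for g in self.genes
            ],
            "assay_effects": self.assay_effects,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        implants = [
            Implant(GenomicInterval(d["chrom"], d["start"], d["end"]),
                    {k: float(v) for k, v in d["effects"].items()},
                    float(d["wt_level"]))
            for d in payload["implants"]
        ]
        genes = [
            GeneModel(GenomicInterval(d["chrom"], d["start"], d["end"], d["strand"]), d["gene_id"])
            for d in payload["genes"]
        ]
        return cls(implants, genes, payload.get("assay_effects", {}))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Uniform-random genome: ``n_chrom`` chromosomes of ``chrom_length`` bp."""
    config.validate()
    if config.chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1 kb")
    rng = _rng(config, "genome")
    genome = {}
    for i in range(config.n_chrom):
        codes = rng.integers(0, 4, size=config.chrom_length)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
        genome[f"chr{i + 1}"] = seq.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# implant placement and methylomes
# ---------------------------------------------------------------------------

def place_implants(catalogue: pd.DataFrame, config: SimulationConfig) -> list[GenomicInterval]:
    """Place non-overlapping implant intervals with enough CHH sites each.

    Intervals are ``dmr_width`` bp, pairwise separated by >= ``dmr_min_gap``
    and required to contain >= ``min_chh_per_dmr`` CHH sites; placement is
    rejection sampling, erroring with the shortfall when the genome cannot
    host the request.
    """
    rng = _rng(config, "implants")
    chroms = sorted(catalogue["chrom"].unique())
    chh = catalogue[catalogue["context"] == "CHH"]
    placed: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    max_attempts = config.n_dmrs * 200
    attempts = 0
    chh_pos = {c: chh.loc[chh["chrom"] == c, "pos"].to_numpy() for c in chroms}
    # keep implants clear of chromosome ends so a companion gene always fits
    margin = config.gene_length_range[1] + config.near_gene_max_offset
    margin = min(margin, max(0, (config.chrom_length - config.dmr_width) // 4))
    while len(placed) < config.n_dmrs and attempts < max_attempts:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(margin, config.chrom_length - config.dmr_width - margin))
        end = start + config.dmr_width
        lo, hi = start - config.dmr_min_gap, end + config.dmr_min_gap
        if any(s < hi and e > lo for s, e in occupied[chrom]):
            continue
        pos = chh_pos[chrom]
        n_sites = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        if n_sites < config.min_chh_per_dmr:
            continue
        occupied[chrom].append((start, end))
        placed.append(GenomicInterval(chrom, start, end))
    if len(placed) < config.n_dmrs:
        raise ValueError(
            f"could not place {config.n_dmrs} non-overlapping implants; "
            f"short by {config.n_dmrs - len(placed)}"
        )
    placed.sort(key=lambda iv: (iv.chrom, iv.start))
    return placed


def _regional_means(catalogue: pd.DataFrame, config: SimulationConfig,
                    implants: Sequence[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    """Per-site WT regional mean and a boolean mask of implant membership."""
    ctx = catalogue["context"].to_numpy()
    mean = np.where(ctx == "CG", config.background_cg_level,
                    np.where(ctx == "CHG", config.background_chg_level,
                             config.background_chh_level))
    in_implant = np.zeros(len(catalogue), dtype=bool)
    chrom_arr = catalogue["chrom"].to_numpy()
    pos = catalogue["pos"].to_numpy()
    for iv in implants:
        sel = (chrom_arr == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        in_implant |= sel
        mean[sel & (ctx == "CHH")] = config.dmr_wt_level
    return mean, in_implant


def _beta_around(rng: np.random.Generator, mean: np.ndarray, nu: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * nu, (1 - mean) * nu)


def simulate_methylomes(
    genome: dict[str, str], config: SimulationConfig,
    catalogue: pd.DataFrame | None = None,
) -> tuple[list[MethylomeTable], dict[str, MethylomeTable], SyntheticTruth]:
    """WT replicate and mutant methylomes plus the truth record.

    Per-site coverage is Poisson(``coverage_mean``) per library; methylated
    counts are Binomial(coverage, p) with p drawn once per site from a Beta
    around the regional mean. WT replicates (and the mutant outside implants)
    share the site-level p, so genotypes differ only inside implants, where
    the mutant's p is drawn around ``wt mean - dmr_effect``.
    """
    config.validate()
    if catalogue is None:
        catalogue = catalogue_cytosines(genome)
    implant_ivs = place_implants(catalogue, config)
    mean_wt, in_implant = _regional_means(catalogue, config, implant_ivs)
    is_chh = (catalogue["context"] == "CHH").to_numpy()
    nu = config.beta_concentration

    rng_wt = _rng(config, "meth_wt")
    p_wt = _beta_around(rng_wt, mean_wt, nu)

    n = len(catalogue)
    base = catalogue[["chrom", "pos", "strand", "context"]]

    def _table(label: str, p: np.ndarray, rng: np.random.Generator) -> MethylomeTable:
        cov = rng.poisson(config.coverage_mean, size=n)
        m = rng.binomial(cov, p)
        df = base.copy()
        df["m"] = m
        df["t"] = cov
        # catalogue is already sorted and unique; skip revalidation for speed
        return MethylomeTable(label, df, validate=False)

    wt_tables = [_table(f"wt_{i + 1}", p_wt, _rng(config, "meth_wt", offset=i + 1))
                 for i in range(config.n_wt_replicates)]

    mut_tables: dict[str, MethylomeTable] = {}
    affected = in_implant & is_chh
    for j, spec in enumerate(config.mutant_specs):
        rng_mut = _rng(config, "meth_mut", offset=j)
        p_mut = p_wt.copy()
        mut_mean = np.clip(mean_wt[affected] - spec.dmr_effect, 1e-3, 1.0)
        p_mut[affected] = _beta_around(rng_mut, mut_mean, nu)
        mut_tables[spec.label] = _table(spec.label, p_mut, _rng(config, "meth_mut", offset=50 + j))

    implants = [
        Implant(iv, {spec.label: spec.dmr_effect for spec in config.mutant_specs},
                config.dmr_wt_level)
        for iv in implant_ivs
    ]
    truth = SyntheticTruth(
        implants=implants,
        assay_effects={
            spec.label: {"dmr_effect": spec.dmr_effect, "h3k4_gain": spec.h3k4_gain,
                         "srna_depletion": spec.srna_depletion}
            for spec in config.mutant_specs
        },
    )
    return wt_tables, mut_tables, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(genome: dict[str, str], config: SimulationConfig,
                        truth: SyntheticTruth) -> list[GeneModel]:
    """Non-overlapping gene models; a fraction of implants get a nearby gene.

    For a "near" implant the companion gene is oriented so that the implant
    lies 5' of the TSS within ``near_gene_max_offset`` bp of the gene edge
    (i.e. in what the expression stage will treat as promoter space). The
    remaining genes are placed uniformly, avoiding genes and implants.
    """
    config.validate()
    if config.n_genes < 1:
        raise ValueError("at least one gene must be requested")
    rng = _rng(config, "annotation")
    chrom_len = {c: len(s) for c, s in genome.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for iv in truth.implant_intervals:
        occupied[iv.chrom].append((iv.start, iv.end))

    def _free(chrom: str, start: int, end: int) -> bool:
        return 0 <= start and end <= chrom_len[chrom] and not any(
            s < end and e > start for s, e in occupied[chrom]
        )

    genes: list[GeneModel] = []

    def _add(chrom: str, start: int, end: int, strand: str) -> None:
        occupied[chrom].append((start, end))
        genes.append(GeneModel(GenomicInterval(chrom, start, end, strand),
                               f"gene_{len(genes) + 1:05d}"))

    lo_len, hi_len = config.gene_length_range
    n_near = int(round(config.near_gene_fraction * len(truth.implants)))
    n_near = min(n_near, config.n_genes)
    for imp in truth.implants[:n_near]:
        placed = False
        for _ in range(50):
            glen = int(rng.integers(lo_len, hi_len + 1))
            offset = int(rng.integers(0, config.near_gene_max_offset + 1))
            if rng.random() < 0.5:  # gene downstream of implant, + strand
                start = imp.interval.end + offset
                cand = (imp.interval.chrom, start, start + glen, "+")
            else:  # gene upstream, - strand (TSS at gene end, facing implant)
                end = imp.interval.start - offset
                cand = (imp.interval.chrom, end - glen, end, "-")
            if cand[1] >= 0 and _free(*cand[:3]):
                _add(*cand)
                placed = True
                break
        if not placed:
            raise ValueError("could not place a near-gene companion; lower gene density")

    attempts = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > config.n_genes * 500:
            raise ValueError("gene density too high to place genes without overlap")
        chrom = sorted(genome)[int(rng.integers(len(genome)))]
        glen = int(rng.integers(lo_len, hi_len + 1))
        if chrom_len[chrom] <= glen:
            continue
        start = int(rng.integers(0, chrom_len[chrom] - glen))
        if _free(chrom, start, start + glen):
            _add(chrom, start, start + glen, "+" if rng.random() < 0.5 else "-")

    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    truth.genes = genes
    return genes


# ---------------------------------------------------------------------------
# read sets
# ---------------------------------------------------------------------------

def _implant_arrays(truth: SyntheticTruth) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in truth.implant_intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def _in_implant(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                implants: dict[str, np.ndarray]) -> np.ndarray:
    """>=1 bp overlap of read intervals with any implant."""
    hit = np.zeros(len(starts), dtype=bool)
    for chrom, arr in implants.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        s, e = starts[sel], ends[sel]
        # implant index whose start is <= read end-1
        idx = np.searchsorted(arr[:, 0], e - 1, side="right") - 1
        ok = idx >= 0
        idx = np.clip(idx, 0, len(arr) - 1)
        ov = ok & (arr[idx, 1] > s)  # implant end > read start
        out = np.zeros(sel.sum(), dtype=bool)
        out[:] = ov
        hit[sel] = out
    return hit


def _reads_frame(chrom: np.ndarray, start: np.ndarray, length: np.ndarray,
                 strand: np.ndarray, unique: np.ndarray, mult: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": chrom, "start": start, "end": start + length,
        "strand": strand, "unique": unique, "multiplicity": mult,
    })


def simulate_reads(genome: dict[str, str], truth: SyntheticTruth, assay: str,
                   config: SimulationConfig, mutant: str | None = None,
                   replicate: int = 0) -> ReadSet:
    """Simulate one assay's aligned-read set.

    ``mutant`` selects the effect sizes for the ``*_mut`` assays (defaults to
    the first configured mutant). ``replicate`` shifts the sampling stream so
    repeat libraries of the same assay differ only by sampling noise (the
    mRNA per-gene rates stay genotype-independent regardless).
    """
    config.validate()
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    spec = None
    if assay.endswith("_mut"):
        label = mutant or config.mutant_specs[0].label
        matches = [s for s in config.mutant_specs if s.label == label]
        if not matches:
            raise ValueError(f"unknown mutant label {label!r}")
        spec = matches[0]
    rng = _rng(config, assay, offset=30 * replicate)
    chroms_sorted = sorted(genome)
    chrom_len = np.array([len(genome[c]) for c in chroms_sorted])
    genome_len = int(chrom_len.sum())
    implants = _implant_arrays(truth)

    def _uniform_positions(n: int, read_len: int, avoid_implants: bool = False
                           ) -> tuple[np.ndarray, np.ndarray]:
        """n uniform read starts over the genome (optionally rejecting implants)."""
        chrom_idx = rng.choice(len(chroms_sorted), size=n,
                               p=chrom_len / genome_len)
        starts = (rng.random(n) * (chrom_len[chrom_idx] - read_len)).astype(np.int64)
        chroms = np.array(chroms_sorted, dtype=object)[chrom_idx]
        if avoid_implants:
            for _ in range(100):
                bad = _in_implant(chroms, starts, starts + read_len, implants)
                n_bad = int(bad.sum())
                if n_bad == 0:
                    break
                chrom_idx_b = rng.choice(len(chroms_sorted), size=n_bad,
                                         p=chrom_len / genome_len)
                starts[bad] = (rng.random(n_bad)
                               * (chrom_len[chrom_idx_b] - read_len)).astype(np.int64)
                chroms[bad] = np.array(chroms_sorted, dtype=object)[chrom_idx_b]
        return chroms, starts

    if assay.startswith("chip"):
        n = config.chip_n_reads
        rl = config.chip_read_length
        n_gene = int(round(config.chip_gene_fraction * n))
        # 5'-gene component: read starts uniform in [TSS, TSS + window) along
        # the gene's direction
        genes = truth.genes
        if not genes:
            raise ValueError("annotation must be simulated before ChIP reads")
        gidx = rng.integers(0, len(genes), size=n_gene)
        offs = rng.integers(0, config.chip_tss_window, size=n_gene)
        g_chrom = np.empty(n_gene, dtype=object)
        g_start = np.empty(n_gene, dtype=np.int64)
        for k, (gi, off) in enumerate(zip(gidx, offs)):
            g = genes[gi]
            if g.interval.strand == "+":
                s = g.tss + off
            else:
                s = g.tss - off - rl + 1
            g_chrom[k] = g.interval.chrom
            g_start[k] = max(0, min(s, len(genome[g.interval.chrom]) - rl))
        b_chrom, b_start = _uniform_positions(n - n_gene, rl)
        chrom = np.concatenate([g_chrom, b_chrom])
        start = np.concatenate([g_start, b_start])
        if assay == "chip_mut" and spec is not None and spec.h3k4_gain > 1:
            # extra reads inside implants raise local density gain-fold above
            # the background component's rate
            bg_per_bp = (n - n_gene) / genome_len
            extra_chrom, extra_start = [], []
            for iv in truth.implant_intervals:
                lam = bg_per_bp * len(iv) * (spec.h3k4_gain - 1)
                k = rng.poisson(lam)
                if k:
                    extra_start.append(rng.integers(iv.start, max(iv.start + 1, iv.end - rl), size=k))
                    extra_chrom.append(np.full(k, iv.chrom, dtype=object))
            if extra_chrom:
                chrom = np.concatenate([chrom, *extra_chrom])
                start = np.concatenate([start, *extra_start])
        n_total = len(chrom)
        strand = np.where(rng.random(n_total) < 0.5, "+", "-")
        df = _reads_frame(chrom, start, np.full(n_total, rl), strand,
                          np.ones(n_total, dtype=bool), np.ones(n_total, dtype=np.int64))
        return ReadSet(df, assay=assay)

    if assay.startswith("srna"):
        n = config.srna_n_reads
        lengths = rng.choice(SRNA_LENGTHS, size=n, p=SRNA_LENGTH_PROBS)
        n_cluster = int(round(config.srna_cluster_fraction * n))
        if assay == "srna_mut" and spec is not None:
            keep = rng.random(n_cluster) >= spec.srna_depletion
            n_cluster = int(keep.sum())
        ivs = truth.implant_intervals
        c_chrom = np.empty(n_cluster, dtype=object)
        c_start = np.empty(n_cluster, dtype=np.int64)
        if n_cluster:
            pick = rng.integers(0, len(ivs), size=n_cluster)
            for k, pi in enumerate(pick):
                iv = ivs[pi]
                c_chrom[k] = iv.chrom
                c_start[k] = rng.integers(iv.start, iv.end - 28)
        n_bg = n - int(round(config.srna_cluster_fraction * n))
        b_chrom, b_start = _uniform_positions(n_bg, 28, avoid_implants=True)
        chrom = np.concatenate([c_chrom, b_chrom])
        start = np.concatenate([c_start, b_start])
        lengths = np.concatenate([lengths[:n_cluster], lengths[n - n_bg:]])
        n_total = len(chrom)
        strand = np.where(rng.random(n_total) < 0.5, "+", "-")
        unique = rng.random(n_total) >= config.srna_nonunique_fraction
        mult = rng.geometric(config.srna_multiplicity_p, size=n_total)
        df = _reads_frame(chrom, start, lengths, strand, unique, mult)
        return ReadSet(df, assay=assay)

    # mRNA: reads confined to gene bodies; per-gene rates drawn once from a
    # genotype-independent stream so WT and mutant share expression levels
    genes = truth.genes
    if not genes:
        raise ValueError("annotation must be simulated before mRNA reads")
    rate_rng = _rng(config, "gene_rates")
    weights = rate_rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    weights /= weights.sum()
    rl = config.mrna_read_length
    gidx = rng.choice(len(genes), size=config.mrna_n_reads, p=weights)
    chrom = np.empty(config.mrna_n_reads, dtype=object)
    start = np.empty(config.mrna_n_reads, dtype=np.int64)
    g_start = np.array([g.interval.start for g in genes])
    g_end = np.array([g.interval.end for g in genes])
    g_chrom = np.array([g.interval.chrom for g in genes], dtype=object)
    span = np.maximum(1, g_end[gidx] - g_start[gidx] - rl)
    start = g_start[gidx] + (rng.random(config.mrna_n_reads) * span).astype(np.int64)
    chrom = g_chrom[gidx]
    strand = np.where(rng.random(config.mrna_n_reads) < 0.5, "+", "-")
    df = _reads_frame(chrom, start, np.full(config.mrna_n_reads, rl), strand,
                      np.ones(config.mrna_n_reads, dtype=bool),
                      np.ones(config.mrna_n_reads, dtype=np.int64))
    return ReadSet(df, assay="mrna")


# ---------------------------------------------------------------------------
# one-call scenario + file emission
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """In-memory bundle of one full simulated study."""

    config: SimulationConfig
    genome: dict[str, str]
    catalogue: pd.DataFrame
    wt_tables: list[MethylomeTable]
    mut_tables: dict[str, MethylomeTable]
    truth: SyntheticTruth
    genes: list[GeneModel]


def simulate_scenario(config: SimulationConfig, with_annotation: bool = True) -> Scenario:
    """Genome, methylomes, truth and (optionally) annotation in one call."""
    genome = simulate_genome(config)
    catalogue = catalogue_cytosines(genome)
    wt_tables, mut_tables, truth = simulate_methylomes(genome, config, catalogue)
    genes = simulate_annotation(genome, config, truth) if with_annotation else []
    return Scenario(config, genome, catalogue, wt_tables, mut_tables, truth, genes)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path,
                    assays: Sequence[str] = ASSAYS) -> dict[str, object]:
    """Emit FASTA, methylation TSVs, GFF3, BED read sets and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = simulate_scenario(config)
    paths: dict[str, object] = {}
    write_fasta(scen.genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    paths["wt_methylomes"] = []
    for table in scen.wt_tables:
        p = outdir / f"{table.library_id}.meth.tsv"
        write_methylome_tsv(table, p)
        paths["wt_methylomes"].append(str(p))
    paths["mut_methylomes"] = {}
    for label, table in scen.mut_tables.items():
        p = outdir / f"{label}.meth.tsv"
        write_methylome_tsv(table, p)
        paths["mut_methylomes"][label] = str(p)
    write_gff_genes(scen.genes, outdir / "genes.gff3")
    paths["genes"] = str(outdir / "genes.gff3")
    paths["reads"] = {}
    for assay in assays:
        reads = simulate_reads(scen.genome, scen.truth, assay, config)
        p = outdir / f"{assay}.bed"
        write_bed_reads(reads, p)
        paths["reads"][assay] = str(p)
    scen.truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    return paths
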