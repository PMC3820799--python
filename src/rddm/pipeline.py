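"""End-to-end orchestration: simulate -> call DMRs -> compare -> quantify ->
expression, with a manifest that makes a run reproducible.

The single YAML/dict config carries a simulation block plus per-stage
override blocks; every caller threshold is a named config key with its
standard default. Re-running with the same config and seed reproduces the
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .core import DMR, GenomicInterval, intervals_overlap
from .dmr import DmrParams, audit_dmrs, call_chh_dmrs, dmrs_to_frame
from .expression import expression_table, genes_with_dmr_promoters
from .io import write_bed, write_fasta, write_gff_genes, write_methylome_tsv
from .regions import distance_to_nearest_gene, venn_counts, welch_t_test
from .signal import (collapse_duplicates, dmr_window_density, mann_whitney_u,
                     select_srna)
from .simulate import MutantSpec, Scenario, SimulationConfig, simulate_reads, simulate_scenario

logger = logging.getLogger(__name__)


def recovery_metrics(called: Sequence[DMR | GenomicInterval],
                     truth: Sequence[GenomicInterval]) -> dict[str, float]:
    """Sensitivity and false-discovery proportion against implanted truth.

    A truth region is recovered if any called DMR overlaps it by >= 1 bp; a
    called DMR is a false discovery if it overlaps no truth region.
    """
    called_ivs = [d.interval if isinstance(d, DMR) else d for d in called]
    n_truth = len(truth)
    recovered = sum(
        1 for tv in truth if any(intervals_overlap(tv, cv) for cv in called_ivs)
    )
    false = sum(
        1 for cv in called_ivs if not any(intervals_overlap(cv, tv) for tv in truth)
    )
    return {
        "n_truth": n_truth,
        "n_called": len(called_ivs),
        "n_recovered": recovered,
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
        "fdp": false / len(called_ivs) if called_ivs else 0.0,
    }


def _build_sim_config(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    block = dict(block)
    mutants = block.pop("mutants", None)
    if not mutants:
        raise ValueError("config must declare at least one mutant library")
    specs = tuple(MutantSpec(**m) for m in mutants)
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    if "gene_length_range" in block:
        block["gene_length_range"] = tuple(block["gene_length_range"])
    return SimulationConfig(seed=seed, mutant_specs=specs, **block)


def load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping")
    return dict(config)


def validate_config(config: Mapping[str, Any]) -> tuple[SimulationConfig, DmrParams, dict, dict]:
    """Parse and validate all stage blocks before any compute."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    sim = _build_sim_config(cfg.get("simulation", {}), seed)
    sim.validate()
    dmr_block = dict(cfg.get("dmr", {}))
    directions = tuple(dmr_block.pop("directions", ("hypo",)))
    params = DmrParams(directions=directions, **dmr_block)
    quant = {"window_flank": 500, "srna_cap": 100, "chip_cap": 1,
             "srna_len": [18, 28], "srna_class": 24, "min_overlap_bp": 1}
    quant.update(cfg.get("quantify", {}))
    expr = {"promoter_upstream": 1000, "pseudocount": 1.0}
    expr.update(cfg.get("expression", {}))
    return sim, params, quant, expr


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_pipeline(config: Mapping[str, Any] | str | Path,
                      outdir: str | Path) -> tuple[dict, dict]:
    """Execute all stages; return (manifest, report) and write both to disk.

    Any stage failure raises with the stage name; validation failures occur
    before any compute.
    """
    cfg = load_config(config)
    sim_config, dmr_params, quant, expr = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": sim_config.seed,
        "thresholds": {
            **dataclasses.asdict(dmr_params),
            **{k: v for k, v in quant.items()},
            **{f"expression_{k}": v for k, v in expr.items()},
        },
        "paths": {},
        "stages": [],
    }
    report: dict[str, Any] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                entry = {"stage": name, "seconds": round(time.time() - self_inner.t0, 2),
                         "ok": exc is None}
                if exc is not None:
                    entry["error"] = str(exc)
                    manifest["stages"].append(entry)
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"].append(entry)
        return _Ctx()

    with _stage("simulate"):
        scen = simulate_scenario(sim_config)
        chrom_sizes = {c: len(s) for c, s in scen.genome.items()}
        write_fasta(scen.genome, outdir / "genome.fa")
        write_gff_genes(scen.genes, outdir / "genes.gff3")
        scen.truth.to_json(outdir / "truth.json")
        for table in scen.wt_tables:
            write_methylome_tsv(table, outdir / f"{table.library_id}.meth.tsv")
        for label, table in scen.mut_tables.items():
            write_methylome_tsv(table, outdir / f"{label}.meth.tsv")
        manifest["paths"]["genome"] = str(outdir / "genome.fa")
        manifest["paths"]["truth"] = str(outdir / "truth.json")

    dmr_sets: dict[str, list[DMR]] = {}
    with _stage("call_dmrs"):
        for label, table in scen.mut_tables.items():
            dmrs = call_chh_dmrs(scen.wt_tables, table, dmr_params)
            dmr_sets[label] = dmrs
            frame = dmrs_to_frame(dmrs)
            frame.to_csv(outdir / f"dmrs_{label}.tsv", sep="\t", index=False)
            write_bed([d.interval for d in dmrs], outdir / f"dmrs_{label}.bed",
                      names=[d.direction for d in dmrs],
                      scores=[round(d.area, 1) for d in dmrs])
            manifest["paths"][f"dmrs_{label}"] = str(outdir / f"dmrs_{label}.bed")
            metrics = recovery_metrics(dmrs, scen.truth.implant_intervals)
            audit = audit_dmrs(dmrs, scen.wt_tables, table, dmr_params)
            report.setdefault("dmr", {})[label] = {
                **metrics,
                "audit_pass_fraction": float(audit["ok"].mean()) if len(audit) else 1.0,
            }

    with _stage("compare_dmrs"):
        distances = {}
        for label, dmrs in dmr_sets.items():
            d = distance_to_nearest_gene([x.interval for x in dmrs], scen.genes)
            distances[label] = d[~np.isnan(d)]
        truth_dist = distance_to_nearest_gene(scen.truth.implant_intervals, scen.genes)
        report["distance"] = {
            label: {"mean_bp": float(np.mean(d)) if len(d) else float("nan"),
                    "n": int(len(d))}
            for label, d in distances.items()
        }
        report["distance"]["implants"] = {
            "mean_bp": float(np.nanmean(truth_dist)), "n": int(len(truth_dist))}
        if len(dmr_sets) >= 2:
            sets = {label: [d.interval for d in dmrs] for label, dmrs in
                    list(dmr_sets.items())[:3]}
            venn = venn_counts(sets)
            report["venn"] = {
                label: {"|".join(k): v for k, v in counter.items()}
                for label, counter in venn.per_set.items()
            }

    with _stage("quantify"):
        first_label = next(iter(scen.mut_tables))
        truth_ivs = scen.truth.implant_intervals
        chip_wt = collapse_duplicates(
            simulate_reads(scen.genome, scen.truth, "chip_wt", sim_config),
            cap=quant["chip_cap"])
        chip_mut = collapse_duplicates(
            simulate_reads(scen.genome, scen.truth, "chip_mut", sim_config, mutant=first_label),
            cap=quant["chip_cap"])
        wt_dens = dmr_window_density(truth_ivs, chip_wt, quant["window_flank"], chrom_sizes)
        mut_dens = dmr_window_density(truth_ivs, chip_mut, quant["window_flank"], chrom_sizes)
        chip_test = mann_whitney_u(mut_dens, wt_dens)
        report["h3k4"] = {
            "wt_median_rpkm": float(np.median(wt_dens)),
            "mut_median_rpkm": float(np.median(mut_dens)),
            "mw_p": chip_test.p_value, "n": len(truth_ivs),
        }
        lo, hi = quant["srna_len"]
        srna_wt = collapse_duplicates(
            select_srna(simulate_reads(scen.genome, scen.truth, "srna_wt", sim_config),
                        lo, hi, size_class=quant["srna_class"]),
            cap=quant["srna_cap"])
        srna_mut = collapse_duplicates(
            select_srna(simulate_reads(scen.genome, scen.truth, "srna_mut", sim_config,
                                       mutant=first_label),
                        lo, hi, size_class=quant["srna_class"]),
            cap=quant["srna_cap"])
        s_wt = dmr_window_density(truth_ivs, srna_wt, quant["window_flank"], chrom_sizes)
        s_mut = dmr_window_density(truth_ivs, srna_mut, quant["window_flank"], chrom_sizes)
        srna_test = mann_whitney_u(s_mut, s_wt)
        report["srna24"] = {
            "wt_median_rpkm": float(np.median(s_wt)),
            "mut_median_rpkm": float(np.median(s_mut)),
            "mw_p": srna_test.p_value, "n": len(truth_ivs),
        }

    with _stage("expression"):
        mrna_wt = collapse_duplicates(
            simulate_reads(scen.genome, scen.truth, "mrna", sim_config), cap=quant["chip_cap"])
        # second library from the same genotype-independent gene rates
        mrna_mut = collapse_duplicates(
            simulate_reads(scen.genome, scen.truth, "mrna", sim_config, replicate=1),
            cap=quant["chip_cap"])
        prom_genes = genes_with_dmr_promoters(
            scen.genes, scen.truth.implant_intervals,
            upstream=expr["promoter_upstream"], chrom_sizes=chrom_sizes)
        if prom_genes:
            table = expression_table(prom_genes, mrna_wt, mrna_mut,
                                     pseudocount=expr["pseudocount"])
            table.to_csv(outdir / "expression_promoter_genes.tsv", sep="\t", index=False)
            report["expression"] = {
                "n_promoter_genes": len(prom_genes),
                "median_log2_ratio": float(table["log2_ratio"].median()),
            }
        else:
            report["expression"] = {"n_promoter_genes": 0}

    manifest_path = outdir / "manifest.json"
    report_path = outdir / "report.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    report_path.write_text(json.dumps(report, indent=1, default=str))
    manifest["paths"]["report"] = str(report_path)
    return manifest, report
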