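#!/usr/bin/env python
"""Transcription at implanted regions and at their promoter-overlapping genes.

With per-gene mRNA rates identical between genotypes (the generator's null),
computes the per-gene log2 expression ratio for genes whose kilobase
promoters overlap an implanted region, and the mRNA metaplot over the
implants for both genotypes.
"""

import json
from pathlib import Path

import numpy as np

from rddm.expression import (dmr_transcription_profile, expression_table,
                             genes_with_dmr_promoters)
from rddm.io import catalogue_cytosines
from rddm.signal import collapse_duplicates
from rddm.simulate import (Implant, SimulationConfig, SyntheticTruth,
                           place_implants, simulate_annotation, simulate_genome,
                           simulate_reads)

RESULTS = Path(__file__).resolve().parent.parent / "results" / "05_expression"
SEED = 1


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED, n_dmrs=200, dmr_width=500, dmr_min_gap=2000,
                              n_genes=200, gene_length_range=(800, 1500),
                              near_gene_fraction=1.0, near_gene_max_offset=200)
    genome = simulate_genome(config)
    catalogue = catalogue_cytosines(genome)
    implants = place_implants(catalogue, config)
    truth = SyntheticTruth([Implant(iv, {"mut": 0.3}, 0.4) for iv in implants])
    genes = simulate_annotation(genome, config, truth)

    mrna_wt = collapse_duplicates(simulate_reads(genome, truth, "mrna", config), cap=1)
    mrna_mut = collapse_duplicates(
        simulate_reads(genome, truth, "mrna", config, replicate=1), cap=1)

    prom = genes_with_dmr_promoters(genes, truth.implant_intervals)
    table = expression_table(prom, mrna_wt, mrna_mut)
    table.to_csv(RESULTS / "promoter_gene_expression.tsv", sep="\t", index=False)

    profiles = dmr_transcription_profile(truth.implant_intervals,
                                         {"wt": mrna_wt, "mut": mrna_mut})
    for label, profile in profiles.items():
        profile.df.to_csv(RESULTS / f"mrna_metaplot_{label}.tsv", sep="\t", index=False)

    body = {label: float(p.df.query("kind == 'body'")["density"].mean())
            for label, p in profiles.items()}
    summary = {
        "n_promoter_overlapping_genes": len(prom),
        "median_log2_ratio": float(table["log2_ratio"].median()),
        "body_mean_density_wt": body["wt"],
        "body_mean_density_mut": body["mut"],
    }
    (RESULTS / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"{summary['n_promoter_overlapping_genes']} genes carry an implanted "
          f"region in their promoter; median log2 mut/wt expression ratio "
          f"{summary['median_log2_ratio']:.4f} (no de-repression)")
    print(f"mRNA density over implant bodies: wt {body['wt']:.4f}, "
          f"mut {body['mut']:.4f} RPKM (transcription confined to gene bodies)")


if __name__ == "__main__":
    main()
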