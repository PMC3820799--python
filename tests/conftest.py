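"""Shared builders for the test suite.

All fixtures construct data programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rddm.core import GenomicInterval, MethylomeTable, ReadSet


def make_methylome(library_id: str, rows: list[tuple]) -> MethylomeTable:
    """rows: (chrom, pos, strand, context, m, t)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "t"])
    return MethylomeTable(library_id, df)


def make_reads(rows: list[tuple], assay: str = "") -> ReadSet:
    """rows: (chrom, start, end, strand, unique, multiplicity)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "unique", "multiplicity"])
    return ReadSet(df, assay=assay)


def chh_tables(positions, wt_props, mut_props, coverage=10, n_wt=4,
               chrom="chr1", noise=None):
    """Aligned WT-replicate + mutant CHH methylomes with given proportions.

    ``wt_props``/``mut_props`` are per-site methylation levels; counts are
    deterministic (m = round(p * coverage)) unless ``noise`` (an rng) is
    given, in which case replicate counts are binomial draws.
    """
    positions = np.asarray(positions)
    wt_props = np.broadcast_to(np.asarray(wt_props, dtype=float), positions.shape)
    mut_props = np.broadcast_to(np.asarray(mut_props, dtype=float), positions.shape)

    def build(label, props, rng=None):
        rows = []
        for pos, p in zip(positions, props):
            t = coverage
            m = rng.binomial(t, p) if rng is not None else int(round(p * t))
            rows.append((chrom, int(pos), "+", "CHH", m, t))
        return make_methylome(label, rows)

    wt = [build(f"wt_{i}", wt_props, noise) for i in range(n_wt)]
    mut = build("mut", mut_props, noise)
    return wt, mut


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def iv():
    def _iv(start, end, chrom="chr1", strand="."):
        return GenomicInterval(chrom, start, end, strand)
    return _iv
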