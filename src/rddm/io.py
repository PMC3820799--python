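"""Reading and writing of external formats, plus cytosine-context classification.

Supported formats (all gzip-transparent by ``.gz`` suffix):

* genome FASTA;
* per-cytosine methylation TSV with columns
  ``chrom  pos(1-based)  strand  context  count_methylated  count_total``;
* BED6 read sets, with the *name* column carrying the uniqueness flag
  (``U``/``M``) and the *score* column the multiplicity;
* GFF3 gene annotation (``gene`` features).

Internally everything is 0-based half-open; the 1-based convention of the
TSV and GFF3 dialects is converted at this boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval, MethylomeTable, ReadSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str:
    """Classify the trinucleotide context of a cytosine.

    The context is determined solely by the two bases immediately downstream
    of the site on its own strand (reverse-complement on ``-``): ``CG`` if the
    next base is G, ``CHG`` if the next is H (not G) and the one after is G,
    and ``CHH`` otherwise, where H is any base that is not a G.

    Returns ``"incomplete"`` when fewer than two downstream bases exist
    (sites at chromosome ends); such sites are excluded downstream.

    Raises
    ------
    ValueError
        If the addressed base is not a cytosine on the given strand.
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos].upper() != "C":
            raise ValueError(f"not a cytosine: {chrom}:{pos}({strand})")
        if pos + 2 >= len(seq):
            return "incomplete"
        down = seq[pos + 1 : pos + 3].upper()
    elif strand == "-":
        if seq[pos].upper() != "G":  # C on the minus strand
            raise ValueError(f"not a cytosine: {chrom}:{pos}({strand})")
        if pos - 2 < 0:
            return "incomplete"
        down = seq[pos - 2 : pos].upper()[::-1].translate(_COMPLEMENT)
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if down[0] == "G":
        return "CG"
    if down[1] == "G":
        return "CHG"
    return "CHH"


def catalogue_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """List every cytosine on both strands with its context, vectorized.

    Returns a DataFrame (chrom, pos, strand, context) sorted by (chrom, pos).
    Sites with incomplete downstream context (chromosome ends) are excluded.
    """
    frames = []
    for chrom in sorted(genome):
        seq = np.frombuffer(genome[chrom].upper().encode("ascii"), dtype=np.uint8)
        is_c = seq == ord("C")
        is_g = seq == ord("G")
        n = len(seq)

        # plus strand: context from the two following bases
        pos = np.nonzero(is_c[: n - 2])[0]
        nxt1, nxt2 = is_g[pos + 1], is_g[pos + 2]
        ctx = np.where(nxt1, "CG", np.where(nxt2, "CHG", "CHH"))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+", "context": ctx}))

        # minus strand: a C on - is a G on +; downstream = preceding bases
        posm = np.nonzero(is_g[2:])[0] + 2
        prv1, prv2 = is_c[posm - 1], is_c[posm - 2]
        ctxm = np.where(prv1, "CG", np.where(prv2, "CHG", "CHH"))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": posm, "strand": "-", "context": ctxm}))

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# methylation TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


def read_methylome_tsv(path: str | Path, library_id: str | None = None) -> MethylomeTable:
    """Read a per-cytosine methylation TSV into a :class:`MethylomeTable`.

    Positions are 1-based in the file and converted to 0-based. Rows with
    ``count_methylated > count_total`` are dropped with a logged warning;
    structurally malformed lines raise with their line number.
    """
    path = Path(path)
    if library_id is None:
        library_id = path.name.removesuffix(".gz").removesuffix(".tsv")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}")
            chrom, pos_s, strand, context, m_s, t_s = fields
            try:
                pos1, m, t = int(pos_s), int(m_s), int(t_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if m > t:
                logger.warning("%s:%d: count_methylated %d > count_total %d; row dropped",
                               path, lineno, m, t)
                continue
            rows.append((chrom, pos1 - 1, strand, context, m, t))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "t"])
    return MethylomeTable(library_id, df)


def write_methylome_tsv(table: MethylomeTable, path: str | Path) -> None:
    """Write a methylome back to the 1-based TSV dialect (inverse of reading)."""
    out = table.df.copy()
    out["pos"] = out["pos"] + 1
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED6 read sets and generic interval BED
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | Path, assay: str = "") -> ReadSet:
    """Read a BED6 read set (name=U/M uniqueness, score=multiplicity).

    Rows with ``end <= start`` are rejected with a logged warning.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            start, end, mult = int(start_s), int(end_s), int(score_s)
            if end <= start:
                logger.warning("%s:%d: end <= start; row dropped", path, lineno)
                continue
            rows.append((chrom, start, end, strand, name == "U", mult))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "unique", "multiplicity"])
    return ReadSet(df, assay=assay)


def write_bed_reads(reads: ReadSet, path: str | Path) -> None:
    out = reads.df.copy()
    out["name"] = np.where(out["unique"], "U", "M")
    out = out[["chrom", "start", "end", "name", "multiplicity", "strand"]]
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write plain intervals as BED6 (name/score default to '.'/0)."""
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneModel]:
    """Extract gene models from GFF3 (1-based closed coordinates converted).

    Gene features without usable coordinates are skipped with a warning.
    """
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                continue
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: gene without usable coordinates; skipped", path, lineno)
                continue
            if end1 < start1:
                logger.warning("%s:%d: gene with end < start; skipped", path, lineno)
                continue
            gene_id = ""
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            genes.append(GeneModel(GenomicInterval(chrom, start1 - 1, end1, strand),
                                   gene_id or f"gene_{lineno}"))
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\trddm\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
            )
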