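"""Core genomic data types shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; 1-based
coordinates exist only at the TSV/GFF3 file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")
VALID_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint, floored for odd-length intervals (deterministic)."""
        return (self.start + self.end) // 2


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared length of two half-open intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intervals_overlap(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the intervals share at least ``min_bp`` bases.

    Half-open arithmetic: [0,100) and [100,200) do not overlap; [0,100)
    and [99,200) share exactly one base. Symmetric in its arguments.
    """
    return overlap_length(a, b) >= min_bp


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with its trinucleotide context on its own strand."""

    interval: GenomicInterval
    context: str

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("cytosine site must have width 1")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read after duplicate collapsing.

    ``multiplicity`` counts identical copies observed; ``is_unique`` marks
    uniquely mapping reads (the only reads that enter density numerators).
    """

    interval: GenomicInterval
    is_unique: bool = True
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-oriented transcription start site."""

    interval: GenomicInterval
    gene_id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene must be stranded")

    @property
    def tss(self) -> int:
        """TSS offset: ``start`` on +, ``end - 1`` on -. Lies within the gene."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region with its filter statistics.

    ``mean_diff`` is mean(raw WT methylation) - mean(raw mutant methylation)
    over the member CHH sites; ``area`` is the sum of the signed site
    statistics; direction is hypo when the mutant lost methylation.
    """

    interval: GenomicInterval
    n_chh: int
    mean_diff: float
    area: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample location test with its exact method recorded."""

    name: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


_METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "m", "t"]


class MethylomeTable:
    """Per-cytosine methylated/total read counts for one library.

    Backed by a DataFrame with columns (chrom, pos, strand, context, m, t),
    pos 0-based, sorted by (chrom, pos), no duplicate (chrom, pos, strand).
    """

    def __init__(self, library_id: str, df: pd.DataFrame, validate: bool = True):
        self.library_id = library_id
        df = df.loc[:, _METHYLOME_COLUMNS].reset_index(drop=True)
        if validate:
            self._validate(df)
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            return
        if (df["m"] < 0).any() or (df["t"] < 0).any():
            raise ValueError("negative counts")
        if (df["m"] > df["t"]).any():
            raise ValueError("methylated_count exceeds total_count")
        if not df["strand"].isin(("+", "-")).all():
            raise ValueError("cytosine strand must be + or -")
        if not df["context"].isin(VALID_CONTEXTS).all():
            raise ValueError("invalid context value")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) rows")

    def __len__(self) -> int:
        return len(self.df)

    def subset_context(self, context: str) -> pd.DataFrame:
        return self.df[self.df["context"] == context]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeTable):
            return NotImplemented
        return self.library_id == other.library_id and self.df.equals(other.df)


_READ_COLUMNS = ["chrom", "start", "end", "strand", "unique", "multiplicity"]


class ReadSet:
    """Aligned-read intervals (post-collapse representation).

    Backed by a DataFrame with columns
    (chrom, start, end, strand, unique, multiplicity); read length is
    ``end - start``.
    """

    def __init__(self, df: pd.DataFrame, assay: str = ""):
        df = df.loc[:, _READ_COLUMNS].reset_index(drop=True)
        if len(df) and ((df["end"] <= df["start"]).any() or (df["start"] < 0).any()):
            raise ValueError("read intervals must satisfy 0 <= start < end")
        if len(df) and (df["multiplicity"] < 1).any():
            raise ValueError("multiplicity must be >= 1")
        self.df = df
        self.assay = assay

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def total_reads(self) -> int:
        """Sum of multiplicities over all reads, unique and non-unique."""
        return int(self.df["multiplicity"].sum())

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord], assay: str = "") -> "ReadSet":
        rows = [
            (r.interval.chrom, r.interval.start, r.interval.end,
             r.interval.strand, r.is_unique, r.multiplicity)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=_READ_COLUMNS)
        return cls(df, assay=assay)

    def to_records(self) -> list[ReadRecord]:
        return [
            ReadRecord(
                GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                is_unique=bool(row.unique),
                multiplicity=int(row.multiplicity),
            )
            for row in self.df.itertuples()
        ]


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Tabulate intervals as (chrom, start, end, strand) for vector ops."""
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals],
        columns=["chrom", "start", "end", "strand"],
    )
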