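"""Core containers for per-locus allele-depth data.

A bulked-segregant experiment yields, for every SNP locus, four base-count
quadruples (reads of A, C, G, T) — one per sample: the two inbred parents and
the two phenotype-extreme F2 bulks.  :class:`LocusTable` holds these as a
column-typed :class:`pandas.DataFrame` so the genome scans can run vectorised;
:class:`LocusRecord` is the single-locus view used by the per-record
operations.

Conventions
-----------
* ``parent_wt`` / ``bulk_wt`` refer to the wild-type (sterile) side of the
  cross, ``parent_mut`` / ``bulk_mut`` to the mutant (restorer) side; the
  "mut" bulk is the pool of recessive-phenotype (sterile) F2 plants.
* ``allele_wt`` / ``allele_mut`` are the two parental alleles at the locus.
* Coordinates are 1-based inclusive throughout (VCF convention); BED output
  converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: sample roles, in the fixed column order used everywhere
SAMPLES: tuple[str, ...] = ("parent_wt", "parent_mut", "bulk_mut", "bulk_wt")

#: the 16 base-count columns of a locus table
COUNT_COLS: list[str] = [f"{s}_{b}" for s in SAMPLES for b in BASES]

#: full required column set of a locus table
REQUIRED_COLS: list[str] = ["chrom", "pos", "allele_wt", "allele_mut", "multiallelic"] + COUNT_COLS


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic (or multi-allelic-flagged) SNP locus."""

    chrom: str
    pos: int
    allele_wt: str
    allele_mut: str
    parent_wt_depths: tuple[int, int, int, int]
    parent_mut_depths: tuple[int, int, int, int]
    bulk_mut_depths: tuple[int, int, int, int]
    bulk_wt_depths: tuple[int, int, int, int]
    multiallelic: bool = False

    def depths(self, sample: str) -> tuple[int, int, int, int]:
        return getattr(self, f"{sample}_depths")


class LocusTable:
    """Ordered collection of loci plus an optional chromosome-length map.

    Parameters
    ----------
    df
        Frame with :data:`REQUIRED_COLS`.  Must be sorted by (chrom, pos)
        with no duplicate positions within a chromosome.
    genome
        Mapping chromosome name -> length in bp.  Optional; used by the
        simulator, the VCF writer (contig headers) and genome-fraction
        summaries.
    """

    def __init__(self, df: pd.DataFrame, genome: dict[str, int] | None = None):
        missing = [c for c in REQUIRED_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"locus table missing columns: {missing}")
        df = df.reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        for c in COUNT_COLS:
            df[c] = df[c].astype(np.int64)
        df["multiallelic"] = df["multiallelic"].astype(bool)
        self._validate_order(df)
        self.df = df
        self.genome: dict[str, int] = dict(genome or {})

    @staticmethod
    def _validate_order(df: pd.DataFrame) -> None:
        if len(df) < 2:
            return
        chrom = df["chrom"].to_numpy()
        pos = df["pos"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        bad = same & (pos[1:] <= pos[:-1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0]) + 1
            if pos[i] == pos[i - 1]:
                raise ValueError(
                    f"duplicate locus at {chrom[i]}:{pos[i]} (rows {i - 1},{i})"
                )
            raise ValueError(
                f"unsorted input at {chrom[i]}:{pos[i]} (row {i}); "
                "records must be sorted by (chrom, pos)"
            )
        # a chromosome may not reappear after another one started
        seen: set[str] = set()
        prev = None
        for c in chrom:
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c} occurs in two blocks; input unsorted")
                seen.add(c)
                prev = c

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusTable):
            return NotImplemented
        return self.genome == other.genome and self.df.equals(other.df)

    def counts(self, sample: str) -> np.ndarray:
        """(n, 4) int array of A/C/G/T read counts for one sample role."""
        if sample not in SAMPLES:
            raise KeyError(f"unknown sample role {sample!r}")
        return self.df[[f"{sample}_{b}" for b in BASES]].to_numpy()

    def total_depth(self, sample: str) -> np.ndarray:
        return self.counts(sample).sum(axis=1)

    def allele_index(self, which: str) -> np.ndarray:
        """Base index (0..3) of ``allele_wt`` or ``allele_mut`` per locus."""
        col = {"wt": "allele_wt", "mut": "allele_mut"}[which]
        return self.df[col].map(BASE_INDEX).to_numpy()

    def allele_counts(self, sample: str, which: str) -> np.ndarray:
        """Reads of the wt or mut parental allele in one sample, per locus."""
        c = self.counts(sample)
        return c[np.arange(len(c)), self.allele_index(which)]

    def subset(self, mask: np.ndarray) -> "LocusTable":
        return LocusTable(self.df.loc[np.asarray(mask, bool)].copy(), self.genome)

    def records(self) -> Iterator[LocusRecord]:
        for row in self.df.itertuples(index=False):
            yield LocusRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                allele_wt=row.allele_wt,
                allele_mut=row.allele_mut,
                parent_wt_depths=tuple(getattr(row, f"parent_wt_{b}") for b in BASES),
                parent_mut_depths=tuple(getattr(row, f"parent_mut_{b}") for b in BASES),
                bulk_mut_depths=tuple(getattr(row, f"bulk_mut_{b}") for b in BASES),
                bulk_wt_depths=tuple(getattr(row, f"bulk_wt_{b}") for b in BASES),
                multiallelic=bool(row.multiallelic),
            )

    @staticmethod
    def from_records(records: list[LocusRecord], genome: dict[str, int] | None = None) -> "LocusTable":
        rows = []
        for r in records:
            d = {
                "chrom": r.chrom,
                "pos": r.pos,
                "allele_wt": r.allele_wt,
                "allele_mut": r.allele_mut,
                "multiallelic": r.multiallelic,
            }
            for s in SAMPLES:
                for b, n in zip(BASES, r.depths(s)):
                    d[f"{s}_{b}"] = n
            rows.append(d)
        return LocusTable(pd.DataFrame(rows, columns=REQUIRED_COLS), genome)


def cotton_style_chrom_names(n: int) -> list[str]:
    """Chromosome names for an n-chromosome genome.

    For n == 26 (allotetraploid cotton) names follow the A/D subgenome
    convention ``chrA01..chrA13, chrD01..chrD13``; otherwise ``chr01..chrNN``.
    """
    if n == 26:
        return [f"chrA{i:02d}" for i in range(1, 14)] + [f"chrD{i:02d}" for i in range(1, 14)]
    return [f"chr{i:02d}" for i in range(1, n + 1)]
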