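"""Reading, writing and filtering of parent/bulk allele-depth tables.

Two on-disk dialects carry the same information:

* **VCF 4.2** with four samples (two parents, two bulks).  REF is the
  wild-type (sterile) parent allele and the first ALT the restorer-parent
  allele.  Each genotype carries ``AD`` (allele depths, interoperable) and
  ``BC`` (A,C,G,T base counts) — ``BC`` preserves reads of error bases that
  ``AD`` cannot represent, making the writer/reader pair an exact inverse.
* **TSV**: one row per locus with the 16 base-count columns spelled out,
  plus ``#genome`` header lines recording chromosome lengths.

Filtering follows the two analysis paths.  The SNP-index path drops, in
order: multi-allelic loci; loci with total read support below a cutoff in
either bulk; loci without a usable parental polymorphism.  The ED path
applies only the depth rule.  Each removal is attributed to the first rule
that fails, so the ledger counts partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .records import BASES, COUNT_COLS, REQUIRED_COLS, SAMPLES, LocusTable

log = logging.getLogger(__name__)

#: default lower bound on per-bulk read support ("read support < 4" rule)
DEFAULT_MIN_BULK_DEPTH = 4


@dataclass(frozen=True)
class FilterReport:
    """Ledger of one filtering pass; removal counts partition the input."""

    n_input: int
    n_removed_multiallelic: int
    n_removed_lowdepth: int
    n_removed_parent_absent: int
    n_retained: int
    path: str  # "snp_index" | "ed"

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_multiallelic
            + self.n_removed_lowdepth
            + self.n_removed_parent_absent
        )
        if self.n_input != removed + self.n_retained:
            raise ValueError("filter report does not balance")
        if self.path == "ed" and (
            self.n_removed_multiallelic or self.n_removed_parent_absent
        ):
            raise ValueError("ed path only removes low-depth loci")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# predicates (shared by the filter chain and usable as independent oracles)

def lowdepth_mask(table: LocusTable, min_bulk_depth: int) -> np.ndarray:
    """True where total read support is below the cutoff in either bulk."""
    return (table.total_depth("bulk_mut") < min_bulk_depth) | (
        table.total_depth("bulk_wt") < min_bulk_depth
    )


def parent_absent_mask(table: LocusTable) -> np.ndarray:
    """True where no usable parental polymorphism exists.

    A locus is unusable when either parent has a missing call (zero reads)
    or both parents' consensus bases agree (no polymorphism to orient the
    SNP-index).
    """
    c_wt = table.counts("parent_wt")
    c_mut = table.counts("parent_mut")
    missing = (c_wt.sum(axis=1) == 0) | (c_mut.sum(axis=1) == 0)
    same = c_wt.argmax(axis=1) == c_mut.argmax(axis=1)
    return missing | (~missing & same)


def filter_snp_index_path(
    table: LocusTable, min_bulk_depth: int = DEFAULT_MIN_BULK_DEPTH
) -> tuple[LocusTable, FilterReport]:
    """Apply the SNP-index path's three sequential locus filters.

    Order: multi-allelic, then low bulk depth, then parent-absent; every
    removed locus is charged to the first rule it fails.
    """
    multi = table.df["multiallelic"].to_numpy()
    low = ~multi & lowdepth_mask(table, min_bulk_depth)
    absent = ~multi & ~low & parent_absent_mask(table)
    keep = ~(multi | low | absent)
    report = FilterReport(
        n_input=len(table),
        n_removed_multiallelic=int(multi.sum()),
        n_removed_lowdepth=int(low.sum()),
        n_removed_parent_absent=int(absent.sum()),
        n_retained=int(keep.sum()),
        path="snp_index",
    )
    log.info(
        "snp-index filter: %d in, %d multi-allelic, %d low-depth, "
        "%d parent-absent, %d retained",
        report.n_input,
        report.n_removed_multiallelic,
        report.n_removed_lowdepth,
        report.n_removed_parent_absent,
        report.n_retained,
    )
    return table.subset(keep), report


def filter_ed_path(
    table: LocusTable, min_bulk_depth: int = DEFAULT_MIN_BULK_DEPTH
) -> tuple[LocusTable, FilterReport]:
    """Apply the ED path's single filter: read support in every bulk."""
    low = lowdepth_mask(table, min_bulk_depth)
    report = FilterReport(
        n_input=len(table),
        n_removed_multiallelic=0,
        n_removed_lowdepth=int(low.sum()),
        n_removed_parent_absent=0,
        n_retained=int((~low).sum()),
        path="ed",
    )
    log.info(
        "ed filter: %d in, %d low-depth, %d retained",
        report.n_input,
        report.n_removed_lowdepth,
        report.n_retained,
    )
    return table.subset(~low), report


def genotype_calls(table: LocusTable, sample: str, het_band: tuple[float, float] = (0.25, 0.75)) -> np.ndarray:
    """Coarse genotype call per locus for one bulk from allele fractions.

    Returns 0 (hom wild-type allele), 1 (het), 2 (hom restorer allele) or -1
    (missing: no informative reads).  The call uses the restorer-allele
    fraction among reads matching either parental allele, binned at
    ``het_band`` (defaults: <0.25 hom-ref, >0.75 hom-alt, else het).
    """
    lo, hi = het_band
    n_wt = table.allele_counts(sample, "wt").astype(float)
    n_mut = table.allele_counts(sample, "mut").astype(float)
    denom = n_wt + n_mut
    call = np.full(len(table), -1, dtype=np.int8)
    ok = denom > 0
    frac = np.divide(n_mut, denom, out=np.zeros_like(denom), where=ok)
    call[ok & (frac < lo)] = 0
    call[ok & (frac > hi)] = 2
    call[ok & (frac >= lo) & (frac <= hi)] = 1
    return call


def select_pool_divergent(
    table: LocusTable, het_band: tuple[float, float] = (0.25, 0.75)
) -> LocusTable:
    """Keep loci whose coarse genotype call differs between the two bulks.

    Loci with a missing call in either bulk are dropped (no evidence of
    divergence).  This reproduces the ED path's "different loci between the
    two mixed pools" selection.
    """
    g_mut = genotype_calls(table, "bulk_mut", het_band)
    g_wt = genotype_calls(table, "bulk_wt", het_band)
    keep = (g_mut >= 0) & (g_wt >= 0) & (g_mut != g_wt)
    return table.subset(keep)


# ---------------------------------------------------------------------------
# readers / writers

def write_tsv(table: LocusTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in table.genome.items():
            fh.write(f"#genome\t{chrom}\t{length}\n")
        table.df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> LocusTable:
    genome: dict[str, int] = {}
    with open(path) as fh:
        pos0 = fh.tell()
        line = fh.readline()
        while line.startswith("#genome\t"):
            _, chrom, length = line.rstrip("\n").split("\t")
            genome[chrom] = int(length)
            pos0 = fh.tell()
            line = fh.readline()
        fh.seek(pos0)
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "allele_wt": str, "allele_mut": str})
    return LocusTable(df, genome)


_VCF_HEADER_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per listed allele">',
    '##FORMAT=<ID=BC,Number=4,Type=Integer,Description="Read counts of A,C,G,T bases">',
]


def write_vcf(
    table: LocusTable,
    path: str | Path,
    sample_names: dict[str, str] | None = None,
) -> None:
    """Write the table as uncompressed VCF 4.2.

    ``sample_names`` maps the four roles (parent_wt, parent_mut, bulk_mut,
    bulk_wt) to column names; defaults to the role names themselves.
    """
    names = {s: s for s in SAMPLES}
    names.update(sample_names or {})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsascan\n")
        for chrom, length in table.genome.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        cols = "\t".join(names[s] for s in SAMPLES)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        counts = {s: table.counts(s) for s in SAMPLES}
        df = table.df
        for i in range(len(df)):
            ref = df.at[i, "allele_wt"]
            alts = [df.at[i, "allele_mut"]]
            if df.at[i, "multiallelic"]:
                # surface the extra allele(s): any other base seen in a bulk
                pooled = counts["bulk_mut"][i] + counts["bulk_wt"][i]
                for j, b in enumerate(BASES):
                    if b not in (ref, alts[0]) and pooled[j] > 0:
                        alts.append(b)
                if len(alts) == 1:  # flagged but no visible third base
                    alts.append(next(b for b in BASES if b not in (ref, alts[0])))
            allele_idx = [BASES.index(a) for a in [ref] + alts]
            fields = []
            for s in SAMPLES:
                bc = counts[s][i]
                ad = ",".join(str(bc[j]) for j in allele_idx)
                fields.append(f"./.:{ad}:" + ",".join(str(x) for x in bc))
            fh.write(
                f"{df.at[i, 'chrom']}\t{df.at[i, 'pos']}\t.\t{ref}\t{','.join(alts)}"
                f"\t.\tPASS\t.\tGT:AD:BC\t" + "\t".join(fields) + "\n"
            )


def _read_vcf(path: str | Path, sample_roles: dict[str, str]) -> LocusTable:
    missing = [r for r in SAMPLES if r not in sample_roles]
    if missing:
        raise ValueError(f"sample_roles missing roles: {missing}")
    rows = []
    genome: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        for role, name in sample_roles.items():
            if name not in header_samples:
                raise ValueError(f"sample {name!r} (role {role}) not in VCF header")
        for ctg in vf.header.contigs.values():
            if ctg.length:
                genome[ctg.name] = ctg.length
        for rec in vf:
            if rec.ref is None or not rec.alts:
                raise ValueError(f"malformed record at {rec.chrom}:{rec.pos}")
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "allele_wt": rec.ref,
                "allele_mut": rec.alts[0],
                "multiallelic": len(rec.alts) > 1,
            }
            alleles = [rec.ref] + list(rec.alts)
            for role in SAMPLES:
                sample = rec.samples[sample_roles[role]]
                if "BC" in sample and sample["BC"] is not None and sample["BC"][0] is not None:
                    bc = list(sample["BC"])
                else:
                    ad = sample.get("AD")
                    if ad is None or ad[0] is None:
                        raise ValueError(
                            f"missing depth field for {sample_roles[role]} at {rec.chrom}:{rec.pos}"
                        )
                    bc = [0, 0, 0, 0]
                    for a, d in zip(alleles, ad):
                        if a in BASES:
                            bc[BASES.index(a)] += int(d)
                for b, n in zip(BASES, bc):
                    row[f"{role}_{b}"] = int(n)
            rows.append(row)
    df = pd.DataFrame(rows, columns=REQUIRED_COLS)
    return LocusTable(df, genome)


def read_locus_table(
    path: str | Path,
    format: str = "auto",
    sample_roles: dict[str, str] | None = None,
) -> LocusTable:
    """Read a locus table from VCF or TSV.

    ``sample_roles`` maps the roles parent_wt/parent_mut/bulk_mut/bulk_wt to
    VCF sample names (defaults to identical names; ignored for TSV).
    Multi-allelic sites are retained and flagged — removal is the filter's
    job, not the reader's.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path, sample_roles or {s: s for s in SAMPLES})
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")
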