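"""Genic-context classification of SNVs and indels in candidate regions.

Every variant gets exactly one category per annotation run, chosen by
precedence ``exonic > splicing > intronic > upstream/downstream >
intergenic``:

* **exonic** — inside an exon; for SNVs in CDS the coding effect is called
  by codon translation with the standard genetic code (synonymous,
  nonsynonymous, stop_gain, stop_loss); for indels in CDS by length
  difference mod 3 (frameshift / nonframeshift).
* **splicing** — intronic but within ``splice_bp`` (default 2) of an
  exon/intron boundary.
* **intronic** — inside the gene span, between exons.
* **upstream/downstream** — within ``flank_bp`` (default 1000) of the gene
  span, on the strand-aware side.
* **intergenic** — everything else.

A variant hitting several genes is resolved to the highest-precedence
single call so that category counts partition the variant set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

CATEGORIES = ("exonic", "splicing", "intronic", "upstream", "downstream", "intergenic")
_PRECEDENCE = {"exonic": 0, "splicing": 1, "intronic": 2, "upstream": 3,
               "downstream": 3, "intergenic": 4}

DEFAULT_FLANK_BP = 1_000
DEFAULT_SPLICE_BP = 2


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure of one gene, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in ivs:
                if s > e or s <= prev_end:
                    raise ValueError(f"{self.gene_id}: {name} unsorted or overlapping")
                prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment {s}-{e} outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class Variant:
    """VCF-style variant: pos is the first REF base, 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class VariantAnnotation:
    category: str
    effect: str | None = None  # present only for exonic variants
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.effect is not None and self.category != "exonic":
            raise ValueError("effect is only defined for exonic variants")


def _category_in_gene(v: Variant, g: GeneModel, flank_bp: int, splice_bp: int) -> str | None:
    """Category of ``v`` relative to one gene, or None if out of reach."""
    if v.chrom != g.chrom:
        return None
    if any(s <= v.end and v.pos <= e for s, e in g.exons):
        return "exonic"
    if g.start <= v.pos <= g.end:
        # intronic; splicing when near an exon/intron boundary
        for (s1, e1), (s2, _) in zip(g.exons, g.exons[1:]):
            if e1 < v.pos < s2:
                if v.pos - e1 <= splice_bp or s2 - v.pos <= splice_bp:
                    return "splicing"
                return "intronic"
        return "intronic"
    before = g.start - flank_bp <= v.pos < g.start
    after = g.end < v.pos <= g.end + flank_bp
    if g.strand == "+":
        if before:
            return "upstream"
        if after:
            return "downstream"
    else:
        if before:
            return "downstream"
        if after:
            return "upstream"
    return None


def _coding_effect(v: Variant, g: GeneModel, seqs) -> str | None:
    """Coding effect for a variant overlapping this gene's CDS."""
    in_cds = any(s <= v.end and v.pos <= e for s, e in g.cds)
    if not in_cds:
        return None
    if not v.is_snv:
        shift = (len(v.ref) - len(v.alt)) % 3
        return "frameshift" if shift else "nonframeshift"
    if seqs is None:
        log.warning("no reference sequence; exonic SNV %s:%d left without effect",
                    v.chrom, v.pos)
        return None
    chrom_seq = str(seqs[v.chrom])
    cds_seq = "".join(chrom_seq[s - 1 : e] for s, e in g.cds)
    offset = 0
    for s, e in g.cds:
        if s <= v.pos <= e:
            offset += v.pos - s
            break
        offset += e - s + 1
    mutated = cds_seq[:offset] + v.alt + cds_seq[offset + 1 :]
    if g.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        offset = len(cds_seq) - 1 - offset
    codon_i = offset // 3
    old = str(Seq(cds_seq[3 * codon_i : 3 * codon_i + 3]).translate())
    new = str(Seq(mutated[3 * codon_i : 3 * codon_i + 3]).translate())
    if old == new:
        return "synonymous"
    if new == "*" and old != "*":
        return "stop_gain"
    if old == "*" and new != "*":
        return "stop_loss"
    return "nonsynonymous"


def classify_variant(
    variant: Variant,
    genes: list[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
    splice_bp: int = DEFAULT_SPLICE_BP,
    coding_seq=None,
    chroms: set[str] | None = None,
) -> VariantAnnotation:
    """Classify one variant against a gene-model collection.

    ``coding_seq`` is any chromosome-name-indexable sequence source (a dict
    of strings, a :class:`pyfaidx.Fasta`, ...); without it exonic variants
    get a category but no SNV effect.  ``chroms`` is the known chromosome
    set (defaults to the gene models' chromosomes); a variant on an unknown
    chromosome is an explicit failure.
    """
    known = chroms if chroms is not None else {g.chrom for g in genes}
    if variant.chrom not in known:
        raise ValueError(f"variant chromosome {variant.chrom!r} not in the genome")
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        cat = _category_in_gene(variant, g, flank_bp, splice_bp)
        if cat is not None and (best is None or _PRECEDENCE[cat] < best[0]):
            best = (_PRECEDENCE[cat], cat, g)
    if best is None:
        return VariantAnnotation("intergenic")
    _, cat, gene = best
    effect = _coding_effect(variant, gene, coding_seq) if cat == "exonic" else None
    return VariantAnnotation(cat, effect, gene.gene_id)


def summarize_region_variants(
    annotated: list[tuple[Variant, VariantAnnotation]],
    regions,
) -> pd.DataFrame:
    """Category x (snv, indel) counts restricted to the candidate regions.

    A variant is in a region when its start position lies inside it.  Totals
    over the table equal the number of classified variants inside regions.
    """
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=["snv", "indel"])
    regions = list(regions)
    for v, ann in annotated:
        inside = any(r.chrom == v.chrom and r.start <= v.pos <= r.end for r in regions)
        if inside:
            counts.loc[ann.category, "snv" if v.is_snv else "indel"] += 1
    counts.index.name = "category"
    return counts


def annotations_to_frame(
    annotated: list[tuple[Variant, VariantAnnotation]]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v, _ in annotated],
            "pos": [v.pos for v, _ in annotated],
            "ref": [v.ref for v, _ in annotated],
            "alt": [v.alt for v, _ in annotated],
            "type": ["snv" if v.is_snv else "indel" for v, _ in annotated],
            "category": [a.category for _, a in annotated],
            "effect": [a.effect or "" for _, a in annotated],
            "gene_id": [a.gene_id or "" for _, a in annotated],
        }
    )


# ---------------------------------------------------------------------------
# gene-model readers

def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3 via gffutils (first mRNA per gene)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted((f.start, f.end) for f in db.children(parent, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(parent, featuretype="CDS"))
        if not exons:
            exons = [(gene.start, gene.end)]
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand,
                               tuple(exons), tuple(cds)))
    return genes


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12 (blocks -> exons, thick range -> CDS)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, cstart, cend, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (cstart + st + 1, cstart + st + sz) for st, sz in zip(starts, sizes)
            )
            cds = []
            if thick_e > thick_s:  # thick range in 0-based half-open
                for s, e in exons:
                    cs, ce = max(s, thick_s + 1), min(e, thick_e)
                    if cs <= ce:
                        cds.append((cs, ce))
            genes.append(GeneModel(name, chrom, strand, exons, tuple(cds)))
    return genes


def read_variants_vcf(path: str | Path) -> list[Variant]:
    """All REF/ALT pairs of a VCF as simple variants (one per ALT)."""
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return out
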