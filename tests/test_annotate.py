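"""Genic-context classification: categories, coding effects, summaries."""

import pytest

from bsascan import CandidateRegion, GeneModel, Variant, classify_variant
from bsascan.annotate import (CATEGORIES, VariantAnnotation,
                              read_gene_models_bed12, read_gene_models_gff3,
                              summarize_region_variants)


@pytest.fixture(scope="module")
def reference():
    """One chromosome with a two-exon coding gene on each strand.

    The plus-strand CDS reads ATG (TAC)x18 TGA split over two exons
    (101-130 and 201-230); the minus-strand gene at 501-630 is a single
    exon whose reverse complement reads ATG (GAA)x8 TAG.
    """
    seq = ["A"] * 700
    plus_cds = "ATG" + "TAC" * 18 + "TGA"
    seq[100:130] = plus_cds[:30]
    seq[200:230] = plus_cds[30:]
    from Bio.Seq import Seq

    minus_cds = "ATG" + "GAA" * 8 + "TAG"  # 30 nt
    seq[500:530] = str(Seq(minus_cds).reverse_complement())
    chrom_seq = {"chr1": "".join(seq)}
    plus = GeneModel("Gplus", "chr1", "+", ((101, 130), (201, 230)),
                     ((101, 130), (201, 230)))
    minus = GeneModel("Gminus", "chr1", "-", ((501, 530),), ((501, 530),))
    return chrom_seq, [plus, minus]


def test_gene_model_invariants():
    with pytest.raises(ValueError, match="strand"):
        GeneModel("g", "chr1", "*", ((1, 10),))
    with pytest.raises(ValueError, match="unsorted"):
        GeneModel("g", "chr1", "+", ((10, 20), (5, 8)))
    with pytest.raises(ValueError, match="outside exons"):
        GeneModel("g", "chr1", "+", ((10, 20),), ((15, 25),))


@pytest.mark.parametrize(
    "pos,ref,alt,category,effect",
    [
        (106, "C", "A", "exonic", "stop_gain"),      # TAC -> TAA
        (106, "C", "T", "exonic", "synonymous"),     # TAC -> TAT
        (105, "A", "C", "exonic", "nonsynonymous"),  # TAC -> TCC
        (230, "A", "G", "exonic", "stop_loss"),      # TGA -> TGG
        (131, "A", "T", "splicing", None),           # 1 bp into the intron
        (199, "A", "T", "splicing", None),           # 2 bp before exon 2
        (150, "A", "T", "intronic", None),           # mid-intron
        (50, "A", "T", "upstream", None),
        (300, "A", "T", "downstream", None),
        (400, "A", "T", "intergenic", None),
    ],
)
def test_plus_strand_classification(reference, pos, ref, alt, category, effect):
    # flank of 100 bp keeps the toy chromosome's far side intergenic
    seqs, genes = reference
    ann = classify_variant(Variant("chr1", pos, ref, alt), genes,
                           flank_bp=100, coding_seq=seqs)
    assert ann.category == category
    assert ann.effect == effect


def test_minus_strand_codon_effects(reference):
    seqs, genes = reference
    # last codon of the minus-strand CDS (TAG) occupies genomic 501-503;
    # genomic 501 is its third base: C->T makes genomic CTA, codon TAG->TAA
    ann = classify_variant(Variant("chr1", 501, "C", "T"), genes, coding_seq=seqs)
    assert (ann.category, ann.effect) == ("exonic", "synonymous")
    # genomic 503 pairs with the first codon base T; A->T gives codon AAG: stop_loss
    ann = classify_variant(Variant("chr1", 503, "A", "T"), genes, coding_seq=seqs)
    assert (ann.category, ann.effect) == ("exonic", "stop_loss")


def test_strand_flip_swaps_flanking_calls_only(reference):
    seqs, genes = reference
    plus = genes[0]
    flipped = GeneModel(plus.gene_id, plus.chrom, "-", plus.exons, plus.cds)
    for pos, fwd in ((50, "upstream"), (300, "downstream")):
        assert classify_variant(Variant("chr1", pos, "A", "T"), [plus]).category == fwd
    swapped = {"upstream": "downstream", "downstream": "upstream"}
    for pos, fwd in ((50, "upstream"), (300, "downstream")):
        got = classify_variant(Variant("chr1", pos, "A", "T"), [flipped]).category
        assert got == swapped[fwd]
    for pos in (106, 150):  # exonic/intronic calls unaffected by strand
        a = classify_variant(Variant("chr1", pos, "A", "T"), [plus]).category
        b = classify_variant(Variant("chr1", pos, "A", "T"), [flipped]).category
        assert a == b


def test_indel_effects_by_length_mod_three(reference):
    seqs, genes = reference
    nonfs = classify_variant(Variant("chr1", 110, "CTAC", "C"), genes, coding_seq=seqs)
    assert (nonfs.category, nonfs.effect) == ("exonic", "nonframeshift")
    fs = classify_variant(Variant("chr1", 110, "CT", "C"), genes, coding_seq=seqs)
    assert (fs.category, fs.effect) == ("exonic", "frameshift")


def test_coding_snv_effects_partition_cds_positions(reference):
    """Every CDS SNV gets exactly one of the four coding-effect labels."""
    seqs, genes = reference
    effects = {"synonymous", "nonsynonymous", "stop_gain", "stop_loss"}
    n = 0
    for pos in list(range(101, 131)) + list(range(201, 231)):
        ref = seqs["chr1"][pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            ann = classify_variant(Variant("chr1", pos, ref, alt), genes,
                                   coding_seq=seqs)
            assert ann.category == "exonic"
            assert ann.effect in effects
            n += 1
    assert n == 60 * 3


def test_unknown_chromosome_is_an_error(reference):
    _, genes = reference
    with pytest.raises(ValueError, match="chrX"):
        classify_variant(Variant("chrX", 5, "A", "T"), genes)


def test_exonic_without_reference_sequence_warns_and_omits_effect(reference, caplog):
    _, genes = reference
    with caplog.at_level("WARNING"):
        ann = classify_variant(Variant("chr1", 106, "C", "A"), genes)
    assert ann.category == "exonic"
    assert ann.effect is None
    assert "without effect" in caplog.text


def test_effect_outside_exonic_category_rejected():
    with pytest.raises(ValueError):
        VariantAnnotation("intronic", "synonymous")


# --- summaries -------------------------------------------------------------

def test_summary_recovers_constructed_ground_truth(reference):
    seqs, genes = reference
    placement = (
        [(106, "exonic")] * 1 + [(205, "exonic")] * 1
        + [(150, "intronic")] * 3 + [(400, "intergenic")] * 2
        + [(50, "upstream")] * 1 + [(300, "downstream")] * 1
    )
    variants = [Variant("chr1", pos, "A", "T") for pos, _ in placement]
    annotated = [(v, classify_variant(v, genes, flank_bp=100, coding_seq=seqs))
                 for v in variants]
    region = CandidateRegion("chr1", 1, 700)
    table = summarize_region_variants(annotated, [region])
    assert table.loc["exonic", "snv"] == 2
    assert table.loc["intronic", "snv"] == 3
    assert table.loc["intergenic", "snv"] == 2
    assert table.loc["upstream", "snv"] == 1
    assert table.loc["downstream", "snv"] == 1
    assert table.to_numpy().sum() == len(variants)


def test_summary_counts_partition_region_variants(reference):
    seqs, genes = reference
    variants = [Variant("chr1", p, "A", "T") for p in range(40, 650, 7)]
    annotated = [(v, classify_variant(v, genes, coding_seq=seqs)) for v in variants]
    region = CandidateRegion("chr1", 100, 400)
    table = summarize_region_variants(annotated, [region])
    in_region = sum(1 for v in variants if 100 <= v.pos <= 400)
    assert table.to_numpy().sum() == in_region
    assert set(table.index) == set(CATEGORIES)


def test_summary_empty_for_no_or_outside_variants(reference):
    seqs, genes = reference
    assert summarize_region_variants([], [CandidateRegion("chr1", 1, 10)]).to_numpy().sum() == 0
    v = Variant("chr1", 400, "A", "T")
    annotated = [(v, classify_variant(v, genes, coding_seq=seqs))]
    table = summarize_region_variants(annotated, [CandidateRegion("chr1", 1, 10)])
    assert table.to_numpy().sum() == 0


# --- readers ---------------------------------------------------------------

def test_gff3_and_bed12_readers_agree(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t230\t.\t+\t.\tID=G1\n"
        "chr1\tsrc\tmRNA\t101\t230\t.\t+\t.\tID=G1.t1;Parent=G1\n"
        "chr1\tsrc\texon\t101\t130\t.\t+\t.\tParent=G1.t1\n"
        "chr1\tsrc\texon\t201\t230\t.\t+\t.\tParent=G1.t1\n"
        "chr1\tsrc\tCDS\t101\t130\t.\t+\t0\tParent=G1.t1\n"
        "chr1\tsrc\tCDS\t201\t230\t.\t+\t0\tParent=G1.t1\n"
    )
    bed = tmp_path / "g.bed"
    bed.write_text("chr1\t100\t230\tG1\t0\t+\t100\t230\t0\t2\t30,30\t0,100\n")
    (g1,) = read_gene_models_gff3(gff)
    (g2,) = read_gene_models_bed12(bed)
    assert g1.exons == g2.exons == ((101, 130), (201, 230))
    assert g1.cds == g2.cds == ((101, 130), (201, 230))
    assert g1.strand == g2.strand == "+"
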