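"""Synthetic F2 extreme-bulk sequencing experiments.

Emulates the entry point of a bulked-segregant mapping pipeline: two inbred
parents polymorphic at every marker, an F2 population segregating for a single
dominant fertility-restorer locus, two phenotype-extreme bulks, and per-locus
read counts for parents and bulks.  No reads or alignments are simulated —
the output is post-variant-calling allele depths, which is what the scans
consume.

Model
-----
* Markers are placed uniformly along each chromosome; recombination between
  adjacent markers follows Haldane's mapping function (no interference),
  r = (1 - exp(-2d)) / 2 with d in Morgans from a constant cM/Mb rate.
* The causal locus is planted at a configurable position and carries the
  restorer allele from the mutant parent.  Phenotype is dominant: plants with
  at least one restorer allele are fertile, homozygous-recessive plants are
  sterile.
* The "mut" bulk pools ``bulk_size`` sterile plants, the "wt" bulk
  ``bulk_size`` fertile plants (lowest plant index first, so bulking is
  reproducible).
* Per-locus sequencing depth is Poisson around the configured mean; reads
  draw alleles binomially from the bulk's true allele frequency; each read is
  misread to one of the three other bases with probability ``seq_error_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import BASES, COUNT_COLS, REQUIRED_COLS, LocusTable, cotton_style_chrom_names

#: rows of this matrix list the three base indices other than the row index
_OTHER_BASES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclass
class SimConfig:
    """Design of a simulated F2 bulked-segregant experiment.

    Defaults follow the study design the package targets: 30-plant extreme
    bulks, 26 chromosomes, ~137.7k SNPs, parent depth 47.90x and bulk depth
    50.78x.  The F2 population size from which the extremes are drawn is a
    free design choice (default 200).  ``recomb_cm_per_mb`` converts physical
    to genetic distance; 2.5 cM/Mb is a typical plant-genome average.
    """

    n_f2: int = 200
    bulk_size: int = 30
    n_chromosomes: int = 26
    chrom_length_bp: int = 80_000_000
    n_loci: int = 137_741
    causal_chrom: str = "chrD05"
    causal_pos_bp: int = 40_000_000
    parent_depth_mean: float = 47.90
    bulk_depth_mean: float = 50.78
    seq_error_rate: float = 0.001
    recomb_cm_per_mb: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.bulk_size > self.n_f2:
            raise ValueError("2*bulk_size must not exceed n_f2")
        if not (1 <= self.causal_pos_bp <= self.chrom_length_bp):
            raise ValueError("causal_pos_bp outside [1, chrom_length_bp]")
        if self.parent_depth_mean <= 0 or self.bulk_depth_mean <= 0:
            raise ValueError("sequencing depths must be positive")
        if not (0 <= self.seq_error_rate < 0.25):
            raise ValueError("seq_error_rate must be in [0, 0.25)")
        if self.n_loci < 1 or self.n_chromosomes < 1:
            raise ValueError("n_loci and n_chromosomes must be positive")
        names = cotton_style_chrom_names(self.n_chromosomes)
        if self.causal_chrom not in names:
            raise ValueError(
                f"causal_chrom {self.causal_chrom!r} not among simulated "
                f"chromosomes {names[0]}..{names[-1]}"
            )

    @property
    def chrom_names(self) -> list[str]:
        return cotton_style_chrom_names(self.n_chromosomes)


@dataclass
class TruthRecord:
    """Ground truth of one simulated experiment.

    ``f2_allele_freq`` is the realised frequency of the restorer allele over
    all F2 plants per locus; ``bulk_mut_freq`` / ``bulk_wt_freq`` are the
    realised frequencies among the pooled chromosomes of each bulk (the
    quantity reads are drawn from, before sequencing noise).
    """

    causal_chrom: str
    causal_pos: int
    causal_genotypes: np.ndarray  # (n_f2,) copies of restorer allele, 0/1/2
    phenotypes: np.ndarray  # (n_f2,) True = fertile
    bulk_mut_plants: np.ndarray  # indices of sterile-bulk plants
    bulk_wt_plants: np.ndarray  # indices of fertile-bulk plants
    loci: pd.DataFrame = field(repr=False)  # chrom,pos,f2_allele_freq,bulk_mut_freq,bulk_wt_freq

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#causal_chrom={self.causal_chrom}\tcausal_pos={self.causal_pos}\n")
            fh.write(
                "#n_sterile=%d\tn_fertile=%d\n"
                % ((~self.phenotypes).sum(), self.phenotypes.sum())
            )
            self.loci.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _haldane_r(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Recombination fraction between markers ``dist_bp`` apart."""
    morgans = dist_bp * cm_per_mb / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _simulate_gametes(rng: np.random.Generator, n_gametes: int, r: np.ndarray) -> np.ndarray:
    """(n_gametes, n_loci) matrix of 0/1 parental phases along one chromosome.

    Phase at the first marker is uniform; phase switches between adjacent
    markers with the Haldane recombination fraction ``r`` (length n_loci-1).
    """
    n_loci = len(r) + 1
    start = rng.integers(0, 2, size=(n_gametes, 1))
    switches = rng.random((n_gametes, len(r))) < r
    phase = np.concatenate([start, switches], axis=1).cumsum(axis=1) % 2
    return phase.astype(np.int8)


def _read_counts_for_allele_pair(
    rng: np.random.Generator,
    depth: np.ndarray,
    p_mut: np.ndarray,
    idx_wt: np.ndarray,
    idx_mut: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Draw an (n_loci, 4) base-count matrix for one sample.

    Each of ``depth`` reads carries the mut allele with probability ``p_mut``
    and the wt allele otherwise; a read is then misread to one of the three
    other bases uniformly with probability ``error_rate``.
    """
    n = len(depth)
    counts = np.zeros((n, 4), dtype=np.int64)
    k_mut = rng.binomial(depth, p_mut)
    k_wt = depth - k_mut
    rows = np.arange(n)
    for k_true, idx in ((k_mut, idx_mut), (k_wt, idx_wt)):
        if error_rate > 0:
            errs = rng.binomial(k_true, error_rate)
        else:
            errs = np.zeros(n, dtype=np.int64)
        counts[rows, idx] += k_true - errs
        # split errors uniformly over the three other bases via sequential
        # binomial thinning (marginals of a symmetric multinomial)
        e1 = rng.binomial(errs, 1.0 / 3.0)
        e2 = rng.binomial(errs - e1, 0.5)
        e3 = errs - e1 - e2
        others = _OTHER_BASES[idx]
        counts[rows, others[:, 0]] += e1
        counts[rows, others[:, 1]] += e2
        counts[rows, others[:, 2]] += e3
    return counts


def simulate_f2_experiment(cfg: SimConfig) -> tuple[LocusTable, TruthRecord]:
    """Simulate one F2 extreme-bulk experiment.

    Returns the locus table (parents + both bulks, all loci including the
    planted causal locus) and the ground-truth record.  Identical ``cfg``
    (including seed) gives byte-identical serialised output.

    Raises
    ------
    RuntimeError
        If either phenotype class holds fewer than ``bulk_size`` plants,
        naming the deficit.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names

    # uniform marker placement, causal locus inserted on its chromosome
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per_chrom[: cfg.n_loci % cfg.n_chromosomes] += 1
    positions: dict[str, np.ndarray] = {}
    causal_idx_on_chrom = -1
    for name, k in zip(chroms, per_chrom):
        pos = np.linspace(1, cfg.chrom_length_bp, int(k)).round().astype(np.int64)
        pos = np.unique(pos)
        if name == cfg.causal_chrom:
            pos = np.unique(np.append(pos, cfg.causal_pos_bp))
            causal_idx_on_chrom = int(np.searchsorted(pos, cfg.causal_pos_bp))
        positions[name] = pos

    # F2 genotypes: each plant = two independent F1 gametes; phase 1 carries
    # the mutant (restorer) parent's allele
    genotype_blocks: list[np.ndarray] = []  # (n_f2, n_loci_chrom) copies of mut allele
    for name in chroms:
        pos = positions[name]
        r = _haldane_r(np.diff(pos), cfg.recomb_cm_per_mb)
        gam = _simulate_gametes(rng, 2 * cfg.n_f2, r)
        genotype_blocks.append((gam[: cfg.n_f2] + gam[cfg.n_f2 :]).astype(np.int8))

    ci = chroms.index(cfg.causal_chrom)
    causal_geno = genotype_blocks[ci][:, causal_idx_on_chrom].astype(np.int64)
    fertile = causal_geno >= 1  # dominant restorer

    n_sterile = int((~fertile).sum())
    n_fertile = int(fertile.sum())
    for label, n_have in (("sterile", n_sterile), ("fertile", n_fertile)):
        if n_have < cfg.bulk_size:
            raise RuntimeError(
                f"cannot form {label} bulk: need {cfg.bulk_size} plants, "
                f"only {n_have} of {cfg.n_f2} F2 plants are {label}"
            )
    bulk_mut_plants = np.flatnonzero(~fertile)[: cfg.bulk_size]  # sterile pool
    bulk_wt_plants = np.flatnonzero(fertile)[: cfg.bulk_size]  # fertile pool

    # per-locus allele bases: two distinct bases per locus
    n_total = sum(len(positions[c]) for c in chroms)
    wt_idx = rng.integers(0, 4, size=n_total)
    mut_idx = (wt_idx + rng.integers(1, 4, size=n_total)) % 4

    # true restorer-allele frequencies in each pool
    geno_all = np.concatenate([g for g in genotype_blocks], axis=1)  # (n_f2, n_total)
    two_b = 2 * cfg.bulk_size
    k_mut_bulk = geno_all[bulk_mut_plants].sum(axis=0).astype(np.int64)
    k_wt_bulk = geno_all[bulk_wt_plants].sum(axis=0).astype(np.int64)
    p_bulk_mut = k_mut_bulk / two_b
    p_bulk_wt = k_wt_bulk / two_b
    f2_freq = geno_all.sum(axis=0) / (2 * cfg.n_f2)

    zeros = np.zeros(n_total)
    ones = np.ones(n_total)
    depth_pwt = rng.poisson(cfg.parent_depth_mean, n_total)
    depth_pmut = rng.poisson(cfg.parent_depth_mean, n_total)
    depth_bmut = rng.poisson(cfg.bulk_depth_mean, n_total)
    depth_bwt = rng.poisson(cfg.bulk_depth_mean, n_total)

    e = cfg.seq_error_rate
    c_pwt = _read_counts_for_allele_pair(rng, depth_pwt, zeros, wt_idx, mut_idx, e)
    c_pmut = _read_counts_for_allele_pair(rng, depth_pmut, ones, wt_idx, mut_idx, e)
    c_bmut = _read_counts_for_allele_pair(rng, depth_bmut, p_bulk_mut, wt_idx, mut_idx, e)
    c_bwt = _read_counts_for_allele_pair(rng, depth_bwt, p_bulk_wt, wt_idx, mut_idx, e)

    chrom_col = np.concatenate([np.repeat(c, len(positions[c])) for c in chroms])
    pos_col = np.concatenate([positions[c] for c in chroms])
    base_arr = np.array(BASES)
    data = {
        "chrom": chrom_col,
        "pos": pos_col,
        "allele_wt": base_arr[wt_idx],
        "allele_mut": base_arr[mut_idx],
        "multiallelic": np.zeros(n_total, dtype=bool),
    }
    for sample, mat in (
        ("parent_wt", c_pwt),
        ("parent_mut", c_pmut),
        ("bulk_mut", c_bmut),
        ("bulk_wt", c_bwt),
    ):
        for j, b in enumerate(BASES):
            data[f"{sample}_{b}"] = mat[:, j]
    genome = {c: cfg.chrom_length_bp for c in chroms}
    table = LocusTable(pd.DataFrame(data, columns=REQUIRED_COLS), genome)

    truth = TruthRecord(
        causal_chrom=cfg.causal_chrom,
        causal_pos=cfg.causal_pos_bp,
        causal_genotypes=causal_geno,
        phenotypes=fertile,
        bulk_mut_plants=bulk_mut_plants,
        bulk_wt_plants=bulk_wt_plants,
        loci=pd.DataFrame(
            {
                "chrom": chrom_col,
                "pos": pos_col,
                "f2_allele_freq": f2_freq,
                "bulk_mut_freq": p_bulk_mut,
                "bulk_wt_freq": p_bulk_wt,
            }
        ),
    )
    return table, truth


def make_filter_fixture(
    total: int,
    n_multiallelic: int,
    n_lowdepth: int,
    n_parent_absent: int,
    seed: int = 0,
    min_bulk_depth: int = 4,
) -> LocusTable:
    """Deterministic locus table with planted filter defects.

    Defect classes are disjoint and assigned in the filter chain's order:
    ``n_multiallelic`` loci are flagged multi-allelic, ``n_lowdepth`` of the
    remainder have total read support below ``min_bulk_depth`` in one bulk,
    ``n_parent_absent`` of the rest lack a usable parental polymorphism
    (missing call in one parent, or both parents homozygous for the same
    allele).  All other loci pass every filter.
    """
    for name, v in (
        ("total", total),
        ("n_multiallelic", n_multiallelic),
        ("n_lowdepth", n_lowdepth),
        ("n_parent_absent", n_parent_absent),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_multiallelic + n_lowdepth + n_parent_absent > total:
        raise ValueError("defect counts exceed total loci")

    rng = np.random.default_rng(seed)
    n_chrom = 26
    chroms = cotton_style_chrom_names(n_chrom)
    per_chrom = np.full(n_chrom, total // n_chrom)
    per_chrom[: total % n_chrom] += 1
    chrom_col = np.concatenate([np.repeat(c, k) for c, k in zip(chroms, per_chrom)])
    pos_col = np.concatenate([np.arange(1, k + 1) * 500 for k in per_chrom])

    wt_idx = rng.integers(0, 4, size=total)
    mut_idx = (wt_idx + rng.integers(1, 4, size=total)) % 4
    rows = np.arange(total)

    # clean baseline: parents homozygous for their allele, bulks well covered
    def clipped_poisson(mean: float, lo: int) -> np.ndarray:
        return np.maximum(rng.poisson(mean, total), lo)

    c_pwt = np.zeros((total, 4), dtype=np.int64)
    c_pmut = np.zeros((total, 4), dtype=np.int64)
    c_bmut = np.zeros((total, 4), dtype=np.int64)
    c_bwt = np.zeros((total, 4), dtype=np.int64)
    c_pwt[rows, wt_idx] = clipped_poisson(47.9, 1)
    c_pmut[rows, mut_idx] = clipped_poisson(47.9, 1)
    # bulks: sterile pool fixed for the mut allele, fertile pool mixed
    bmut_depth = clipped_poisson(50.78, min_bulk_depth)
    bwt_depth = clipped_poisson(50.78, min_bulk_depth)
    bwt_mut_reads = rng.binomial(bwt_depth, 2.0 / 3.0)
    c_bmut[rows, mut_idx] = bmut_depth
    c_bwt[rows, mut_idx] = bwt_mut_reads
    c_bwt[rows, wt_idx] += bwt_depth - bwt_mut_reads

    multiallelic = np.zeros(total, dtype=bool)

    order = rng.permutation(total)
    sel_multi = order[:n_multiallelic]
    sel_low = order[n_multiallelic : n_multiallelic + n_lowdepth]
    sel_absent = order[
        n_multiallelic + n_lowdepth : n_multiallelic + n_lowdepth + n_parent_absent
    ]

    # multi-allelic: flag plus a visible third allele in the fertile bulk
    multiallelic[sel_multi] = True
    all4 = np.tile(np.arange(4), (n_multiallelic, 1))
    free_mask = (all4 != wt_idx[sel_multi, None]) & (all4 != mut_idx[sel_multi, None])
    free = all4[free_mask].reshape(n_multiallelic, 2)
    extra = free[np.arange(n_multiallelic), rng.integers(0, 2, size=n_multiallelic)]
    c_bwt[sel_multi, extra] += rng.integers(5, 15, size=n_multiallelic)

    # low support: one randomly chosen bulk drops below the depth cutoff
    low_in_mut = rng.random(n_lowdepth) < 0.5
    low_counts = rng.integers(0, min_bulk_depth, size=n_lowdepth)
    for sel, mat, use in (
        (sel_low[low_in_mut], c_bmut, low_counts[low_in_mut]),
        (sel_low[~low_in_mut], c_bwt, low_counts[~low_in_mut]),
    ):
        mat[sel] = 0
        mat[sel, mut_idx[sel]] = use

    # parent-absent: half missing in one parent, half non-polymorphic
    miss = rng.random(n_parent_absent) < 0.5
    sel_miss = sel_absent[miss]
    sel_same = sel_absent[~miss]
    which_parent = rng.random(len(sel_miss)) < 0.5
    c_pwt[sel_miss[which_parent]] = 0
    c_pmut[sel_miss[~which_parent]] = 0
    c_pmut[sel_same] = 0
    c_pmut[sel_same, wt_idx[sel_same]] = clipped_poisson(47.9, 1)[sel_same]

    base_arr = np.array(BASES)
    data = {
        "chrom": chrom_col,
        "pos": pos_col,
        "allele_wt": base_arr[wt_idx],
        "allele_mut": base_arr[mut_idx],
        "multiallelic": multiallelic,
    }
    for sample, mat in (
        ("parent_wt", c_pwt),
        ("parent_mut", c_pmut),
        ("bulk_mut", c_bmut),
        ("bulk_wt", c_bwt),
    ):
        for j, b in enumerate(BASES):
            data[f"{sample}_{b}"] = mat[:, j]
    genome = {c: int(k) * 500 + 500 for c, k in zip(chroms, per_chrom)}
    return LocusTable(pd.DataFrame(data, columns=REQUIRED_COLS), genome)
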