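"""SNP-index and delta-SNP-index statistics with association thresholds.

The SNP-index of a bulk at a locus is the fraction of its reads that carry
the restorer-parent allele, counted over reads matching either parental
allele only::

    index = rho_x / (rho_X + rho_x)

where ``rho_X`` and ``rho_x`` are the read counts of the wild-parent and
mutant-parent alleles in that pool.  The delta-SNP-index is
``index(mut bulk) - index(wt bulk)``: near 0 at loci unlinked to the trait,
near its theoretical extreme at the causal locus.

Two threshold rules are provided.  For a qualitative trait in an F2 the
theoretical expectation of |delta| under perfect extreme bulking is derived
by enumerating the 1:2:1 genotype classes; for other designs a null
distribution is simulated by resampling bulks with no linkage and taking a
percentile of |delta|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .records import LocusRecord, LocusTable, BASE_INDEX

#: columns of a SNP-index scan frame
SNPINDEX_COLS = ["chrom", "pos", "index_mut", "index_wt", "delta", "depth_mut", "depth_wt"]


@dataclass(frozen=True)
class SnpIndexPoint:
    chrom: str
    pos: int
    index_mut: float
    index_wt: float
    delta: float
    depth_mut: int  # informative (parental-allele) reads in the mut bulk
    depth_wt: int


@dataclass(frozen=True)
class ThresholdSpec:
    """A cutoff plus the rule that produced it.

    ``value`` is the exact cutoff used in comparisons; ``display_value``
    rounds it to the conventional reporting precision (two decimals for the
    theoretical F2 rule).
    """

    value: float
    rule: str  # theoretical_f2 | simulated_percentile | empirical_median_3sd
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")

    @property
    def display_value(self) -> float:
        ndigits = self.params.get("report_digits", 4)
        return round(self.value, ndigits)


def snp_index_point(rec: LocusRecord) -> SnpIndexPoint | None:
    """SNP-index of both bulks and their difference at one locus.

    Reads matching neither parental allele are excluded from the
    denominator.  Returns ``None`` when a bulk has no informative reads
    (the point is absent, never fabricated as 0/0).
    """
    iw, im = BASE_INDEX[rec.allele_wt], BASE_INDEX[rec.allele_mut]
    if iw == im:
        raise ValueError(f"locus {rec.chrom}:{rec.pos} is not parent-polymorphic")
    n_mut_bulk = rec.bulk_mut_depths[im]
    d_mut = rec.bulk_mut_depths[iw] + n_mut_bulk
    n_wt_bulk = rec.bulk_wt_depths[im]
    d_wt = rec.bulk_wt_depths[iw] + n_wt_bulk
    if d_mut == 0 or d_wt == 0:
        return None
    i_mut = n_mut_bulk / d_mut
    i_wt = n_wt_bulk / d_wt
    return SnpIndexPoint(rec.chrom, rec.pos, i_mut, i_wt, i_mut - i_wt, d_mut, d_wt)


def snp_index_scan(table: LocusTable) -> pd.DataFrame:
    """Vectorised SNP-index scan over a filtered locus table.

    Returns a frame with :data:`SNPINDEX_COLS`; loci where either bulk has
    zero informative reads are omitted.
    """
    n_mut_in_mut = table.allele_counts("bulk_mut", "mut").astype(float)
    d_mut = n_mut_in_mut + table.allele_counts("bulk_mut", "wt")
    n_mut_in_wt = table.allele_counts("bulk_wt", "mut").astype(float)
    d_wt = n_mut_in_wt + table.allele_counts("bulk_wt", "wt")
    ok = (d_mut > 0) & (d_wt > 0)
    idx_mut = n_mut_in_mut[ok] / d_mut[ok]
    idx_wt = n_mut_in_wt[ok] / d_wt[ok]
    return pd.DataFrame(
        {
            "chrom": table.df["chrom"].to_numpy()[ok],
            "pos": table.df["pos"].to_numpy()[ok],
            "index_mut": idx_mut,
            "index_wt": idx_wt,
            "delta": idx_mut - idx_wt,
            "depth_mut": d_mut[ok].astype(np.int64),
            "depth_wt": d_wt[ok].astype(np.int64),
        }
    )


def expected_f2_bulk_fractions(dominant: bool = True) -> tuple[Fraction, Fraction]:
    """Expected restorer-allele fraction in each extreme bulk of an F2.

    Enumerates the 1:2:1 RR:Rr:rr genotype classes of an F2 with a dominant
    allele R, conditions one bulk on the recessive phenotype (rr only) and
    the other on the dominant phenotype (RR:Rr at 1:2), and averages the
    per-plant allele dosage.  Exact rational arithmetic.
    """
    if not dominant:
        raise NotImplementedError(
            "only the dominant single-locus F2 design has a theoretical "
            "threshold; use simulated_threshold for other designs"
        )
    classes = [(2, Fraction(1, 4)), (1, Fraction(2, 4)), (0, Fraction(1, 4))]
    rec = [(g, w) for g, w in classes if g == 0]
    dom = [(g, w) for g, w in classes if g >= 1]
    frac_rec = sum(w * Fraction(g, 2) for g, w in rec) / sum(w for _, w in rec)
    frac_dom = sum(w * Fraction(g, 2) for g, w in dom) / sum(w for _, w in dom)
    return frac_rec, frac_dom


def theoretical_threshold_f2(dominant: bool = True) -> ThresholdSpec:
    """Theoretical |delta-SNP-index| cutoff for an F2 with extreme bulks.

    Under perfect bulking the recessive-phenotype bulk carries the restorer
    allele at frequency 0 and the dominant-phenotype bulk at 2/3, so the
    expected |delta| is 2/3 — conventionally reported as 0.67.
    """
    frac_rec, frac_dom = expected_f2_bulk_fractions(dominant)
    value = abs(frac_dom - frac_rec)
    return ThresholdSpec(
        value=float(value),
        rule="theoretical_f2",
        params={
            "design": "F2 extreme bulks, single dominant locus",
            "bulk_fractions": (float(frac_rec), float(frac_dom)),
            "report_digits": 2,
        },
    )


def simulated_threshold(
    depths: np.ndarray | list[tuple[int, int]],
    bulk_size: int,
    percentile: float = 0.95,
    n_rep: int = 10_000,
    seed: int = 0,
) -> ThresholdSpec:
    """Null |delta-SNP-index| percentile by resampling unlinked bulks.

    Under no linkage both bulks sample ``2*bulk_size`` chromosomes from an
    F2 allele frequency of 1/2, then reads are drawn binomially at the
    observed per-locus depth pairs.  ``depths`` is an (n, 2) array of
    informative-read depths (mut bulk, wt bulk) from the real scan; each
    replicate reuses one observed pair (cycled).  The threshold is the
    requested percentile of |delta| over ``n_rep`` replicates.
    """
    depths = np.asarray(depths, dtype=np.int64)
    if depths.ndim != 2 or depths.shape[1] != 2 or len(depths) == 0:
        raise ValueError("depths must be a non-empty (n, 2) array")
    if not (0 < percentile < 1):
        raise ValueError("percentile must be in (0, 1)")
    if n_rep < 1000:
        raise ValueError("n_rep must be at least 1000")
    rng = np.random.default_rng(seed)
    pairs = depths[np.arange(n_rep) % len(depths)]
    two_b = 2 * bulk_size
    deltas = np.empty(n_rep)
    p1 = rng.binomial(two_b, 0.5, n_rep) / two_b
    p2 = rng.binomial(two_b, 0.5, n_rep) / two_b
    k1 = rng.binomial(pairs[:, 0], p1)
    k2 = rng.binomial(pairs[:, 1], p2)
    with np.errstate(invalid="ignore"):
        deltas = k1 / pairs[:, 0] - k2 / pairs[:, 1]
    deltas = deltas[np.isfinite(deltas)]
    value = float(np.quantile(np.abs(deltas), percentile))
    return ThresholdSpec(
        value=value,
        rule="simulated_percentile",
        params={
            "bulk_size": bulk_size,
            "percentile": percentile,
            "n_rep": n_rep,
            "seed": seed,
        },
    )
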