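"""Euclidean-distance (ED) statistic between the two bulks' base frequencies.

At each locus the two pools are summarised by their four-base read-frequency
vectors (A, C, G, T fractions, summing to 1).  The ED statistic is the
Euclidean distance between those vectors::

    ED = sqrt((A_mut-A_wt)^2 + (C_mut-C_wt)^2 + (G_mut-G_wt)^2 + (T_mut-T_wt)^2)

It is 0 when the pools are identical and sqrt(2) when they are fixed for
different bases.  Because sequencing noise gives every locus a small nonzero
ED, the raw value is raised to a power (default 5) before fitting — a
background-suppression transform that leaves the locus ranking unchanged but
collapses noise-level values toward zero.  The genome-wide association cutoff
is empirical: median + 3 standard deviations of the fitted track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import LocusRecord, LocusTable
from .snpindex import ThresholdSpec

#: default background-suppression exponent
DEFAULT_ED_POWER = 5

ED_COLS = ["chrom", "pos", "ed_raw", "ed_powered"]


@dataclass(frozen=True)
class EdPoint:
    chrom: str
    pos: int
    freq_mut: tuple[float, float, float, float]
    freq_wt: tuple[float, float, float, float]
    ed_raw: float
    ed_powered: float
    power: float


def ed_point(rec: LocusRecord, power: float = DEFAULT_ED_POWER) -> EdPoint | None:
    """ED of one locus; ``None`` when either bulk has zero total depth.

    Frequencies are computed over all four base counts — error-base reads
    included — since the statistic is defined on the full base composition.
    """
    d_mut = sum(rec.bulk_mut_depths)
    d_wt = sum(rec.bulk_wt_depths)
    if d_mut == 0 or d_wt == 0:
        return None
    f_mut = tuple(c / d_mut for c in rec.bulk_mut_depths)
    f_wt = tuple(c / d_wt for c in rec.bulk_wt_depths)
    ed = float(np.sqrt(sum((a - b) ** 2 for a, b in zip(f_mut, f_wt))))
    return EdPoint(rec.chrom, rec.pos, f_mut, f_wt, ed, ed**power, power)


def ed_scan(table: LocusTable, power: float = DEFAULT_ED_POWER) -> pd.DataFrame:
    """Vectorised ED scan; loci with a zero-depth bulk are omitted."""
    c_mut = table.counts("bulk_mut").astype(float)
    c_wt = table.counts("bulk_wt").astype(float)
    d_mut = c_mut.sum(axis=1)
    d_wt = c_wt.sum(axis=1)
    ok = (d_mut > 0) & (d_wt > 0)
    f_mut = c_mut[ok] / d_mut[ok, None]
    f_wt = c_wt[ok] / d_wt[ok, None]
    ed = np.sqrt(((f_mut - f_wt) ** 2).sum(axis=1))
    return pd.DataFrame(
        {
            "chrom": table.df["chrom"].to_numpy()[ok],
            "pos": table.df["pos"].to_numpy()[ok],
            "ed_raw": ed,
            "ed_powered": ed**power,
        }
    )


def ed_threshold(fitted_values: np.ndarray | pd.Series) -> ThresholdSpec:
    """Empirical cutoff: median + 3 x sample SD of the fitted ED track.

    The SD uses the n-1 denominator.  Applied to the fitted (position-
    smoothed) values of all loci, matching how the genome-wide cutoff is set
    for this statistic.
    """
    v = np.asarray(fitted_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("fitted track is empty")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ThresholdSpec(
        value=float(np.median(v)) + 3.0 * sd,
        rule="empirical_median_3sd",
        params={"n": int(v.size), "median": float(np.median(v)), "sd": sd, "sd_ddof": 1},
    )
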