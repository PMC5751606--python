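"""Position smoothing, threshold-exceeding region extraction and intersection.

Per-locus scan statistics are noisy; to suppress single-locus false
positives each statistic is fitted along the chromosome with a sliding-
window mean (default 1 Mb window, 10 kb step) before thresholding.  Maximal
runs of above-threshold evaluation points become candidate regions; the two
methods' region sets are intersected to give the final answer, and gene
models can be attached to count genes per region.

Coordinates are 1-based inclusive; region size is reported as
``(end - start) / 1e6`` Mb rounded to two decimals (the convention used for
printed association-region tables, e.g. 39,558,551–40,416,294 -> 0.86 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .snpindex import ThresholdSpec

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_STEP_BP = 10_000


@dataclass(frozen=True)
class FittedTrack:
    """Sliding-window mean of a per-locus statistic along one chromosome."""

    chrom: str
    positions: np.ndarray  # evaluation points (bp), strictly increasing
    values: np.ndarray  # fitted statistic at each point
    window_bp: int
    step_bp: int
    statistic: str  # "delta_snp_index" | "ed"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values differ in length")


@dataclass(frozen=True)
class CandidateRegion:
    """A genomic interval whose fitted statistic exceeds its threshold."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    methods: frozenset[str] = field(default_factory=frozenset)
    n_genes: int | None = None
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def size_mb(self) -> float:
        return round((self.end - self.start) / 1e6, 2)


def fit_track(
    positions: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    chrom: str = "",
    statistic: str = "",
) -> FittedTrack:
    """Sliding-window mean of one chromosome's statistic.

    Evaluation points are multiples of ``step_bp`` spanning the observed
    positions; each point averages the raw values whose positions fall in
    ``[center - window_bp/2, center + window_bp/2]``.  Windows containing no
    loci are absent from the track, never reported as zero.
    """
    if not (0 < step_bp <= window_bp):
        raise ValueError("require window_bp >= step_bp > 0")
    pos = np.asarray(positions, dtype=np.int64)
    val = np.asarray(values, dtype=float)
    if len(pos) == 0:
        return FittedTrack(chrom, pos, val, window_bp, step_bp, statistic)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    lo = max((int(pos[0]) // step_bp) * step_bp, 0)
    centers = np.arange(lo, int(pos[-1]) + step_bp, step_bp, dtype=np.int64)
    half = window_bp / 2.0
    left = np.searchsorted(pos, centers - half, side="left")
    right = np.searchsorted(pos, centers + half, side="right")
    counts = right - left
    csum = np.concatenate([[0.0], np.cumsum(val)])
    keep = counts > 0
    means = (csum[right[keep]] - csum[left[keep]]) / counts[keep]
    return FittedTrack(chrom, centers[keep], means, window_bp, step_bp, statistic)


def fit_scan(
    scan: pd.DataFrame,
    value_col: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    statistic: str = "",
) -> list[FittedTrack]:
    """Fit every chromosome of a scan frame (chrom, pos, ``value_col``)."""
    tracks = []
    for chrom in scan["chrom"].unique():
        sub = scan[scan["chrom"] == chrom]
        tracks.append(
            fit_track(
                sub["pos"].to_numpy(),
                sub[value_col].to_numpy(),
                window_bp,
                step_bp,
                chrom=str(chrom),
                statistic=statistic,
            )
        )
    return tracks


def call_regions(
    tracks: FittedTrack | Iterable[FittedTrack],
    thr: ThresholdSpec,
    merge_gap_bp: int = 0,
    method: str | None = None,
    use_abs: bool = False,
) -> list[CandidateRegion]:
    """Extract maximal above-threshold runs from fitted tracks.

    A run is a maximal stretch of grid-adjacent evaluation points whose
    fitted value (absolute value when ``use_abs``) is >= ``thr.value``;
    runs on the same chromosome closer than ``merge_gap_bp`` are merged.
    Region bounds are the outermost qualifying evaluation points.
    """
    if isinstance(tracks, FittedTrack):
        tracks = [tracks]
    regions: list[CandidateRegion] = []
    for track in tracks:
        if method is None and not track.statistic:
            raise ValueError("track has no statistic label and no method given")
        name = method or track.statistic
        vals = np.abs(track.values) if use_abs else track.values
        above = vals >= thr.value
        runs: list[tuple[int, int]] = []
        start = prev = None
        for p, ok in zip(track.positions, above):
            if ok:
                if start is None:
                    start = prev = int(p)
                elif int(p) - prev == track.step_bp:
                    prev = int(p)
                else:  # grid gap (empty windows) breaks the run
                    runs.append((start, prev))
                    start = prev = int(p)
            elif start is not None:
                runs.append((start, prev))
                start = None
        if start is not None:
            runs.append((start, prev))
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_gap_bp:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        regions.extend(
            CandidateRegion(track.chrom, s, e, frozenset({name})) for s, e in merged
        )
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def intersect_methods(
    a: Iterable[CandidateRegion], b: Iterable[CandidateRegion]
) -> list[CandidateRegion]:
    """Interval intersection of two region sets (as point sets, per chrom).

    Each output interval carries the union of its parents' method labels;
    sizes are recomputed from the new bounds.
    """
    out: list[CandidateRegion] = []
    b_by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in b:
        b_by_chrom.setdefault(r.chrom, []).append(r)
    for ra in a:
        for rb in b_by_chrom.get(ra.chrom, ()):
            s, e = max(ra.start, rb.start), min(ra.end, rb.end)
            if s <= e:
                out.append(CandidateRegion(ra.chrom, s, e, ra.methods | rb.methods))
    return sorted(out, key=lambda r: (r.chrom, r.start))


def attach_genes(
    regions: Iterable[CandidateRegion],
    genes: Iterable,
    contained: bool = False,
) -> list[CandidateRegion]:
    """Count and list the genes overlapping each region.

    ``genes`` are objects with ``gene_id``, ``chrom``, ``start``, ``end``
    (1-based inclusive span).  A gene counts when it overlaps the region by
    at least 1 bp, or — with ``contained`` — only when it lies wholly
    inside.  A region on a chromosome with no gene models gets a warning
    and zero genes.
    """
    genes = list(genes)
    gene_chroms = {g.chrom for g in genes}
    out = []
    for r in regions:
        if r.chrom not in gene_chroms:
            log.warning("no gene models on %s; region %s:%d-%d gets 0 genes",
                        r.chrom, r.chrom, r.start, r.end)
            out.append(replace(r, n_genes=0, gene_ids=()))
            continue
        if contained:
            hits = [g for g in genes
                    if g.chrom == r.chrom and g.start >= r.start and g.end <= r.end]
        else:
            hits = [g for g in genes
                    if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start]
        out.append(replace(r, n_genes=len(hits), gene_ids=tuple(g.gene_id for g in hits)))
    return out


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    """Association-region table: id, chrom, start, end, size (Mb), genes."""
    return pd.DataFrame(
        {
            "region": [_roman(i + 1) for i in range(len(regions))],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "size_mb": [f"{r.size_mb:.2f}" for r in regions],
            "methods": ["+".join(sorted(r.methods)) for r in regions],
            "n_genes": [r.n_genes if r.n_genes is not None else "" for r in regions],
        }
    )


def write_regions_tsv(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """BED output: 0-based half-open, so start-1 .. end."""
    with open(path, "w") as fh:
        for r in regions:
            name = "+".join(sorted(r.methods)) or "region"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, s in vals:
        while n >= v:
            out += s
            n -= v
    return out
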