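"""Sliding-window fitting, region extraction, intersection, gene overlap."""

import numpy as np
import pytest

from bsascan import CandidateRegion, GeneModel, attach_genes, call_regions, fit_track
from bsascan.regions import FittedTrack, intersect_methods, regions_to_frame
from bsascan.snpindex import ThresholdSpec

THR = lambda v: ThresholdSpec(v, "theoretical_f2")


def _track(positions, values, step=10_000, statistic="ed"):
    return FittedTrack("chr01", np.asarray(positions), np.asarray(values),
                       window_bp=step * 10, step_bp=step, statistic=statistic)


# --- fitting ---------------------------------------------------------------

def test_constant_statistic_fits_to_constant():
    pos = np.arange(1, 5_000_001, 100_000)
    t = fit_track(pos, np.full(pos.size, 0.42), 1_000_000, 10_000)
    assert np.allclose(t.values, 0.42)


def test_single_locus_windows_reproduce_raw_value():
    t = fit_track([2_000_000], [0.8], 1_000_000, 10_000)
    assert np.allclose(t.values, 0.8)
    assert t.positions.min() >= 2_000_000 - 500_000
    assert t.positions.max() <= 2_000_000 + 500_000


def test_one_window_mean_matches_brute_force(rng):
    pos = np.sort(rng.integers(1, 900_000, 50))
    val = rng.random(50)
    t = fit_track(pos, val, window_bp=2_000_000, step_bp=2_000_000)
    # a single evaluation point covering everything: plain arithmetic mean
    center_cover = np.abs(pos - t.positions[0]) <= 1_000_000
    assert center_cover.all()
    assert t.values[0] == pytest.approx(val.mean())


def test_fitted_values_stay_within_raw_range(rng):
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), 200, replace=False))
    val = rng.random(200)
    t = fit_track(pos, val, 1_000_000, 50_000)
    assert t.values.min() >= val.min() - 1e-12
    assert t.values.max() <= val.max() + 1e-12


def test_empty_windows_are_absent_not_zero():
    # two clusters 10 Mb apart: no evaluation points in the gap
    pos = np.r_[np.arange(1_000_000, 1_100_000, 10_000),
                np.arange(11_000_000, 11_100_000, 10_000)]
    t = fit_track(pos, np.ones(pos.size), window_bp=200_000, step_bp=10_000)
    in_gap = (t.positions > 1_300_000) & (t.positions < 10_800_000)
    assert not in_gap.any()
    assert np.allclose(t.values, 1.0)


def test_unsorted_positions_rejected():
    with pytest.raises(ValueError, match="sorted"):
        fit_track([200, 100], [1.0, 1.0], 1000, 100)
    with pytest.raises(ValueError):
        fit_track([100], [1.0], window_bp=100, step_bp=200)


# --- region calling --------------------------------------------------------

def test_all_below_threshold_yields_no_regions():
    t = _track(np.arange(10_000, 110_000, 10_000), np.full(10, 0.1))
    assert call_regions(t, THR(0.5)) == []


def test_single_exceedance_run_bounds_match_brute_force():
    pos = np.arange(10_000, 210_000, 10_000)
    val = np.where((pos >= 60_000) & (pos <= 120_000), 0.9, 0.1)
    regions = call_regions(_track(pos, val), THR(0.5))
    above = pos[val >= 0.5]
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (above.min(), above.max())


def test_nearby_runs_merge_under_gap_rule():
    pos = np.arange(10_000, 310_000, 10_000)
    val = np.where((pos <= 50_000) | (pos >= 120_000), 0.9, 0.1)
    split = call_regions(_track(pos, val), THR(0.5), merge_gap_bp=0)
    merged = call_regions(_track(pos, val), THR(0.5), merge_gap_bp=100_000)
    assert [(r.start, r.end) for r in split] == [(10_000, 50_000), (120_000, 300_000)]
    assert [(r.start, r.end) for r in merged] == [(10_000, 300_000)]


def test_negative_peaks_found_with_absolute_value():
    pos = np.arange(10_000, 110_000, 10_000)
    val = np.where(pos >= 60_000, -0.8, 0.0)
    assert call_regions(_track(pos, val), THR(0.5)) == []
    got = call_regions(_track(pos, val), THR(0.5), use_abs=True)
    assert [(r.start, r.end) for r in got] == [(60_000, 100_000)]


def test_called_regions_are_disjoint_and_sorted(rng):
    pos = np.arange(10_000, 2_010_000, 10_000)
    val = rng.random(pos.size)
    regions = call_regions(_track(pos, val), THR(0.7))
    for a, b in zip(regions, regions[1:]):
        assert a.end < b.start


# --- intersection ----------------------------------------------------------

def _regions(intervals, method="snp_index"):
    return [CandidateRegion("chrD05", s, e, frozenset({method}))
            for s, e in intervals]


def test_self_intersection_of_published_style_intervals():
    intervals = [(37_535_705, 37_755_211), (39_558_551, 40_416_294),
                 (40_531_406, 40_804_095)]
    inter = intersect_methods(_regions(intervals), _regions(intervals, "ed"))
    assert [(r.start, r.end) for r in inter] == intervals
    assert [r.size_mb for r in inter] == [0.22, 0.86, 0.27]
    assert sum(r.size_mb for r in inter) == pytest.approx(1.35)
    assert all(r.methods == {"snp_index", "ed"} for r in inter)


def test_disjoint_sets_intersect_to_empty():
    assert intersect_methods(_regions([(100, 200)]), _regions([(300, 400)])) == []


def test_intersection_matches_brute_force_overlap(rng):
    def random_set(method):
        starts = np.sort(rng.choice(np.arange(1, 10_000_000, 1000), 8, replace=False))
        return [CandidateRegion("chrD05", int(s), int(s + rng.integers(1000, 800_000)),
                                frozenset({method})) for s in starts]

    a, b = random_set("snp_index"), random_set("ed")
    got = {(r.start, r.end) for r in intersect_methods(a, b)}
    expected = set()
    for ra in a:
        for rb in b:
            s, e = max(ra.start, rb.start), min(ra.end, rb.end)
            if s <= e:
                expected.add((s, e))
    assert got == expected
    # point-set containment in both inputs
    for r in intersect_methods(a, b):
        assert any(x.start <= r.start and r.end <= x.end for x in a)
        assert any(x.start <= r.start and r.end <= x.end for x in b)


def test_size_reported_as_span_over_megabase():
    r = CandidateRegion("chrD05", 39_558_551, 40_416_294)
    assert r.size_mb == 0.86  # 857,743 bp span
    assert "0.86" in regions_to_frame([r]).size_mb.iloc[0]


# --- genes -----------------------------------------------------------------

def _gene(gene_id, start, end, chrom="chrD05"):
    return GeneModel(gene_id, chrom, "+", ((start, end),))


def test_gene_overlap_counting_and_boundaries():
    region = CandidateRegion("chrD05", 1000, 2000, frozenset({"snp_index"}))
    genes = [
        _gene("inside", 1200, 1800),
        _gene("straddles", 900, 1100),
        _gene("abuts_end_plus_one", 2001, 2500),  # 1-based inclusive: no overlap
        _gene("other_chrom", 1200, 1800, chrom="chrA01"),
    ]
    (out,) = attach_genes([region], genes)
    assert out.n_genes == 2
    assert set(out.gene_ids) == {"inside", "straddles"}
    (contained,) = attach_genes([region], genes, contained=True)
    assert contained.gene_ids == ("inside",)


def test_gene_counts_match_brute_force(rng):
    regions = [CandidateRegion("chrD05", int(s), int(s) + 50_000)
               for s in range(1, 1_000_000, 200_000)]
    genes = [_gene(f"g{i}", int(s), int(s + rng.integers(100, 40_000)))
             for i, s in enumerate(rng.choice(np.arange(1, 1_000_000), 60, replace=False))]
    for r in attach_genes(regions, genes):
        expected = sum(1 for g in genes if g.start <= r.end and g.end >= r.start)
        assert r.n_genes == expected


def test_region_on_geneless_chromosome_warns_and_gets_zero(caplog):
    region = CandidateRegion("chrA01", 10, 20)
    with caplog.at_level("WARNING"):
        (out,) = attach_genes([region], [_gene("g", 1, 5)])
    assert out.n_genes == 0
    assert "chrA01" in caplog.text
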