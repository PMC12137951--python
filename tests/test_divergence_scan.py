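"""Weir-Cockerham F_ST, thresholds, region building, tiers, gene overlap."""

import math

import numpy as np
import pytest

from popscan.divergence_scan import (
    Contrast,
    OutlierRegion,
    build_outlier_regions,
    check_locus_overlap,
    cross_compare,
    intersect_genes,
    parse_locus,
    quantile_thresholds,
    wc_fst_components,
    wc_fst_site,
    windowed_fst,
)
from popscan.diversity_stats import WindowStat
from popscan.io_formats import MISSING, GeneFeature, GenomicInterval

from conftest import gt, make_dataset


# ---------------------------------------------------------------------------
# Independent literal transcription of the 1984 two-population estimator
# ---------------------------------------------------------------------------

def _wc_oracle(column, idx1, idx2):
    """Scalar, loop-based transcription of the variance components."""
    def group(idx):
        n = p_sum = het = 0
        for i in idx:
            a, b = column[i]
            if a == MISSING or b == MISSING:
                continue
            n += 1
            p_sum += int(a == 1) + int(b == 1)
            het += int(a != b)
        if n == 0:
            return 0, 0.0, 0.0
        return n, p_sum / (2 * n), het / n

    n1, p1, h1 = group(idx1)
    n2, p2, h2 = group(idx2)
    if n1 == 0 or n2 == 0:
        return 0.0, 0.0, 0.0
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def test_fixed_difference_gives_theta_one():
    column = np.array(gt(*(["0/0"] * 5 + ["1/1"] * 5)))
    a, b, c = wc_fst_site(column, range(5), range(5, 10))
    assert a == pytest.approx(0.5)
    assert b == pytest.approx(0.0) and c == pytest.approx(0.0)
    assert a / (a + b + c) == pytest.approx(1.0)


def test_monomorphic_site_has_zero_components():
    column = np.array(gt(*(["1/1"] * 10)))
    assert wc_fst_site(column, range(5), range(5, 10)) == (0.0, 0.0, 0.0)


def test_components_match_literal_transcription_on_random_columns(rng):
    """Vectorised components equal the loop-based oracle, 100 random columns."""
    for _ in range(100):
        n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        col = rng.integers(0, 2, size=(n1 + n2, 2)).astype(np.int16)
        if rng.random() < 0.3:
            col[rng.integers(0, n1 + n2)] = -1
        a, b, c = wc_fst_site(col, range(n1), range(n1, n1 + n2))
        ea, eb, ec = _wc_oracle(col, range(n1), range(n1, n1 + n2))
        assert a == pytest.approx(ea, abs=1e-12)
        assert b == pytest.approx(eb, abs=1e-12)
        assert c == pytest.approx(ec, abs=1e-12)


def test_windowed_fst_weighted_equals_component_sums(rng):
    g = rng.integers(0, 2, size=(60, 10, 2)).astype(np.int16)
    pos = np.sort(rng.choice(150_000, 60, replace=False)) + 1
    ds = make_dataset(g, pos=pos, chrom_lengths={"chr1": 150_000})
    con = Contrast("c", tuple(ds.samples[:5]), tuple(ds.samples[5:]))
    comp = wc_fst_components(ds, con)
    for w in windowed_fst(ds, con):
        in_win = (ds.pos >= w.interval.start) & (ds.pos <= w.interval.end)
        denom = comp.a + comp.b + comp.c
        usable = in_win & (denom > 0)
        if not usable.any():
            assert math.isnan(w.fst)
        else:
            assert w.fst == pytest.approx(comp.a[usable].sum() / denom[usable].sum())


def test_windowed_fst_fixed_difference_window_is_one():
    sites = [gt(*(["0/0"] * 4 + ["1/1"] * 4)) for _ in range(5)]
    ds = make_dataset(sites, chrom_lengths={"chr1": 50_000})
    con = Contrast("c", ("s0", "s1", "s2", "s3"), ("s4", "s5", "s6", "s7"))
    w = windowed_fst(ds, con, window=50_000, step=50_000)
    assert w[0].fst == pytest.approx(1.0)


def test_windowed_fst_unknown_samples_rejected():
    ds = make_dataset([gt("0/0", "1/1", "0/1", "0/0")])
    con = Contrast("c", ("s0", "ghost"), ("s2", "s3"))
    with pytest.raises(KeyError, match="ghost"):
        windowed_fst(ds, con)


# ---------------------------------------------------------------------------
# Quantile thresholds
# ---------------------------------------------------------------------------

def _windows_from_values(values):
    return [
        WindowStat(GenomicInterval("chr1", i * 100 + 1, i * 100 + 100), fst=v)
        for i, v in enumerate(values)
    ]


def test_quantile_thresholds_top1_and_top5_of_1_to_100():
    w = _windows_from_values(list(range(1, 101)))
    tops = quantile_thresholds(w)
    assert tops[0.99].threshold == 99 and tops[0.99].members == {99}
    assert tops[0.95].threshold == 95 and tops[0.95].members == {95, 96, 97, 98, 99}


def test_quantile_thresholds_constant_values_empty_set():
    w = _windows_from_values([0.3] * 50)
    tops = quantile_thresholds(w, levels=(0.99,))
    assert tops[0.99].members == set()
    assert tops[0.99].threshold == pytest.approx(0.3)


def test_quantile_thresholds_ties_included():
    w = _windows_from_values([1.0] * 5 + [0.1] * 95)
    tops = quantile_thresholds(w, levels=(0.99,))
    # ceil(0.01*100)=1 but all five tied top values are included
    assert tops[0.99].members == {0, 1, 2, 3, 4}
    assert tops[0.99].threshold == pytest.approx(0.1)


def test_quantile_thresholds_requires_20_windows():
    with pytest.raises(ValueError, match="20"):
        quantile_thresholds(_windows_from_values([0.1] * 10))


# ---------------------------------------------------------------------------
# Region building
# ---------------------------------------------------------------------------

def _grid(chrom="chr1", n=5, window=100_000, step=50_000, fst=0.1):
    out = []
    for i in range(n):
        start = 1 + i * step
        out.append(WindowStat(GenomicInterval(chrom, start, start + window - 1), fst=fst))
    return out


def test_seed_extends_through_top5_flanks():
    # windows 1-100k, 50k-150k, 100k-200k; middle is top1, all top5
    w = _grid(n=3)
    regions = build_outlier_regions(w, top1={1}, top5={0, 1, 2})
    assert len(regions) == 1
    assert (regions[0].interval.start, regions[0].interval.end) == (1, 200_000)
    assert regions[0].seed_windows == [1]
    assert regions[0].flank_windows == [0, 2]


def test_isolated_seed_stays_alone():
    w = _grid(n=3)
    regions = build_outlier_regions(w, top1={1}, top5={1})
    assert len(regions) == 1
    assert (regions[0].interval.start, regions[0].interval.end) == (50_001, 150_000)


def test_two_seeds_with_touching_flanks_merge():
    w = _grid(n=5)
    regions = build_outlier_regions(w, top1={0, 4}, top5={0, 1, 3, 4})
    # seeds 0 and 4 both extend into overlapping flanks 1 and 3 -> one region
    assert len(regions) == 1
    assert regions[0].seed_windows == [0, 4]


def test_region_construction_invariant_to_window_order(rng):
    w = _grid(n=8)
    top1, top5 = {2, 6}, {1, 2, 3, 5, 6}
    expected = build_outlier_regions(w, top1, top5)
    perm = list(rng.permutation(8))
    remap = {old: new for new, old in enumerate(perm)}
    shuffled = [w[i] for i in perm]
    got = build_outlier_regions(
        shuffled, {remap[i] for i in top1}, {remap[i] for i in top5}
    )
    assert [(r.interval.start, r.interval.end) for r in got] == [
        (r.interval.start, r.interval.end) for r in expected
    ]


# ---------------------------------------------------------------------------
# Cross-contrast tiers
# ---------------------------------------------------------------------------

def _region(windows, members, top1, contrast):
    iv = windows[members[0]].interval
    for m in members[1:]:
        iv = iv.union(windows[m].interval)
    return OutlierRegion(
        interval=iv,
        seed_windows=[m for m in members if m in top1],
        flank_windows=[m for m in members if m not in top1],
        max_fst=0.9,
        contrast=contrast,
    )


def _tops(top1, top5):
    from popscan.divergence_scan import QuantileSet

    return {
        0.99: QuantileSet(0.99, 0.0, set(top1)),
        0.95: QuantileSet(0.95, 0.0, set(top5)),
    }


def test_same_top1_window_in_both_contrasts_is_tier1():
    w = _grid(n=3)
    ra = [_region(w, [1], {1}, "A")]
    rb = [_region(w, [1], {1}, "B")]
    tiered = cross_compare(ra, rb, w, w, _tops({1}, {1}), _tops({1}, {1}))
    assert [t.tier for t in tiered] == [1]


def test_top1_overlapping_other_contrasts_top5_flank_is_tier2():
    w = _grid(n=3)
    ra = [_region(w, [0], {0}, "A")]  # top1 window 0 of A: 1-100k
    rb = [_region(w, [2, 1], {2}, "B")]  # B seed at 100k-200k with flank 50k-150k
    tiered = cross_compare(
        ra, rb, w, w, _tops({0}, {0}), _tops({2}, {1, 2})
    )
    # overlap 50,001-100,000 holds A's top1 window and only B's top5 flank
    assert [t.tier for t in tiered if t.tier] == [2]


def test_flank_only_overlap_is_tier3():
    w = _grid(n=5)
    ra = [_region(w, [0, 1], {0}, "A")]  # seed 0, flank 1 (50k-150k)
    rb = [_region(w, [4, 3, 2], {4}, "B")]  # seed 4 with flanks down to 100k-200k
    tiered = cross_compare(
        ra, rb, w, w, _tops({0}, {0, 1}), _tops({4}, {2, 3, 4})
    )
    # overlap 100,001-150,000 touches only flank windows of both contrasts
    assert [t.tier for t in tiered if t.tier] == [3]


def test_non_overlapping_regions_reported_untiered():
    w = _grid(n=3) + _grid(chrom="chr2", n=3)
    ra = [_region(w, [0], {0}, "A")]
    rb = [_region(w, [5], {5}, "B")]
    tiered = cross_compare(ra, rb, w, w, _tops({0}, {0}), _tops({5}, {5}))
    assert [t.tier for t in tiered] == [None, None]


# ---------------------------------------------------------------------------
# Gene intersection and locus check
# ---------------------------------------------------------------------------

def _simple_region(chrom, start, end):
    return OutlierRegion(interval=GenomicInterval(chrom, start, end))


def test_gene_region_overlap_inclusive_boundary():
    genes = [
        GeneFeature("chr1", 100, 200, "+", "hit"),
        GeneFeature("chr1", 201, 300, "+", "miss"),
    ]
    region = _simple_region("chr1", 150, 200)
    intersect_genes([region], genes)
    assert [g.gene_id for g in region.genes] == ["hit"]


def test_gene_intersection_matches_brute_force(rng):
    genes = [
        GeneFeature("chr1", int(s), int(s + rng.integers(50, 500)), "+", f"g{i}")
        for i, s in enumerate(rng.integers(1, 100_000, 60))
    ]
    regions = [
        _simple_region("chr1", int(s), int(s + rng.integers(100, 2000)))
        for s in rng.integers(1, 100_000, 25)
    ]
    intersect_genes(regions, genes)
    for reg in regions:
        expected = {
            g.gene_id
            for g in genes
            if g.start <= reg.interval.end and reg.interval.start <= g.end
        }
        assert {g.gene_id for g in reg.genes} == expected


def test_locus_overlap_check():
    locus = parse_locus("chr7:18,230,603-18,249,975")
    elsewhere = [_simple_region("chr7", 1_000_000, 1_200_000),
                 _simple_region("chr2", 18_230_603, 18_249_975)]
    hit, _ = check_locus_overlap(elsewhere, locus)
    assert hit is False
    containing = [_simple_region("chr7", 18_000_000, 18_300_000)]
    assert check_locus_overlap(containing, locus)[0] is True
    abutting = [_simple_region("chr7", 18_249_976, 18_300_000)]
    assert check_locus_overlap(abutting, locus)[0] is False


def test_contrast_validation():
    with pytest.raises(ValueError, match="overlap"):
        Contrast("c", ("a", "b"), ("b", "c"))
    with pytest.raises(ValueError, match=">= 2"):
        Contrast("c", ("a",), ("b", "c"))
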