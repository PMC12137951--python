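"""Site filters, MAF, dosage r^2 and LD pruning against brute-force oracles."""

import numpy as np
import pytest

from popscan.io_formats import MISSING
from popscan.synthetic_data import SimConfig, simulate
from popscan.variant_filtering import (
    FilterParams,
    LdParams,
    compute_maf,
    filter_sites,
    genotype_r2,
    ld_prune,
)

from conftest import gt, make_dataset


# ---------------------------------------------------------------------------
# compute_maf
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "calls,expected",
    [
        (gt("0/0", "0/1", "1/1"), 0.5),
        (gt("0/0", "0/0", "0/1"), 1 / 6),
        (gt("0/0", "./.", "1/1"), 0.5),  # missing alleles excluded
        (gt("0/0", "0/0"), 0.0),
    ],
)
def test_compute_maf(calls, expected):
    assert compute_maf(np.array(calls)) == pytest.approx(expected)


def test_compute_maf_all_missing_is_nan():
    assert np.isnan(compute_maf(np.array(gt("./.", "./."))))


# ---------------------------------------------------------------------------
# filter_sites
# ---------------------------------------------------------------------------

def _ten_sample_site(n_missing, het=2):
    calls = ["./."] * n_missing + ["0/1"] * het + ["0/0"] * (10 - n_missing - het)
    return gt(*calls)


def test_missingness_boundary_strictly_more_than_three():
    ds = make_dataset([_ten_sample_site(4), _ten_sample_site(3)])
    out, rep = filter_sites(ds, FilterParams(min_qual=None, min_depth=None))
    assert out.n_sites == 1 and rep.removed["missing"] == 1
    assert out.pos[0] == ds.pos[1]


def test_maf_boundary_exactly_at_threshold_is_retained():
    # 10 samples, alt count 1 of 20 alleles -> MAF exactly 0.05
    at = gt(*(["0/1"] + ["0/0"] * 9))
    below = gt(*(["0/0"] * 10))  # monomorphic, MAF 0
    ds = make_dataset([at, below])
    out, rep = filter_sites(ds, FilterParams(min_qual=None, min_depth=None))
    assert out.n_sites == 1 and rep.removed["maf"] == 1


def test_indels_and_qual_removed_with_attribution():
    ds = make_dataset(
        [_ten_sample_site(0), _ten_sample_site(0), _ten_sample_site(5)],
        ref=["A", "AT", "A"],
        alt=[("C",), ("A",), ("C",)],
        qual=[10.0, 50.0, 50.0],
    )
    out, rep = filter_sites(ds, FilterParams(min_depth=None))
    # site 1 fails QUAL, site 2 is an indel, site 3 misses 5 calls
    assert out.n_sites == 0
    assert rep.removed == {"qual": 1, "indel": 1, "multiallelic": 0, "missing": 1, "maf": 0}


def test_depth_masking_feeds_missingness_rule():
    site = gt(*(["0/1"] * 10))
    depth = np.full((1, 10), 30, dtype=np.int32)
    depth[0, :4] = 10  # DP <= 10 masked -> 4 missing -> removed
    ds = make_dataset([site], depth=depth)
    out, rep = filter_sites(ds, FilterParams())
    assert out.n_sites == 0
    assert rep.n_calls_depth_masked == 4
    assert rep.removed["missing"] == 1


def _filter_oracle(ds, params):
    """Independent site-by-site application of each rule, in order."""
    keep = []
    for i, rec in enumerate(ds.records()):
        g = rec.genotypes.copy()
        if params.min_depth is not None and rec.depth is not None:
            for s in range(len(g)):
                if 0 <= rec.depth[s] <= params.min_depth and MISSING not in g[s]:
                    g[s] = (MISSING, MISSING)
        if params.min_qual is not None and not (rec.qual > params.min_qual):
            continue
        if params.drop_indels and rec.is_indel:
            continue
        if params.biallelic_only and not rec.is_biallelic:
            continue
        n_missing = sum(1 for s in range(len(g)) if MISSING in g[s])
        if n_missing > params.max_missing_samples:
            continue
        alleles = [a for pair in g for a in pair if a != MISSING]
        if not alleles:
            continue
        f = sum(1 for a in alleles if a == 1) / len(alleles)
        if min(f, 1 - f) < params.min_maf:
            continue
        keep.append(i)
    return keep


def test_filter_sites_matches_brute_force_oracle_on_1000_sites():
    res = simulate(SimConfig(seed=21, n_sites=1000, missing_rate=0.08, indel_fraction=0.2))
    ds = res.dataset
    # push some QUAL and DP values below threshold to exercise those rules
    r = np.random.default_rng(4)
    ds.qual[r.random(ds.n_sites) < 0.1] = 15.0
    ds.depth[r.random(ds.depth.shape) < 0.05] = 5
    params = FilterParams()
    out, rep = filter_sites(ds, params)
    expected = _filter_oracle(ds, params)
    assert list(out.pos) == list(ds.pos[expected])
    assert sum(rep.removed.values()) == rep.n_input - rep.n_output


def test_filter_sites_idempotent():
    res = simulate(SimConfig(seed=22, n_sites=500, missing_rate=0.05))
    once, _ = filter_sites(res.dataset)
    twice, rep = filter_sites(once)
    assert twice.n_sites == once.n_sites
    assert sum(rep.removed.values()) == 0


# ---------------------------------------------------------------------------
# genotype_r2 and ld_prune
# ---------------------------------------------------------------------------

def test_r2_identical_and_complement_columns():
    col = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
    assert genotype_r2(col, col) == pytest.approx(1.0)
    assert genotype_r2(col, 2 - col) == pytest.approx(1.0)


def test_r2_matches_direct_correlation(rng):
    a = rng.integers(0, 3, 50).astype(float)
    b = rng.integers(0, 3, 50).astype(float)
    expected = np.corrcoef(a, b)[0, 1] ** 2
    assert genotype_r2(a, b) == pytest.approx(expected)


def test_r2_undefined_cases():
    const = np.zeros(10)
    varying = np.arange(10, dtype=float)
    assert np.isnan(genotype_r2(const, varying))
    short = np.array([1.0] + [np.nan] * 9)
    assert np.isnan(genotype_r2(short, varying))


def test_ld_prune_drops_later_duplicate():
    a = gt("0/0", "0/1", "1/1", "0/0", "1/1")
    ds = make_dataset([a, a, gt("0/1", "0/0", "0/1", "1/1", "0/0")])
    kept = ld_prune(ds, LdParams(50, 5, 0.5))
    assert list(kept) == [0, 2]


def test_ld_prune_keeps_independent_columns(rng):
    g = rng.integers(0, 2, size=(30, 40, 2)).astype(np.int16)
    ds = make_dataset(g)
    kept = ld_prune(ds, LdParams(50, 5, 0.95))
    assert len(kept) == 30


def _ld_postcondition_violations(ds, kept, params):
    """Exhaustive within-window pair check over retained SNPs."""
    from popscan.variant_filtering import genotype_r2 as r2

    dosage = ds.dosage()
    bad = []
    kept_set = set(kept)
    # windows over original indices, per chromosome
    chroms = list(dict.fromkeys(ds.chrom))
    for c in chroms:
        idx = np.flatnonzero(ds.chrom == c)
        for start in range(0, len(idx), params.step):
            win = idx[start : start + params.window_size]
            inside = [i for i in win if i in kept_set]
            for x in range(len(inside)):
                for y in range(x + 1, len(inside)):
                    v = r2(dosage[inside[x]], dosage[inside[y]])
                    # 1e-9 slack: oracle and implementation may differ in
                    # the last ulp for pairs sitting exactly on the cutoff
                    if np.isfinite(v) and v > params.r2_threshold + 1e-9:
                        bad.append((inside[x], inside[y]))
    return bad


def test_ld_prune_blocks_of_duplicates_satisfy_postcondition(rng):
    base = rng.integers(0, 2, size=(40, 30, 2)).astype(np.int16)
    cols = []
    for i in range(40):
        cols.append(base[i])
        if i % 4 == 0:  # duplicate block
            for _ in range(4):
                cols.append(base[i])
    g = np.stack(cols)[:200]
    ds = make_dataset(g)
    params = LdParams(50, 5, 0.5)
    kept = ld_prune(ds, params)
    assert len(kept) < len(g)
    assert _ld_postcondition_violations(ds, kept, params) == []


@pytest.mark.parametrize("seed", range(20))
def test_ld_prune_postcondition_property(seed):
    """No retained within-window pair exceeds r^2 threshold, 20 seeds."""
    res = simulate(
        SimConfig(seed=seed, n_sites=120, samples_per_cluster=(5, 5, 5),
                  chrom_lengths={"chr1": 300_000}, missing_rate=0.05)
    )
    params = LdParams(30, 5, 0.3)
    kept = ld_prune(res.dataset, params)
    assert _ld_postcondition_violations(res.dataset, kept, params) == []
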