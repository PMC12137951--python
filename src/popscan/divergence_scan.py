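"""Windowed Weir-Cockerham F_ST and the two-contrast outlier-region scan.

Per-site F_ST uses the 1984 variance-component estimator for r = 2
populations of diploids: from group sample sizes n_i, allele frequencies
p_i and heterozygote proportions h_i it forms the among-population (a),
between-individual-within-population (b) and within-individual (c)
components; the site estimate is theta = a / (a + b + c).  The windowed
default is the "weighted" ratio-of-sums sum(a) / sum(a + b + c), the
headline output of the standard tools; mean-of-site-theta is available.

The candidate-region procedure: windows above the top-1% threshold seed
regions, which extend through consecutive overlapping/adjacent windows above
the top-5% threshold; regions are built per contrast, then cross-checked
between the two seed-colour-style contrasts and tiered by whether the
overlap carries top-1% windows of both (tier 1), of exactly one plus top-5%
of the other (tier 2), or only top-5% of both (tier 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diversity_stats import DEFAULT_STEP, DEFAULT_WINDOW, WindowStat, _chrom_lengths, iter_windows
from .io_formats import MISSING, GeneFeature, GenomicInterval, VariantDataset


@dataclass(frozen=True)
class Contrast:
    """A named two-group sample comparison (e.g. light vs dark seed coats)."""

    name: str
    group_light: tuple[str, ...]
    group_dark: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_light) & set(self.group_dark):
            raise ValueError(f"contrast {self.name!r}: groups overlap")
        if len(self.group_light) < 2 or len(self.group_dark) < 2:
            raise ValueError(f"contrast {self.name!r}: each group needs >= 2 samples")


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham variance components (arrays over sites)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.a / denom, np.nan)


def _group_stats(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n_i (called diploids), p_i (alt freq), h_i (het proportion) per site."""
    called = ~(genotypes == MISSING).any(axis=2)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, (genotypes == 1).sum(axis=2), 0).sum(axis=1).astype(float)
    het = np.where(called, genotypes[:, :, 0] != genotypes[:, :, 1], False).sum(
        axis=1
    ).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_fst_components(
    dataset: VariantDataset, contrast: Contrast
) -> FstComponents:
    """Weir-Cockerham (1984) a, b, c per site for a two-group contrast.

    Sites where either group has no called genotype, or with mean sample
    size <= 1, get zero components (excluded from any ratio).
    """
    missing = [
        s
        for s in contrast.group_light + contrast.group_dark
        if s not in dataset.samples
    ]
    if missing:
        raise KeyError(f"contrast samples absent from dataset: {missing}")
    g1 = dataset.take_samples(contrast.group_light).genotypes
    g2 = dataset.take_samples(contrast.group_dark).genotypes
    n1, p1, h1 = _group_stats(g1)
    n2, p2, h2 = _group_stats(g2)

    r = 2.0
    nbar = (n1 + n2) / r
    usable = (n1 > 0) & (n2 > 0) & (nbar > 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    zero = ~usable
    for arr in (a, b, c):
        arr[zero] = 0.0
        arr[np.isnan(arr)] = 0.0
    return FstComponents(a=a, b=b, c=c)


def wc_fst_site(
    genotype_column: np.ndarray, group1_idx: Sequence[int], group2_idx: Sequence[int]
) -> tuple[float, float, float]:
    """Single-site convenience wrapper: (a, b, c) for one genotype column.

    ``genotype_column`` is (n_samples, 2); groups are sample index lists.
    """
    col = np.asarray(genotype_column)[None, :, :]
    samples = [str(i) for i in range(col.shape[1])]
    ds = VariantDataset(
        samples,
        np.array(["x"], dtype=object),
        np.array([1]),
        ["A"],
        [("C",)],
        np.array([50.0]),
        col,
    )
    contrast = Contrast(
        "site",
        tuple(samples[i] for i in group1_idx),
        tuple(samples[i] for i in group2_idx),
    )
    comp = wc_fst_components(ds, contrast)
    return float(comp.a[0]), float(comp.b[0]), float(comp.c[0])


def windowed_fst(
    dataset: VariantDataset,
    contrast: Contrast,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    mode: str = "weighted",
    clamp_negative: bool = False,
) -> list[WindowStat]:
    """Windowed F_ST for one contrast over the sliding-window grid.

    ``mode="weighted"`` (default) is sum(a)/sum(a+b+c) per window;
    ``mode="mean"`` averages per-site theta.  Windows with no usable site
    get NaN (excluded from quantiles downstream).  Negative per-site
    estimates are retained unless ``clamp_negative``.
    """
    if mode not in {"weighted", "mean"}:
        raise ValueError("mode must be 'weighted' or 'mean'")
    comp = wc_fst_components(dataset, contrast)
    a, denom = comp.a, comp.a + comp.b + comp.c
    theta = comp.theta
    if clamp_negative:
        a = np.maximum(a, 0.0)
        theta = np.clip(theta, 0.0, 1.0)
    out: list[WindowStat] = []
    for chrom, length in _chrom_lengths(dataset).items():
        on_chrom = dataset.chrom == chrom
        pos = dataset.pos[on_chrom]
        a_c, d_c, t_c = a[on_chrom], denom[on_chrom], theta[on_chrom]
        for iv in iter_windows(chrom, length, window, step):
            in_win = (pos >= iv.start) & (pos <= iv.end)
            usable = in_win & (d_c > 0)
            n_snps = int(in_win.sum())
            if usable.sum() == 0:
                fst = math.nan
            elif mode == "weighted":
                fst = float(a_c[usable].sum() / d_c[usable].sum())
            else:
                fst = float(np.nanmean(t_c[usable]))
            out.append(
                WindowStat(iv, n_snps=n_snps, fst=fst, truncated=len(iv) < window)
            )
    return out


# ---------------------------------------------------------------------------
# Thresholding and regions
# ---------------------------------------------------------------------------

@dataclass
class QuantileSet:
    """Top-quantile membership: threshold such that members have fst > it."""

    level: float
    threshold: float
    members: set[int]  # indices into the window list


def quantile_thresholds(
    windows: Sequence[WindowStat], levels: Sequence[float] = (0.99, 0.95)
) -> dict[float, QuantileSet]:
    """Top-(1-q) window sets with "greater than threshold" membership.

    The top set holds the ceil((1-q) N) largest defined F_ST values, with
    boundary ties broken toward inclusion; the reported threshold is the
    largest value NOT in the set.  All-identical values yield an empty set
    whose threshold is that value.
    """
    defined = [(i, w.fst) for i, w in enumerate(windows) if not math.isnan(w.fst)]
    if len(defined) < 20:
        raise ValueError(f"need >= 20 defined windows, got {len(defined)}")
    values = np.array([v for _, v in defined])
    out: dict[float, QuantileSet] = {}
    for q in levels:
        # tiny epsilon guards FP noise in (1-q)*N (e.g. 0.01*100 -> 1.0000000009)
        k = max(1, math.ceil((1.0 - q) * len(values) - 1e-9))
        kth = np.sort(values)[::-1][k - 1]
        below = values[values < kth]
        if below.size:
            thr = float(below.max())
            members = {i for (i, v) in defined if v > thr}
        else:
            # kth equals the minimum: degenerate grid
            thr = float(kth)
            members = {i for (i, v) in defined if v > thr}
        out[q] = QuantileSet(level=q, threshold=thr, members=members)
    return out


@dataclass
class OutlierRegion:
    """A merged candidate interval with its seed and flank windows."""

    interval: GenomicInterval
    seed_windows: list[int] = field(default_factory=list)
    flank_windows: list[int] = field(default_factory=list)
    max_fst: float = math.nan
    contrast: str = ""
    tier: int | None = None
    genes: list[GeneFeature] = field(default_factory=list)


def _adjacent(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start <= b.end + 1 and b.start <= a.end + 1


def build_outlier_regions(
    windows: Sequence[WindowStat],
    top1: set[int],
    top5: set[int],
    contrast: str = "",
) -> list[OutlierRegion]:
    """Seed regions from top-1% windows, extend through top-5% flanks, merge.

    Extension walks left and right from each seed through consecutive
    overlapping/adjacent windows in the top-5% set (top1 must be a subset of
    top5).  Overlapping or bookended regions are merged; the region interval
    is the union of its member windows.  Input window order is irrelevant.
    """
    if not top1 <= top5:
        raise ValueError("top1 must be a subset of top5")
    order = sorted(range(len(windows)), key=lambda i: (windows[i].interval.chrom, windows[i].interval.start))
    rank = {idx: r for r, idx in enumerate(order)}

    raw: list[OutlierRegion] = []
    for seed in sorted(top1):
        members = {seed}
        r = rank[seed]
        for direction in (-1, 1):
            cur = r
            while True:
                nxt = cur + direction
                if nxt < 0 or nxt >= len(order):
                    break
                i_cur, i_nxt = order[cur], order[nxt]
                if i_nxt not in top5:
                    break
                if not _adjacent(windows[i_cur].interval, windows[i_nxt].interval):
                    break
                members.add(i_nxt)
                cur = nxt
        iv = windows[seed].interval
        for m in members:
            iv = iv.union(windows[m].interval)
        raw.append(
            OutlierRegion(
                interval=iv,
                seed_windows=sorted(m for m in members if m in top1),
                flank_windows=sorted(m for m in members if m not in top1),
                max_fst=max(windows[m].fst for m in members),
                contrast=contrast,
            )
        )

    # merge overlapping or bookended regions (touching flanks join up)
    raw.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    merged: list[OutlierRegion] = []
    for reg in raw:
        if merged and _adjacent(merged[-1].interval, reg.interval):
            prev = merged[-1]
            prev.interval = prev.interval.union(reg.interval)
            prev.seed_windows = sorted(set(prev.seed_windows) | set(reg.seed_windows))
            prev.flank_windows = sorted(
                (set(prev.flank_windows) | set(reg.flank_windows))
                - set(prev.seed_windows)
            )
            prev.max_fst = max(prev.max_fst, reg.max_fst)
        else:
            merged.append(reg)
    return merged


@dataclass
class TieredRegion:
    """A cross-contrast candidate: merged interval plus support tier."""

    interval: GenomicInterval
    tier: int | None
    contrasts: tuple[str, str] | tuple[str]
    max_fst: float


def cross_compare(
    regions_a: Sequence[OutlierRegion],
    regions_b: Sequence[OutlierRegion],
    windows_a: Sequence[WindowStat],
    windows_b: Sequence[WindowStat],
    top_a: dict[float, QuantileSet],
    top_b: dict[float, QuantileSet],
) -> list[TieredRegion]:
    """Cross-check two contrasts' regions and tier the overlaps.

    Overlapping region pairs (>= 1 bp) yield a merged candidate whose tier
    reflects the strongest window support inside the overlap: tier 1 when it
    intersects top-1% windows of both contrasts, tier 2 when top-1% of
    exactly one and top-5% of the other, tier 3 when only top-5% windows of
    both.  Regions with no cross-contrast overlap are reported untier-ed.
    """

    def hit(iv: GenomicInterval, windows, members: set[int]) -> bool:
        return any(windows[i].interval.overlaps(iv) for i in members)

    out: list[TieredRegion] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for ia, ra in enumerate(regions_a):
        for ib, rb in enumerate(regions_b):
            if not ra.interval.overlaps(rb.interval):
                continue
            overlap = GenomicInterval(
                ra.interval.chrom,
                max(ra.interval.start, rb.interval.start),
                min(ra.interval.end, rb.interval.end),
            )
            a1 = hit(overlap, windows_a, top_a[0.99].members)
            b1 = hit(overlap, windows_b, top_b[0.99].members)
            a5 = hit(overlap, windows_a, top_a[0.95].members)
            b5 = hit(overlap, windows_b, top_b[0.95].members)
            if a1 and b1:
                tier = 1
            elif (a1 and b5) or (b1 and a5):
                tier = 2
            elif a5 and b5:
                tier = 3
            else:
                tier = None
            out.append(
                TieredRegion(
                    interval=ra.interval.union(rb.interval),
                    tier=tier,
                    contrasts=(ra.contrast, rb.contrast),
                    max_fst=max(ra.max_fst, rb.max_fst),
                )
            )
            used_a.add(ia)
            used_b.add(ib)
    for ia, ra in enumerate(regions_a):
        if ia not in used_a:
            out.append(TieredRegion(ra.interval, None, (ra.contrast,), ra.max_fst))
    for ib, rb in enumerate(regions_b):
        if ib not in used_b:
            out.append(TieredRegion(rb.interval, None, (rb.contrast,), rb.max_fst))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def intersect_genes(
    regions: Sequence[OutlierRegion], genes: Sequence[GeneFeature]
) -> None:
    """Attach gene hits (>= 1 bp overlap, 1-based inclusive) to each region."""
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    for reg in regions:
        hits = [
            g
            for g in by_chrom.get(reg.interval.chrom, [])
            if g.start <= reg.interval.end and reg.interval.start <= g.end
        ]
        reg.genes = hits


def check_locus_overlap(
    regions: Sequence[OutlierRegion | TieredRegion], locus: GenomicInterval
) -> tuple[bool, list]:
    """Does any region overlap the locus (e.g. a known seed-colour gene)?"""
    hits = [r for r in regions if r.interval.overlaps(locus)]
    return bool(hits), hits


def parse_locus(spec: str) -> GenomicInterval:
    """Parse "chr7:18230603-18249975" (commas in numbers tolerated)."""
    chrom, _, span = spec.partition(":")
    lo, _, hi = span.replace(",", "").partition("-")
    return GenomicInterval(chrom, int(lo), int(hi))
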