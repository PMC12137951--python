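"""Site filtering and windowed LD pruning for the analysis-ready SNP set.

Filter rules run in a fixed order, each site attributed to the first rule
that removes it: QUAL -> indel -> biallelic-only -> missingness -> MAF.
A per-call depth rule runs before everything else by *masking* low-depth
calls to missing (they then count toward the missingness rule), mirroring
the usual per-genotype DP semantics; site QUAL below threshold removes the
whole site.  Boundaries are strict: QUAL must exceed min_qual, DP must
exceed min_depth, a site is removed when strictly more than
``max_missing_samples`` calls are missing, and when MAF is strictly below
``min_maf`` (a site at exactly the MAF threshold is retained).

LD pruning slides windows of ``window_size`` SNPs advanced by ``step`` along
each chromosome; within a window every pair of still-retained SNPs with
dosage r^2 above the threshold marks the later (higher-index) SNP for
removal.  Zero-variance or <2-sample pairs are treated as "not in LD".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, VariantDataset

RULE_ORDER = ("qual", "indel", "multiallelic", "missing", "maf")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the site filters (defaults follow the strict setting)."""

    max_missing_samples: int = 3
    min_maf: float = 0.05
    min_qual: float | None = 20.0
    min_depth: int | None = 10
    drop_indels: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.max_missing_samples < 0:
            raise ValueError("max_missing_samples must be >= 0")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")


@dataclass(frozen=True)
class LdParams:
    """Sliding-window LD pruning parameters (PLINK-style 50 5 0.5)."""

    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.step > self.window_size or self.step < 1:
            raise ValueError("require 1 <= step <= window_size")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal counts; sites attribute to the first triggering rule."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    n_calls_depth_masked: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("input_sites", self.n_input)]
        rows += [(f"removed_{r}", self.removed.get(r, 0)) for r in RULE_ORDER]
        rows.append(("calls_masked_low_depth", self.n_calls_depth_masked))
        rows.append(("output_sites", self.n_output))
        return rows


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor-allele frequency of one biallelic column over non-missing alleles.

    ``genotype_column`` is (n_samples, 2) allele indices with -1 for missing.
    Returns NaN when no allele is called.
    """
    alleles = np.asarray(genotype_column).reshape(-1)
    called = alleles[alleles != MISSING]
    if called.size == 0:
        return float("nan")
    f_alt = float(np.mean(called == 1))
    return min(f_alt, 1.0 - f_alt)


def filter_sites(
    dataset: VariantDataset, params: FilterParams = FilterParams()
) -> tuple[VariantDataset, FilterReport]:
    """Apply the site filters in order; return retained sites and a report.

    Depth masking mutates only the returned copy, never the input.
    """
    n = dataset.n_sites
    genotypes = dataset.genotypes.copy()
    report = FilterReport(n_input=n, n_output=0)

    if params.min_depth is not None and dataset.depth is not None:
        low = (dataset.depth <= params.min_depth) & (dataset.depth >= 0)
        low &= ~(genotypes == MISSING).any(axis=2)
        genotypes[low] = MISSING
        report.n_calls_depth_masked = int(low.sum())

    masked = VariantDataset(
        dataset.samples,
        dataset.chrom,
        dataset.pos,
        dataset.ref,
        dataset.alt,
        dataset.qual,
        genotypes,
        dataset.depth,
        dataset.chrom_lengths,
    )

    alive = np.ones(n, dtype=bool)
    removed: dict[str, int] = {r: 0 for r in RULE_ORDER}

    if params.min_qual is not None:
        bad = ~(masked.qual > params.min_qual)  # NaN QUAL fails the rule
        removed["qual"] = int((alive & bad).sum())
        alive &= ~bad

    if params.drop_indels:
        bad = masked.is_indel
        removed["indel"] = int((alive & bad).sum())
        alive &= ~bad

    if params.biallelic_only:
        bad = ~masked.is_biallelic
        removed["multiallelic"] = int((alive & bad).sum())
        alive &= ~bad

    n_missing = (genotypes == MISSING).any(axis=2).sum(axis=1)
    bad = n_missing > params.max_missing_samples
    removed["missing"] = int((alive & bad).sum())
    alive &= ~bad

    # MAF over non-missing alleles, computed after the missingness filter;
    # a site with zero called alleles was already removed above.
    called = (genotypes != MISSING)
    n_alleles = called.sum(axis=(1, 2))
    alt_count = ((genotypes == 1) & called).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    bad = ~(maf >= params.min_maf)  # strict "< min_maf removed"; NaN removed
    removed["maf"] = int((alive & bad).sum())
    alive &= ~bad

    report.removed = removed
    out = masked.take_sites(alive)
    report.n_output = out.n_sites
    return out, report


def genotype_r2(column_a: np.ndarray, column_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages over jointly-called samples.

    Columns are (n_samples,) dosage vectors with NaN for missing calls.
    Returns NaN when fewer than 2 shared samples or either column has zero
    variance over the shared samples (callers treat NaN as "not in LD").
    """
    a = np.asarray(column_a, dtype=float)
    b = np.asarray(column_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(cov * cov / (va * vb))


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise r^2 for a (n_snps, n_samples) dosage block with NaNs.

    Moments are taken over the samples jointly called in each pair, so every
    entry agrees exactly with :func:`genotype_r2`.  Undefined pairs (shared
    n < 2 or zero variance over the shared samples) are NaN.
    """
    V = (~np.isnan(dosage)).astype(float)
    X = np.where(np.isnan(dosage), 0.0, dosage)
    n = V @ V.T
    Sx = X @ V.T
    Sxx = (X * X) @ V.T
    Sxy = X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Sx / n
        my = Sx.T / n
        cov = Sxy / n - mx * my
        vx = Sxx / n - mx * mx
        vy = Sxx.T / n - my * my
        r2 = cov * cov / (vx * vy)
        r2[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
    return r2


def ld_prune(dataset: VariantDataset, params: LdParams = LdParams()) -> np.ndarray:
    """Return indices of retained SNPs after windowed dosage-r^2 pruning.

    Sites must be ordered by (chrom, pos).  Within each window pairs are
    visited in index order and only pairs of still-retained SNPs are tested;
    the later SNP of an offending pair is dropped.  Marks accumulate across
    windows, so no retained pair within any window exceeds the threshold.
    """
    n = dataset.n_sites
    keep = np.ones(n, dtype=bool)
    dosage = dataset.dosage()
    # chromosome runs in input order
    boundaries: list[tuple[int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or dataset.chrom[i] != dataset.chrom[start]:
            boundaries.append((start, i))
            start = i
    for lo, hi in boundaries:
        n_chr = hi - lo
        for w_start in range(lo, hi, params.step):
            idx = np.arange(w_start, min(w_start + params.window_size, hi))
            if len(idx) < 2:
                break
            r2 = _window_r2(dosage[idx])
            for ai in range(len(idx)):
                if not keep[idx[ai]]:
                    continue
                for bi in range(ai + 1, len(idx)):
                    if not keep[idx[bi]]:
                        continue
                    v = r2[ai, bi]
                    if np.isfinite(v) and v > params.r2_threshold:
                        keep[idx[bi]] = False
            if w_start + params.window_size >= hi:
                break
    return np.flatnonzero(keep)
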