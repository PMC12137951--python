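"""Nucleotide diversity, inbreeding coefficients, spacing and density ratios.

Per-site diversity uses the unbiased pairwise estimator
``pi = 2 c (n - c) / (n (n - 1))`` over the ``n`` non-missing alleles with
``c`` alternate copies.  Windowed diversity divides the summed site values by
the full window length in bp (per-bp diversity, the convention that yields
the familiar 1e-3-scale values), with a per-variant alternative exposed.

The per-individual inbreeding coefficient follows the observed-vs-expected
homozygosity form F = (O_hom - E_hom) / (L - E_hom), where the per-site
expected homozygosity is the unbiased 1 - 2c(n-c)/(n(n-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io_formats import MISSING, GenomicInterval, VariantDataset

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 50_000


@dataclass
class WindowStat:
    """Per-window summary: site count, per-bp pi, and (optionally) F_ST."""

    interval: GenomicInterval
    n_snps: int = 0
    pi: float = 0.0
    fst: float = math.nan
    truncated: bool = False  # trailing window shorter than the configured size

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class SampleHetStats:
    """Observed/expected homozygosity and the inbreeding coefficient F."""

    sample: str
    observed_hom: int
    expected_hom: float
    n_sites: int
    f_is: float


@dataclass
class SpeciesDensity:
    """Variant density of one dataset/species for cross-species comparison."""

    label: str
    n_snps: int
    n_indels: int
    genome_length: int

    @property
    def bp_per_snp(self) -> int:
        return variant_spacing(self.n_snps, self.genome_length)

    @property
    def bp_per_indel(self) -> int:
        return variant_spacing(self.n_indels, self.genome_length)

    @property
    def combined_density(self) -> float:
        return (self.n_snps + self.n_indels) / self.genome_length

    @classmethod
    def from_spacing(
        cls, label: str, bp_per_snp: float, bp_per_indel: float, genome_length: int = 306_400_000
    ) -> "SpeciesDensity":
        """Build from printed per-variant spacings (bp per SNP / per indel)."""
        return cls(
            label,
            int(round(genome_length / bp_per_snp)),
            int(round(genome_length / bp_per_indel)),
            genome_length,
        )


def iter_windows(
    chrom: str, length: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> Iterator[GenomicInterval]:
    """Sliding windows tiling a chromosome from position 1 (1-based inclusive)."""
    start = 1
    while start <= length:
        yield GenomicInterval(chrom, start, min(start + window - 1, length))
        start += step


def _chrom_lengths(dataset: VariantDataset) -> dict[str, int]:
    if dataset.chrom_lengths:
        return dataset.chrom_lengths
    # fall back to the last observed variant position per chromosome
    out: dict[str, int] = {}
    for c, p in zip(dataset.chrom, dataset.pos):
        out[str(c)] = max(out.get(str(c), 0), int(p))
    return out


def site_pi(genotype_column: np.ndarray) -> float:
    """Unbiased per-site diversity 2c(n-c)/(n(n-1)); NaN if <2 called alleles."""
    alleles = np.asarray(genotype_column).reshape(-1)
    called = alleles[alleles != MISSING]
    n = called.size
    if n < 2:
        return float("nan")
    c = int((called == 1).sum())
    return 2.0 * c * (n - c) / (n * (n - 1))


def _site_pi_vector(dataset: VariantDataset) -> np.ndarray:
    called = dataset.genotypes != MISSING
    n = called.sum(axis=(1, 2)).astype(float)
    c = ((dataset.genotypes == 1) & called).sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * c * (n - c) / (n * (n - 1)), np.nan)
    return pi


def windowed_pi(
    dataset: VariantDataset,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    per_variant: bool = False,
) -> list[WindowStat]:
    """Windowed nucleotide diversity over sliding windows.

    ``pi`` per window is the sum of site values divided by the window length
    in bp (invariant positions count as zero diversity); with ``per_variant``
    the divisor is the number of contributing sites instead.  Empty windows
    report pi 0 and n_snps 0.
    """
    pis = _site_pi_vector(dataset)
    out: list[WindowStat] = []
    for chrom, length in _chrom_lengths(dataset).items():
        on_chrom = dataset.chrom == chrom
        pos = dataset.pos[on_chrom]
        vals = pis[on_chrom]
        for iv in iter_windows(chrom, length, window, step):
            in_win = (pos >= iv.start) & (pos <= iv.end)
            site_vals = vals[in_win]
            usable = site_vals[~np.isnan(site_vals)]
            n_snps = int(in_win.sum())
            if per_variant:
                pi = float(usable.mean()) if usable.size else 0.0
            else:
                pi = float(usable.sum()) / len(iv)
            out.append(
                WindowStat(iv, n_snps=n_snps, pi=pi, truncated=len(iv) < window)
            )
    return out


def individual_f(dataset: VariantDataset, sample: str) -> SampleHetStats:
    """Inbreeding coefficient of one sample from homozygosity excess.

    Uses every site where the sample is called and at least 2 alleles are
    called in total.  Raises ValueError if the denominator L - E_hom is zero
    (every site expected fully homozygous).
    """
    si = dataset.sample_index(sample)
    g = dataset.genotypes[:, si]
    sample_called = ~(g == MISSING).any(axis=1)

    called = dataset.genotypes != MISSING
    n = called.sum(axis=(1, 2)).astype(float)
    c = ((dataset.genotypes == 1) & called).sum(axis=(1, 2)).astype(float)
    use = sample_called & (n >= 2)
    if not use.any():
        raise ValueError(f"sample {sample!r} has no usable site")
    n_u, c_u = n[use], c[use]
    e_hom = float((1.0 - 2.0 * c_u * (n_u - c_u) / (n_u * (n_u - 1))).sum())
    o_hom = int((g[use, 0] == g[use, 1]).sum())
    n_sites = int(use.sum())
    denom = n_sites - e_hom
    if denom == 0.0:
        raise ValueError(f"sample {sample!r}: all sites expected homozygous (F undefined)")
    return SampleHetStats(sample, o_hom, e_hom, n_sites, (o_hom - e_hom) / denom)


def all_individual_f(dataset: VariantDataset) -> list[SampleHetStats]:
    return [individual_f(dataset, s) for s in dataset.samples]


def variant_spacing(n_variants: int, genome_length: int) -> int:
    """bp per variant, rounded half-up to the nearest integer."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return int(math.floor(genome_length / n_variants + 0.5))


@dataclass
class DiversityRatio:
    ratio: float  # combined density of a relative to b
    percent_reduction: float  # of b relative to a


def diversity_ratio(a: SpeciesDensity, b: SpeciesDensity) -> DiversityRatio:
    """Combined-density ratio a/b and percent reduction of b relative to a."""
    da, db = a.combined_density, b.combined_density
    if da <= 0 or db <= 0:
        raise ValueError("densities must be positive")
    return DiversityRatio(ratio=da / db, percent_reduction=100.0 * (1.0 - db / da))


def cluster_summary(
    dataset: VariantDataset,
    assignments: dict[str, str],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    polymorphic_only: bool = True,
) -> dict[str, dict[str, float]]:
    """Per-cluster mean windowed pi and mean SNPs per window.

    Each cluster is subset to its samples; by default only sites polymorphic
    within the cluster contribute (``polymorphic_only=False`` counts every
    site called in the cluster).
    """
    clusters: dict[str, list[str]] = {}
    for sample, group in assignments.items():
        clusters.setdefault(group, []).append(sample)
    out: dict[str, dict[str, float]] = {}
    for group, names in sorted(clusters.items()):
        sub = dataset.take_samples(names)
        if polymorphic_only:
            called = sub.genotypes != MISSING
            n = called.sum(axis=(1, 2))
            c = ((sub.genotypes == 1) & called).sum(axis=(1, 2))
            poly = (c > 0) & (c < n)
            sub = sub.take_sites(poly)
        stats = windowed_pi(sub, window, step)
        out[group] = {
            "n_samples": float(len(names)),
            "mean_pi": float(np.mean([w.pi for w in stats])) if stats else 0.0,
            "mean_snps_per_window": float(np.mean([w.n_snps for w in stats]))
            if stats
            else 0.0,
            "n_windows": float(len(stats)),
        }
    return out
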