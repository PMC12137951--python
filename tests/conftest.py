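"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from popscan.io_formats import VariantDataset


def make_dataset(
    genotypes,
    samples=None,
    pos=None,
    chrom=None,
    ref=None,
    alt=None,
    qual=None,
    depth=None,
    chrom_lengths=None,
):
    """Build a VariantDataset from a (sites, samples, 2) genotype array.

    Defaults: SNPs A->C on chr1 at positions 100, 200, ..., QUAL 50.
    """
    g = np.asarray(genotypes, dtype=np.int16)
    n_sites, n_samples = g.shape[0], g.shape[1]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    pos = np.asarray(pos if pos is not None else (np.arange(n_sites) + 1) * 100)
    chrom = np.asarray(
        chrom if chrom is not None else ["chr1"] * n_sites, dtype=object
    )
    ref = ref or ["A"] * n_sites
    alt = alt or [("C",)] * n_sites
    qual = np.asarray(qual if qual is not None else [50.0] * n_sites, dtype=float)
    return VariantDataset(
        samples, chrom, pos, ref, alt, qual, g, depth, chrom_lengths
    )


def gt(*calls):
    """One site from strings: gt("0/0", "0/1", "./.")."""
    out = []
    for c in calls:
        a, b = c.replace("|", "/").split("/")
        out.append(
            (-1 if a == "." else int(a), -1 if b == "." else int(b))
        )
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
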