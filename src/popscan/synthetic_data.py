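"""Synthetic genotype, sequence and annotation fixtures with known truth.

The generator emulates a small, highly inbred, three-cluster diploid panel:
per-cluster allele frequencies follow the Balding-Nichols model (Beta with
mean p and variance F*p*(1-p)), genotypes within a cluster deviate from
Hardy-Weinberg by a within-individual inbreeding coefficient f, a fraction of
variants are emitted as short (1-5 bp) indels, and calls go missing at a
configurable rate.  Selected windows can be "planted" with an allele-frequency
displacement between the cluster groups of a named contrast so that the
divergence scan has a known positive control.

Defaults mirror the study system the package was built around: 3 clusters of
9/9/8 samples, cluster divergence F = 0.10 (pairwise cluster F_ST in the
field data ranged 0.07-0.13), inbreeding f = 0.55 (observed 0.52-0.58),
13% indels (70,509 of 539,800 variants), ancestral frequencies uniform on
[0.05, 0.95] so the MAF filter keeps a predictable fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    GeneFeature,
    GenomicInterval,
    VariantDataset,
    write_assignments,
    write_fasta,
    write_gff,
    write_vcf,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedWindow:
    """A window whose allele frequencies are displaced for one contrast."""

    interval: GenomicInterval
    contrast: str
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``contrasts`` maps a contrast name to a pair of cluster-index groups
    (group A shifted toward the alt allele in planted windows, group B away).
    """

    n_clusters: int = 3
    samples_per_cluster: tuple[int, ...] = (9, 9, 8)
    n_sites: int = 5000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    fst_divergence: float | tuple[float, ...] = 0.10
    f_is: float = 0.55
    indel_fraction: float = 0.13
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    planted_windows: tuple[PlantedWindow, ...] = ()
    contrasts: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = field(
        default_factory=lambda: {
            "contrast1": ((0,), (1,)),
            "contrast2": ((0,), (2,)),
        }
    )
    mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ValueError("samples_per_cluster length must equal n_clusters")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for r in (self.indel_fraction, self.missing_rate, self.maf_floor):
            if not (0.0 <= r <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")
        if not (0.0 <= self.f_is < 1.0):
            raise ValueError("f_is must lie in [0, 1)")
        total_bp = sum(self.chrom_lengths.values())
        if self.n_sites > total_bp // 10:
            raise ValueError("infeasible config: more variants than spacing allows")
        for pw in self.planted_windows:
            if pw.interval.chrom not in self.chrom_lengths:
                raise ValueError(f"planted window on unknown chromosome {pw.interval.chrom}")
            if pw.interval.end > self.chrom_lengths[pw.interval.chrom]:
                raise ValueError("planted window extends past chromosome end")
            if pw.contrast not in self.contrasts:
                raise ValueError(f"planted window names unknown contrast {pw.contrast!r}")

    @property
    def cluster_fst(self) -> tuple[float, ...]:
        if isinstance(self.fst_divergence, (int, float)):
            return (float(self.fst_divergence),) * self.n_clusters
        return tuple(self.fst_divergence)

    def sample_names(self) -> list[str]:
        return [
            f"K{k + 1}_{i:02d}"
            for k in range(self.n_clusters)
            for i in range(self.samples_per_cluster[k])
        ]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_windows"] = [
            {
                "chrom": pw.interval.chrom,
                "start": pw.interval.start,
                "end": pw.interval.end,
                "contrast": pw.contrast,
                "delta": pw.delta,
            }
            for pw in self.planted_windows
        ]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        d["samples_per_cluster"] = tuple(d["samples_per_cluster"])
        if isinstance(d["fst_divergence"], list):
            d["fst_divergence"] = tuple(d["fst_divergence"])
        d["planted_windows"] = tuple(
            PlantedWindow(
                GenomicInterval(p["chrom"], p["start"], p["end"]), p["contrast"], p["delta"]
            )
            for p in d["planted_windows"]
        )
        d["contrasts"] = {
            k: (tuple(v[0]), tuple(v[1])) for k, v in d["contrasts"].items()
        }
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    cluster_assignment: dict[str, int]
    ancestral_p: np.ndarray  # (n_sites,)
    cluster_p: np.ndarray  # (n_clusters, n_sites) after planting
    planted_windows: tuple[PlantedWindow, ...]
    planted_ssrs: list[dict]
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "cluster_assignment": self.cluster_assignment,
            "ancestral_p": [round(float(x), 6) for x in self.ancestral_p],
            "cluster_p": [
                [round(float(x), 6) for x in row] for row in self.cluster_p
            ],
            "planted_windows": [
                {
                    "chrom": pw.interval.chrom,
                    "start": pw.interval.start,
                    "end": pw.interval.end,
                    "contrast": pw.contrast,
                    "delta": pw.delta,
                }
                for pw in self.planted_windows
            ],
            "planted_ssrs": self.planted_ssrs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d) + "\n")


# ---------------------------------------------------------------------------
# Primitive draws
# ---------------------------------------------------------------------------

def draw_cluster_frequencies(
    p: float, F: float, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-cluster allele frequencies under the Balding-Nichols model.

    Each cluster frequency is Beta(p(1-F)/F, (1-p)(1-F)/F): mean p,
    variance F*p*(1-p).  Degenerate p in {0, 1} returns p for all clusters.
    """
    if not (0.0 < F < 1.0):
        raise ValueError("F must lie in (0, 1)")
    if p <= 0.0 or p >= 1.0:
        return np.full(n_clusters, float(np.clip(p, 0.0, 1.0)))
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale, size=n_clusters)


def draw_genotype(p_k: float, f_is: float, rng: np.random.Generator) -> tuple[int, int]:
    """One diploid genotype under inbreeding coefficient f_is.

    P(alt hom) = p^2 + f*p*q, P(het) = 2pq(1-f), P(ref hom) = q^2 + f*p*q.
    """
    d = _draw_dosages(np.array([p_k]), f_is, rng, n_samples=1)[0, 0]
    return ((1, 1) if d == 2 else (0, 1) if d == 1 else (0, 0))


def _draw_dosages(
    p: np.ndarray, f_is: float, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    """Alt dosages (sites x samples) for one cluster at frequencies ``p``."""
    q = 1.0 - p
    hom_alt = p * p + f_is * p * q
    het = 2.0 * p * q * (1.0 - f_is)
    u = rng.random((len(p), n_samples))
    dos = np.zeros((len(p), n_samples), dtype=np.int16)
    dos[u < (hom_alt + het)[:, None]] = 1
    dos[u < hom_alt[:, None]] = 2
    return dos


def plant_divergent_window(
    cluster_p: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    interval: GenomicInterval,
    clusters_a: Sequence[int],
    clusters_b: Sequence[int],
    delta: float,
) -> np.ndarray:
    """Displace in-window cluster frequencies toward fixation between groups.

    Group-A cluster frequencies are shifted by +delta and group-B by -delta,
    clipped to [0, 1]; delta=1 plants a fixed difference (window F_ST = 1),
    delta=0 is the identity.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    known = set(np.unique(chrom))
    if interval.chrom not in known:
        raise ValueError(f"interval chromosome {interval.chrom!r} not simulated")
    out = cluster_p.copy()
    mask = (chrom == interval.chrom) & (pos >= interval.start) & (pos <= interval.end)
    for k in clusters_a:
        out[k, mask] = np.clip(out[k, mask] + delta, 0.0, 1.0)
    for k in clusters_b:
        out[k, mask] = np.clip(out[k, mask] - delta, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(
    length: int, rng: np.random.Generator, exclude_repeats: bool = False
) -> str:
    """Random A/C/G/T sequence; optionally scrubbed of short tandem repeats.

    With ``exclude_repeats`` every stretch periodic at unit size 1-6 for
    three or more complete units is broken, so SSR-census tests see exactly
    the repeats that were planted afterwards.
    """
    seq = rng.integers(0, 4, size=length)
    if exclude_repeats:
        for _ in range(50):
            dirty = False
            for k in range(1, 7):
                eq = np.zeros(length, dtype=bool)
                eq[k:] = seq[k:] == seq[:-k]
                # break any run of >= 2k consecutive matches (>= 3 units)
                run = 0
                for j in range(length):
                    run = run + 1 if eq[j] else 0
                    if run >= 2 * k:
                        old = seq[j]
                        seq[j] = (old + 1 + rng.integers(0, 3)) % 4
                        run = 0
                        dirty = True
            if not dirty:
                break
    return "".join(BASES[seq])


def plant_ssr(seq: list[str], start0: int, motif: str, n_repeats: int) -> dict:
    """Overwrite ``seq`` (0-based list) with ``motif * n_repeats``; break flanks."""
    unit = list(motif)
    tract = unit * n_repeats
    seq[start0 : start0 + len(tract)] = tract
    # make the bases just outside the tract unable to extend the repeat
    for flank, inside in ((start0 - 1, start0 - 1 + len(motif)),
                          (start0 + len(tract), start0 + len(tract) - len(motif))):
        if 0 <= flank < len(seq) and seq[flank] == seq[inside]:
            seq[flank] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[flank]]
    return {
        "start": start0 + 1,
        "end": start0 + len(tract),
        "motif": motif,
        "n_repeats": n_repeats,
    }


DEFAULT_SSR_PLAN = (
    ("A", 12),
    ("AG", 9),
    ("AAT", 7),
    ("ACAT", 5),
    ("AACGT", 4),
    ("AACGTT", 4),
)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    dataset: VariantDataset
    truth: SimTruth
    sequences: dict[str, str]
    genes: list[GeneFeature]
    assignments: dict[str, str]
    config: SimConfig


def simulate(config: SimConfig) -> SimResult:
    """Simulate variants, reference sequence, genes and assignments in memory.

    Deterministic given ``config.seed``; per-chromosome draws use sub-streams
    seeded from (seed, chromosome index) so chromosome content is stable under
    changes elsewhere in the configuration.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = list(config.chrom_lengths)

    # -- positions, allocated proportionally to chromosome length ---------
    total_bp = sum(config.chrom_lengths.values())
    alloc: list[int] = []
    for i, name in enumerate(chrom_names):
        if i == len(chrom_names) - 1:
            alloc.append(config.n_sites - sum(alloc))
        else:
            alloc.append(int(round(config.n_sites * config.chrom_lengths[name] / total_bp)))
    chrom_list: list[str] = []
    pos_list: list[np.ndarray] = []
    sequences: dict[str, str] = {}
    planted_ssrs: list[dict] = []
    for i, name in enumerate(chrom_names):
        sub = np.random.default_rng([config.seed, i])
        L = config.chrom_lengths[name]
        seq = list(random_sequence(L, sub))
        # plant a deterministic SSR census, spaced across the chromosome
        offset = L // (len(DEFAULT_SSR_PLAN) + 1)
        for j, (motif, reps) in enumerate(DEFAULT_SSR_PLAN):
            rec = plant_ssr(seq, (j + 1) * offset, motif, reps)
            rec["chrom"] = name
            planted_ssrs.append(rec)
        sequences[name] = "".join(seq)
        p = np.sort(sub.choice(np.arange(1, L - 6), size=alloc[i], replace=False))
        chrom_list.extend([name] * alloc[i])
        pos_list.append(p)
    chrom = np.array(chrom_list, dtype=object)
    pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=np.int64)

    # -- frequencies ------------------------------------------------------
    anc_p = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=config.n_sites)
    cluster_p = np.empty((config.n_clusters, config.n_sites))
    fst = config.cluster_fst
    for k in range(config.n_clusters):
        scale = (1.0 - fst[k]) / fst[k]
        cluster_p[k] = rng.beta(anc_p * scale, (1.0 - anc_p) * scale)
    for pw in config.planted_windows:
        a, b = config.contrasts[pw.contrast]
        cluster_p = plant_divergent_window(
            cluster_p, chrom, pos, pw.interval, a, b, pw.delta
        )

    # -- genotypes --------------------------------------------------------
    samples = config.sample_names()
    genotypes = np.empty((config.n_sites, len(samples), 2), dtype=np.int16)
    col = 0
    assignment: dict[str, int] = {}
    for k, n_k in enumerate(config.samples_per_cluster):
        dos = _draw_dosages(cluster_p[k], config.f_is, rng, n_k)
        g = np.zeros((config.n_sites, n_k, 2), dtype=np.int16)
        g[:, :, 0] = (dos == 2).astype(np.int16)
        g[:, :, 1] = (dos >= 1).astype(np.int16)
        genotypes[:, col : col + n_k] = g
        for i in range(n_k):
            assignment[samples[col + i]] = k
        col += n_k
    if config.missing_rate > 0:
        miss = rng.random((config.n_sites, len(samples))) < config.missing_rate
        genotypes[miss] = -1

    # -- alleles, QUAL, DP -------------------------------------------------
    is_indel = rng.random(config.n_sites) < config.indel_fraction
    comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
    ref: list[str] = []
    alt: list[tuple[str, ...]] = []
    indel_len = rng.integers(1, 6, size=config.n_sites)
    indel_ins = rng.random(config.n_sites) < 0.5
    ins_bases = rng.integers(0, 4, size=(config.n_sites, 5))
    for i in range(config.n_sites):
        seq = sequences[chrom[i]]
        base = seq[pos[i] - 1]
        if is_indel[i]:
            ln = int(indel_len[i])
            if indel_ins[i]:
                ref.append(base)
                alt.append((base + "".join(BASES[ins_bases[i, :ln]]),))
            else:
                ref.append(seq[pos[i] - 1 : pos[i] - 1 + ln + 1])
                alt.append((base,))
        else:
            ref.append(base)
            alt.append((comp[base],))
    qual = np.round(rng.uniform(25.0, 60.0, size=config.n_sites), 1)
    depth = rng.poisson(config.mean_depth, size=(config.n_sites, len(samples))).astype(
        np.int32
    )

    dataset = VariantDataset(
        samples, chrom, pos, ref, alt, qual, genotypes, depth, dict(config.chrom_lengths)
    )

    # -- genes: tile planted windows, plus background genes ----------------
    genes: list[GeneFeature] = []
    gid = 0
    for pw in config.planted_windows:
        iv = pw.interval
        third = max(len(iv) // 3, 1)
        for j in range(2):
            gid += 1
            start = iv.start + j * third
            genes.append(
                GeneFeature(
                    iv.chrom,
                    start,
                    min(start + third - 1, iv.end),
                    "+" if j % 2 == 0 else "-",
                    f"gene{gid:04d}",
                    f"planted-window gene ({pw.contrast})",
                )
            )
    for name in chrom_names:
        L = config.chrom_lengths[name]
        for start in range(50_000, L - 3_000, 150_000):
            gid += 1
            genes.append(
                GeneFeature(name, start, start + 2_999, "+", f"gene{gid:04d}",
                            "background gene")
            )
    genes.sort(key=lambda g: (g.chrom, g.start))

    truth = SimTruth(
        cluster_assignment=assignment,
        ancestral_p=anc_p,
        cluster_p=cluster_p,
        planted_windows=config.planted_windows,
        planted_ssrs=planted_ssrs,
        seed=config.seed,
    )
    named = {s: f"cluster{assignment[s] + 1}" for s in samples}
    return SimResult(dataset, truth, sequences, genes, named, config)


def generate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write VCF/FASTA/GFF/assignment TSV plus truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate(config)
    paths = {
        "vcf": outdir / "variants.vcf",
        "fasta": outdir / "reference.fa",
        "gff": outdir / "genes.gff3",
        "assignments": outdir / "assignments.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    write_vcf(res.dataset, paths["vcf"])
    write_fasta(res.sequences, paths["fasta"])
    write_gff(res.genes, paths["gff"])
    write_assignments(res.assignments, paths["assignments"])
    res.truth.to_json(paths["truth"])
    config.to_json(paths["config"])
    return paths
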