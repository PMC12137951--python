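"""Readers, writers and shared containers for the formats the pipeline touches.

All coordinates held in memory are 1-based inclusive, matching VCF and GFF3.
The single exception is BED output, which is converted to 0-based half-open
at the write boundary and nowhere else.

Multi-allelic records are read intact; discarding them is the job of the
variant filter, not the reader.  Phased ("|") and unphased ("/") genotypes
are treated identically — phase is never used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  # allele index for an uncalled allele


class VcfFormatError(ValueError):
    """Raised for malformed or unsupported (non-diploid) VCF input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (1-based inclusive)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level annotation feature (1-based inclusive span)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class VariantRecord:
    """One VCF record: site fields plus per-sample diploid calls.

    ``genotypes`` holds one ``(a, b)`` pair of allele indices per sample,
    with :data:`MISSING` marking an uncalled allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    qual: float
    genotypes: np.ndarray  # (n_samples, 2) int
    depth: np.ndarray | None = None  # (n_samples,) int, -1 missing

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alt)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1


class VariantDataset:
    """A samples x variants genotype matrix with site metadata.

    Column-major site arrays make the windowed statistics and filters
    vectorisable; :meth:`records` offers a per-record view when needed.
    """

    def __init__(
        self,
        samples: Sequence[str],
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: Sequence[str],
        alt: Sequence[tuple[str, ...]],
        qual: np.ndarray,
        genotypes: np.ndarray,
        depth: np.ndarray | None = None,
        chrom_lengths: dict[str, int] | None = None,
    ) -> None:
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alt = [tuple(a) for a in alt]
        self.qual = np.asarray(qual, dtype=float)
        self.genotypes = np.asarray(genotypes, dtype=np.int16)
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int32)
        self.chrom_lengths = dict(chrom_lengths or {})
        if self.genotypes.shape != (len(self.pos), len(self.samples), 2):
            raise ValueError("genotype array shape does not match sites x samples x 2")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_indel(self) -> np.ndarray:
        out = np.zeros(self.n_sites, dtype=bool)
        for i, (r, alts) in enumerate(zip(self.ref, self.alt)):
            out[i] = any(len(a) != len(r) for a in alts)
        return out

    @property
    def is_biallelic(self) -> np.ndarray:
        return np.fromiter((len(a) == 1 for a in self.alt), dtype=bool, count=self.n_sites)

    def records(self) -> Iterator[VariantRecord]:
        for i in range(self.n_sites):
            yield VariantRecord(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=self.ref[i],
                alt=self.alt[i],
                qual=float(self.qual[i]),
                genotypes=self.genotypes[i],
                depth=None if self.depth is None else self.depth[i],
            )

    # -- views ----------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "VariantDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantDataset(
            self.samples,
            self.chrom[index],
            self.pos[index],
            [self.ref[i] for i in index],
            [self.alt[i] for i in index],
            self.qual[index],
            self.genotypes[index],
            None if self.depth is None else self.depth[index],
            self.chrom_lengths,
        )

    def take_samples(self, names: Sequence[str]) -> "VariantDataset":
        idx = [self.sample_index(n) for n in names]
        return VariantDataset(
            [self.samples[i] for i in idx],
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.qual,
            self.genotypes[:, idx],
            None if self.depth is None else self.depth[:, idx],
            self.chrom_lengths,
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in dataset") from None

    # -- derived matrices -----------------------------------------------
    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) per call, NaN where either allele is missing.

        Only meaningful for biallelic sites; multi-allelic alt indices are
        summed as-is and should be filtered out first.
        """
        g = self.genotypes.astype(float)
        d = g[:, :, 0] + g[:, :, 1]
        d[(self.genotypes == MISSING).any(axis=2)] = np.nan
        return d

    def call_missing(self) -> np.ndarray:
        """Boolean (sites, samples): call has at least one missing allele."""
        return (self.genotypes == MISSING).any(axis=2)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> VariantDataset:
    """Read a diploid VCF v4.x into a :class:`VariantDataset`.

    Record and sample order are preserved; ``./.`` calls stay missing.
    Raises :class:`VcfFormatError` on malformed input or non-diploid GT.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfFormatError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[tuple[str, ...]] = []
    qual: list[float] = []
    gts: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    has_depth = False

    for lineno, v in enumerate(vcf, start=1):
        g = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for si, call in enumerate(v.genotypes):
            if len(call) != 3:
                raise VcfFormatError(
                    f"{path}: record {lineno} ({v.CHROM}:{v.POS}) sample "
                    f"{samples[si]!r} is not diploid"
                )
            a, b = call[0], call[1]
            g[si, 0] = a if a >= 0 else MISSING
            g[si, 1] = b if b >= 0 else MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(tuple(v.ALT))
        qual.append(float(v.QUAL) if v.QUAL is not None else math.nan)
        gts.append(g)
        try:
            dp = v.format("DP")
        except KeyError:  # DP absent from the header
            dp = None
        if dp is not None:
            has_depth = True
            d = dp.reshape(-1).astype(np.int32)
            d[d < 0] = -1
            depths.append(d)
        else:
            depths.append(np.full(len(samples), -1, dtype=np.int32))

    lengths: dict[str, int] = {}
    try:
        lengths = {n: int(l) for n, l in zip(vcf.seqnames, vcf.seqlens)}
    except Exception:
        pass

    n = len(pos)
    return VariantDataset(
        samples,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        ref,
        alt,
        np.array(qual, dtype=float),
        np.stack(gts) if n else np.empty((0, len(samples), 2), dtype=np.int16),
        np.stack(depths) if (n and has_depth) else None,
        lengths,
    )


def write_vcf(dataset: VariantDataset, path: str | Path) -> None:
    """Write a :class:`VariantDataset` as plain-text VCF v4.2 (byte-stable)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan\n")
        for name, length in dataset.chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dataset.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        fmt = "GT" if dataset.depth is None else "GT:DP"
        for i in range(dataset.n_sites):
            q = dataset.qual[i]
            qs = "." if math.isnan(q) else f"{q:.1f}"
            calls = []
            for si in range(dataset.n_samples):
                a, b = dataset.genotypes[i, si]
                gt = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                if dataset.depth is not None:
                    d = dataset.depth[i, si]
                    gt += ":" + ("." if d < 0 else str(int(d)))
                calls.append(gt)
            fh.write(
                f"{dataset.chrom[i]}\t{dataset.pos[i]}\t.\t{dataset.ref[i]}\t"
                f"{','.join(dataset.alt[i])}\t{qs}\t.\t.\t{fmt}\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene-level features only)
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneFeature]:
    """Read gene-level features from GFF3.

    gene_id is taken from the ``ID`` attribute, falling back to ``Name``,
    falling back to the raw attribute string.  The free-text description is
    taken from ``description``/``product``/``Note`` when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneFeature] = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = f.attributes
        if "ID" in attrs:
            gene_id = attrs["ID"][0]
        elif "Name" in attrs:
            gene_id = attrs["Name"][0]
        else:
            gene_id = str(f.attributes)
        desc = ""
        for key in ("description", "product", "Note"):
            if key in attrs:
                desc = attrs[key][0]
                break
        genes.append(
            GeneFeature(
                chrom=f.seqid,
                start=int(f.start),
                end=int(f.end),
                strand=f.strand or ".",
                gene_id=gene_id,
                description=desc,
            )
        )
    return genes


def write_gff(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\tpopscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED / Newick / tables
# ---------------------------------------------------------------------------

def write_bed(
    regions: Iterable[GenomicInterval | tuple[GenomicInterval, str]],
    path: str | Path,
) -> None:
    """Write intervals as BED (0-based half-open), optional 4th label column."""
    with open(path, "w") as fh:
        for item in regions:
            if isinstance(item, tuple):
                iv, label = item
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{label}\n")
            else:
                fh.write(f"{item.chrom}\t{item.start - 1}\t{item.end}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as Newick (supports as internal labels)."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def read_assignments(path: str | Path) -> dict[str, str]:
    """Read a 2-column sample -> group TSV (header optional, '#' comments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad assignment line: {line!r}")
            if parts[0] == "sample" and parts[1] in {"group", "cluster", "population"}:
                continue
            out[parts[0]] = parts[1]
    return out


def write_assignments(assignments: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcluster\n")
        for sample, group in assignments.items():
            fh.write(f"{sample}\t{group}\n")
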