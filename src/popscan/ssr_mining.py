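"""Microsatellite (SSR) detection in FASTA sequences.

Finds maximal perfect tandem repeats of primitive 1-6 bp motifs meeting
per-unit-size minimum repeat counts (default 10/8/6/4/4/4 for mono- through
hexanucleotides).  A run reportable at several unit sizes is reported once,
at its smallest true period: the motif must be primitive (not itself a
repetition of a shorter unit), so poly-A is mono, (AT)n is di and never
mono, and (AT)n is never also reported as the non-primitive tetramer ATAT.
Matching is case-insensitive; N never participates in a repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 8, 3: 6, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SsrThresholds:
    """Minimum repeat count per motif length (all must be >= 2)."""

    by_length: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        for k, v in self.by_length.items():
            if not (1 <= k <= 6) or v < 2:
                raise ValueError("thresholds map motif lengths 1-6 to counts >= 2")


@dataclass(frozen=True)
class SsrRecord:
    """One perfect tandem repeat: 1-based inclusive span of motif x n."""

    chrom: str
    start: int
    end: int
    motif: str
    n_repeats: int

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def canonical_motif(self) -> str:
        return canonicalise_motif(self.motif)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.n_repeats:
            raise ValueError("span does not equal motif_length x n_repeats")


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def find_ssrs(
    sequence: str,
    chrom: str = "seq",
    thresholds: SsrThresholds | Mapping[int, int] | None = None,
) -> list[SsrRecord]:
    """All maximal perfect tandem repeats meeting the thresholds.

    For each unit size k the sequence is scanned for maximal k-periodic
    stretches; a stretch of length L yields floor(L/k) complete units
    anchored at the stretch start.  Records whose motif is non-primitive or
    contains N are dropped (the run is instead reported at its primitive
    period, by the k equal to that period).
    """
    if thresholds is None:
        thresholds = SsrThresholds()
    thr = thresholds.by_length if isinstance(thresholds, SsrThresholds) else thresholds
    s = sequence.upper()
    n = len(s)
    out: list[SsrRecord] = []
    if n == 0:
        return out
    arr = np.frombuffer(s.encode(), dtype="S1")
    is_n = arr == b"N"
    for k, min_reps in sorted(thr.items()):
        if n < k * min_reps:
            continue
        eq = np.zeros(n, dtype=bool)
        eq[k:] = (arr[k:] == arr[:-k]) & ~is_n[k:] & ~is_n[:-k]
        # maximal runs of eq: a run j0..j1 means s[j0-k..j1] is k-periodic
        j = k
        while j < n:
            if not eq[j]:
                j += 1
                continue
            j0 = j
            while j < n and eq[j]:
                j += 1
            stretch_start = j0 - k  # 0-based
            stretch_len = (j - 1) - stretch_start + 1
            m = stretch_len // k
            if m >= min_reps:
                motif = s[stretch_start : stretch_start + k]
                if _is_primitive(motif) and "N" not in motif:
                    out.append(
                        SsrRecord(
                            chrom=chrom,
                            start=stretch_start + 1,
                            end=stretch_start + k * m,
                            motif=motif,
                            n_repeats=m,
                        )
                    )
    out.sort(key=lambda r: (r.start, r.motif_length))
    return out


def find_ssrs_genome(
    sequences: Mapping[str, str],
    thresholds: SsrThresholds | Mapping[int, int] | None = None,
) -> list[SsrRecord]:
    out: list[SsrRecord] = []
    for chrom, seq in sequences.items():
        out.extend(find_ssrs(seq, chrom=chrom, thresholds=thresholds))
    return out


def canonicalise_motif(motif: str) -> str:
    """Lexicographically smallest among all cyclic rotations of the motif
    and of its reverse complement (the usual SSR class label)."""
    m = motif.upper()
    rc = m.translate(_COMPLEMENT)[::-1]
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


@dataclass
class SsrSummary:
    """Motif-class composition of a set of SSR records."""

    n_records: int
    by_unit_length: dict[int, float]
    by_canonical_motif: dict[str, float]


def summarise_ssrs(records: Sequence[SsrRecord]) -> SsrSummary:
    """Fractions of records per unit-length class and per canonical motif."""
    n = len(records)
    if n == 0:
        return SsrSummary(0, {}, {})
    by_len: dict[int, int] = {}
    by_motif: dict[str, int] = {}
    for r in records:
        by_len[r.motif_length] = by_len.get(r.motif_length, 0) + 1
        cm = r.canonical_motif
        by_motif[cm] = by_motif.get(cm, 0) + 1
    return SsrSummary(
        n_records=n,
        by_unit_length={k: v / n for k, v in sorted(by_len.items())},
        by_canonical_motif={k: v / n for k, v in sorted(by_motif.items())},
    )
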