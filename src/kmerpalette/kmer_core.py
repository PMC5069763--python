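"""Exact k-mer enumeration and the common k-mer (pckm) matrix.

The similarity primitive of the whole package is the *percentage of common
k-mers*::

    pckm_k(g_i, g_j) = sum_{w shared by g_i and g_j} occ_w(g_j) / W_j(k)

where ``occ_w`` counts occurrences with overlap and ``W_j(k)`` is the number
of valid (all-ACGT) length-k windows of genome ``g_j``.  It is a containment
score, not a Jaccard index: it is weighted by the multiplicities of genome
j's k-mers and is asymmetric in its two arguments.  Collecting all pairwise
values over a reference database gives the common k-mer matrix ``A^(k)``,
whose column j is genome j's "palette" — its k-mer sharing pattern against
every reference.

Counting is exact and hash based.  Windows containing any non-ACGT letter
contribute nothing; windows never span record boundaries in multi-record
genomes.  By default each k-mer is collapsed with its reverse complement
(canonical form), since shotgun reads sample both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "KmerMultiset",
    "CommonKmerMatrix",
    "reverse_complement",
    "occ",
    "enumerate_kmers",
    "pckm",
    "build_common_kmer_matrix",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; ``qual`` holds per-base Phred scores for reads.

    Lowercase letters are uppercased on construction.  IUPAC ambiguity
    codes are allowed in ``seq``; they simply invalidate any k-mer window
    that covers them.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class KmerMultiset:
    """Exact multiset of the valid k-length windows of one sequence set.

    ``total`` equals ``n_windows`` by construction: every valid window is
    counted exactly once, so the multiset cardinality is the window count.
    """

    k: int
    counts: Counter
    n_windows: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        total = sum(self.counts.values())
        if total != self.n_windows:
            raise ValueError(
                f"inconsistent multiset: sum of counts {total} != "
                f"n_windows {self.n_windows}"
            )

    @property
    def total(self) -> int:
        """Multiset cardinality (== number of valid windows scanned)."""
        return self.n_windows

    def key_set(self) -> frozenset:
        """The distinct k-mers, for fast membership queries."""
        return frozenset(self.counts)


@dataclass
class CommonKmerMatrix:
    """All pairwise pckm values of a genome set at one k-mer size.

    ``values[i, j] == pckm_k(g_i, g_j)``; the matrix is generally not
    symmetric.  Column j is genome j's palette.
    """

    k: int
    genome_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        M = len(self.genome_ids)
        if self.values.shape != (M, M):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{M} genome ids"
            )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.genome_ids) + "\n")
            for gid, row in zip(self.genome_ids, self.values):
                fh.write(gid + "," + ",".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path, k: int) -> "CommonKmerMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split(",")
                rows.append([float(v) for v in parts[1:]])
        return cls(k=k, genome_ids=header, values=np.array(rows))


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def occ(v: str, w: str) -> int:
    """Number of (possibly overlapping) occurrences of subword v in w."""
    if not v:
        raise ValueError("query word must be nonempty")
    n = 0
    i = w.find(v)
    while i != -1:
        n += 1
        i = w.find(v, i + 1)
    return n


def valid_window_starts(
    seq: str, k: int, qual: Sequence[int] | None = None, qmin: int | None = None
) -> np.ndarray:
    """Start indices of length-k windows that are all-ACGT (and, when qmin
    is given, whose every base has Phred >= qmin)."""
    L = len(seq)
    if L < k:
        return np.empty(0, dtype=np.intp)
    bad = np.zeros(L + 1, dtype=np.intp)
    clean = True
    for i, c in enumerate(seq):
        if c not in ALPHABET:
            bad[i + 1] = 1
            clean = False
    if qmin is not None and qual is not None:
        q = np.asarray(qual)
        low = q < qmin
        if low.any():
            bad[1:][low] = 1
            clean = False
    if clean:
        return np.arange(L - k + 1, dtype=np.intp)
    csum = np.cumsum(bad)
    starts = np.nonzero(csum[k:] - csum[: L - k + 1] == 0)[0]
    return starts.astype(np.intp)


def _window_kmers(seq: str, k: int, canonical: bool,
                  starts: Iterable[int]) -> list[str]:
    if canonical:
        rc = reverse_complement(seq)
        L = len(seq)
        out = []
        for i in starts:
            f = seq[i : i + k]
            r = rc[L - k - i : L - i]
            out.append(f if f <= r else r)
        return out
    return [seq[i : i + k] for i in starts]


def enumerate_kmers(
    records: Iterable[SequenceRecord], k: int, canonical: bool = True
) -> KmerMultiset:
    """Count every valid k-length window across a set of records.

    Windows never span record boundaries.  With ``canonical`` set, each
    k-mer is replaced by the lexicographic minimum of itself and its
    reverse complement before counting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    n = 0
    for rec in records:
        starts = valid_window_starts(rec.seq, k)
        if len(starts) == 0:
            continue
        kmers = _window_kmers(rec.seq, k, canonical, starts)
        counts.update(kmers)
        n += len(kmers)
    return KmerMultiset(k=k, counts=counts, n_windows=n)


def pckm(ms_i: KmerMultiset, ms_j: KmerMultiset) -> float:
    """Fraction of genome j's k-mers (with multiplicity) shared with genome i.

    Asymmetric: the summand is genome j's occurrence count and the
    denominator genome j's valid-window count.  ``pckm(ms, ms) == 1``
    for any nonempty multiset.
    """
    if ms_i.k != ms_j.k:
        raise ValueError(f"k-mer size mismatch: {ms_i.k} != {ms_j.k}")
    if ms_j.n_windows < 1:
        raise ValueError("genome j has no valid k-mer windows")
    ci, cj = ms_i.counts, ms_j.counts
    if len(ci) <= len(cj):
        shared = sum(cj[w] for w in ci if w in cj)
    else:
        shared = sum(c for w, c in cj.items() if w in ci)
    return shared / ms_j.n_windows


def build_common_kmer_matrix(
    genomes: Sequence[Sequence[SequenceRecord]],
    k: int,
    canonical: bool = True,
    genome_ids: Sequence[str] | None = None,
) -> CommonKmerMatrix:
    """Pairwise pckm matrix over a genome set (each genome a record list).

    Raises ValueError, naming the genome, if any genome has no valid
    window at this k.
    """
    if genome_ids is None:
        genome_ids = [g[0].id for g in genomes]
    if len(genome_ids) != len(genomes):
        raise ValueError("genome_ids length does not match genome count")
    multisets = []
    for gid, recs in zip(genome_ids, genomes):
        ms = enumerate_kmers(recs, k, canonical=canonical)
        if ms.n_windows == 0:
            raise ValueError(
                f"genome {gid!r} has no valid {k}-mer window"
            )
        multisets.append(ms)
    M = len(multisets)
    values = np.empty((M, M))
    for i in range(M):
        for j in range(M):
            values[i, j] = pckm(multisets[i], multisets[j])
    return CommonKmerMatrix(k=k, genome_ids=list(genome_ids), values=values)
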