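"""Sample k-mer signatures: the measurement vectors y^(30), y^(50).

K-mers are counted over the whole sample at once, never per read.  For each
reference genome i the signature entry is

    y_i = (sum of sample counts of k-mers also found in genome i)
          / (total count of all valid sample k-mers)

The denominator deliberately includes sample k-mers matching *no* reference,
so unmatched content depresses every entry equally — mass the hypothetical
bins then absorb.  Under uniform read sampling, y ≈ A x where x is the
vector of per-genome read proportions; that linear relation is what the
mixture solver inverts.

FASTQ quality scores can gate counting: with ``qmin`` set, a window counts
only when every one of its k bases has Phred >= qmin (the strictest
reading of quality-thresholded counting), which suppresses error k-mers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .kmer_core import (
    KmerMultiset,
    SequenceRecord,
    _window_kmers,
    valid_window_starts,
)
from collections import Counter

__all__ = [
    "SampleSignature",
    "count_sample_kmers",
    "sample_vector",
    "stack_signatures",
]


@dataclass
class SampleSignature:
    """Normalized shared-k-mer vector of one sample against M references."""

    k: int
    y: np.ndarray
    total_kmers: int
    qmin: int | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("signature entries must lie in [0, 1]")
        if self.total_kmers < 0:
            raise ValueError("total_kmers must be >= 0")


def count_sample_kmers(
    reads: Iterable[SequenceRecord],
    k: int,
    canonical: bool = True,
    qmin: int | None = None,
) -> KmerMultiset:
    """Count valid k-mer windows over an entire read stream.

    A window contributes iff all its bases are ACGT and, when ``qmin`` is
    set, every base's Phred score is >= qmin.  Reads without quality
    strings (FASTA input) trigger a warning and are counted unfiltered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    n = 0
    warned = False
    for rec in reads:
        q = rec.qual
        if qmin is not None and q is None:
            if not warned:
                warnings.warn(
                    "quality threshold given but input has no quality "
                    "scores; qmin ignored",
                    stacklevel=2,
                )
                warned = True
            starts = valid_window_starts(rec.seq, k)
        else:
            starts = valid_window_starts(rec.seq, k, qual=q, qmin=qmin)
        if len(starts) == 0:
            continue
        counts.update(_window_kmers(rec.seq, k, canonical, starts))
        n += len(starts)
    return KmerMultiset(k=k, counts=counts, n_windows=n)


def sample_vector(
    sample_ms: KmerMultiset,
    genome_kmer_sets: Sequence[frozenset],
    qmin: int | None = None,
) -> SampleSignature:
    """Per-genome shared-k-mer fractions of one sample multiset.

    ``genome_kmer_sets`` are the distinct-k-mer sets of the M references
    at the same k (and the same canonicalization) as ``sample_ms``.
    """
    if sample_ms.total < 1:
        raise ValueError("sample contains no valid k-mers")
    M = len(genome_kmer_sets)
    shared = np.zeros(M)
    items = list(sample_ms.counts.items())
    for i, gset in enumerate(genome_kmer_sets):
        shared[i] = sum(c for w, c in items if w in gset)
    y = shared / sample_ms.total
    return SampleSignature(
        k=sample_ms.k, y=y, total_kmers=sample_ms.total, qmin=qmin
    )


def stack_signatures(y30: SampleSignature, y50: SampleSignature) -> np.ndarray:
    """Concatenate the two signatures into the stacked measurement vector."""
    if len(y30.y) != len(y50.y):
        raise ValueError(
            f"signature lengths differ: {len(y30.y)} != {len(y50.y)}"
        )
    return np.concatenate([y30.y, y50.y])
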