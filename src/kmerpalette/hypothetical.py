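"""Hypothetical-organism columns and the stacked two-k linear system.

A sample can contain organisms absent from the reference database.  They are
modelled as extra "hypothetical" matrix columns: to represent an unseen
organism whose 30-mer containment with reference genome g_i is at level h
(a similarity *bin*, default 0.9, 0.8, …, 0.1), genome i's 30-mer palette
column is rounded down so no entry exceeds h.  Entries already below h are
kept — a relative of g_i shares the same k-mer pattern with distant
"outgroup" references as g_i itself does.

The 50-mer behaviour of such a column is predicted from the 30-mer values by
a no-intercept cubic p(x) = c3·x³ + c2·x² + c1·x fitted to the (pckm_30,
pckm_50) pairs of a reference database; the packaged default coefficients
(−0.5141, 1.0932, 0.3824) come from a large whole-bacterial-genome fit and
are only meaningful for the (30, 50) size pair.  The cap is applied before
the polynomial map; since p is monotone increasing on [0, 1] this equals
capping the 50-mer column at p(h).

Reference and hypothetical columns for both k sizes are stacked into one
2M × M(1+B) system (B = number of bins; 2M × 10M with the default nine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_core import CommonKmerMatrix

__all__ = [
    "SimilarityPolynomial",
    "DEFAULT_POLYNOMIAL",
    "DEFAULT_BINS",
    "AugmentedSystem",
    "eval_polynomial",
    "fit_similarity_polynomial",
    "make_hypothetical_columns",
    "assemble_system",
]

DEFAULT_BINS: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class SimilarityPolynomial:
    """No-intercept cubic linking 30-mer to 50-mer containment.

    p(0) = 0 by construction (two genomes sharing no 30-mers share no
    50-mers).  ``rmse`` and ``r_squared`` are filled by the fitting
    routine and are None for hand-specified coefficients.
    """

    c3: float
    c2: float
    c1: float
    rmse: float | None = None
    r_squared: float | None = None

    @property
    def coeffs(self) -> tuple[float, float, float]:
        return (self.c3, self.c2, self.c1)

    def __call__(self, x):
        return eval_polynomial(self, x)


#: Coefficients of the packaged default 30↔50-mer polynomial.
DEFAULT_POLYNOMIAL = SimilarityPolynomial(c3=-0.5141, c2=1.0932, c1=0.3824)


def eval_polynomial(p: SimilarityPolynomial, x):
    """Evaluate p on [0, 1], clipping the result into [0, 1].

    Accepts a scalar or array; raises if any input lies outside [0, 1]
    (containment values cannot).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("polynomial argument must lie in [0, 1]")
    val = ((p.c3 * arr + p.c2) * arr + p.c1) * arr
    val = np.clip(val, 0.0, 1.0)
    return float(val) if np.isscalar(x) or arr.ndim == 0 else val


def fit_similarity_polynomial(pairs) -> SimilarityPolynomial:
    """Least-squares fit of s50 on (s30³, s30², s30), no intercept.

    ``pairs`` is a sequence of (s30, s50) containment pairs in [0, 1];
    at least 3 pairs with a full-rank design are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (s30, s50) pairs")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("containment values must lie in [0, 1]")
    x, y = arr[:, 0], arr[:, 1]
    X = np.column_stack([x**3, x**2, x])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: need >= 3 distinct nonzero s30 values")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return SimilarityPolynomial(
        c3=float(coef[0]),
        c2=float(coef[1]),
        c1=float(coef[2]),
        rmse=float(np.sqrt(rss / len(y))),
        r_squared=r2,
    )


def make_hypothetical_columns(
    col30: np.ndarray,
    h: float,
    p: SimilarityPolynomial = DEFAULT_POLYNOMIAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Cap a 30-mer palette column at similarity bin h; predict its 50-mer twin.

    Returns ``(min(h, col30), p(min(h, col30)))``.  The cap precedes the
    polynomial map, so the 50-mer column is capped at p(h).
    """
    if not 0 < h < 1:
        raise ValueError(f"similarity bin must lie in (0, 1), got {h}")
    col30 = np.asarray(col30, dtype=float)
    if np.any(col30 < 0) or np.any(col30 > 1):
        raise ValueError("palette column entries must lie in [0, 1]")
    col30_h = np.minimum(h, col30)
    col50_h = eval_polynomial(p, col30_h)
    return col30_h, np.asarray(col50_h, dtype=float)


@dataclass
class AugmentedSystem:
    """Stacked 2M × M(1+B) mixture matrix with per-column provenance.

    Rows 0..M−1 are the k=30 block, rows M..2M−1 the k=50 block.  Columns
    come in genome-ordered blocks: the reference palettes first, then one
    block per similarity bin.  ``col_meta[c] = (genome_index, bin)`` with
    bin 1.0 marking an uncapped reference column.  ``y`` holds the stacked
    sample signature once measured.
    """

    matrix: np.ndarray = field(repr=False)
    genome_ids: list[str] = field(default_factory=list)
    bins: tuple[float, ...] = DEFAULT_BINS
    col_meta: list[tuple[int, float]] = field(default_factory=list)
    y: np.ndarray | None = None

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)


def assemble_system(
    A30: CommonKmerMatrix,
    A50: CommonKmerMatrix,
    p: SimilarityPolynomial = DEFAULT_POLYNOMIAL,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> AugmentedSystem:
    """Build the stacked reference+hypothetical system from both matrices.

    Column block order is [reference | bin b1 | bin b2 | …] with genomes in
    matrix order inside each block; the reference block reproduces A30 and
    A50 verbatim.
    """
    if A30.genome_ids != A50.genome_ids:
        raise ValueError("A30 and A50 genome id ordering differs")
    M = len(A30.genome_ids)
    B = len(bins)
    mat = np.empty((2 * M, M * (1 + B)))
    mat[:M, :M] = A30.values
    mat[M:, :M] = A50.values
    col_meta: list[tuple[int, float]] = [(i, 1.0) for i in range(M)]
    for b, h in enumerate(bins):
        lo = M * (1 + b)
        for i in range(M):
            c30, c50 = make_hypothetical_columns(A30.values[:, i], h, p)
            mat[:M, lo + i] = c30
            mat[M:, lo + i] = c50
            col_meta.append((i, float(h)))
    return AugmentedSystem(
        matrix=mat,
        genome_ids=list(A30.genome_ids),
        bins=tuple(bins),
        col_meta=col_meta,
    )
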