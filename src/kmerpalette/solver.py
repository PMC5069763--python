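"""Sparsity-promoting nonnegative deconvolution of the stacked system.

The abundance vector is recovered from A x ≈ y by a nonnegative variant of
basis pursuit denoising: minimize ‖z‖₁² + λ²‖Az − y‖₂² subject to z ≥ 0.
Because z ≥ 0 makes ‖z‖₁ a linear functional (the all-ones row), the whole
problem reduces to ordinary nonnegative least squares on the augmented pair

    Ã = [1 … 1; λA],   ỹ = [0; λy]

solved with a Lawson–Hanson active-set routine.  Large λ favours fitting
the measured signature; small λ favours sparsity.  λ = 200 is the default
throughout, a good trade-off between sparsity and fit of the k-mer counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .hypothetical import AugmentedSystem

__all__ = [
    "AbundanceSolution",
    "AbundanceEntry",
    "solve_nnreg",
    "deconvolute",
    "postprocess_abundances",
    "aggregate_by_genome",
]

DEFAULT_LAMBDA = 200.0


@dataclass
class AbundanceSolution:
    """Nonnegative solution of the regularized system.

    ``x`` is aligned 1:1 with ``col_meta`` (genome_index, bin) when the
    system carries column metadata; ``residual`` is ‖Ax − y‖₂ on the
    *unscaled* system.
    """

    x: np.ndarray
    lam: float
    residual: float
    col_meta: list[tuple[int, float]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("abundance solution must be nonnegative")


@dataclass(frozen=True)
class AbundanceEntry:
    """One pruned, renormalized abundance: a (genome, bin) pair with mass."""

    genome_index: int
    bin: float
    abundance: float


def solve_nnreg(
    A: np.ndarray,
    y: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    col_meta: list[tuple[int, float]] | None = None,
    maxiter: int | None = None,
) -> AbundanceSolution:
    """Minimize ‖z‖₁² + λ²‖Az − y‖₂² over z ≥ 0 via augmented NNLS.

    Deterministic for fixed input (active-set order of the underlying
    Lawson–Hanson solver).  An all-zero y short-circuits to the zero
    vector, its exact minimizer.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != y.shape[0]:
        raise ValueError(
            f"dimension mismatch: A is {A.shape}, y has length {y.shape[0]}"
        )
    if lam <= 0:
        raise ValueError("lam must be positive")
    n = A.shape[1]
    if not np.any(y):
        return AbundanceSolution(
            x=np.zeros(n), lam=lam, residual=0.0, col_meta=col_meta
        )
    A_aug = np.vstack([np.ones((1, n)), lam * A])
    y_aug = np.concatenate([[0.0], lam * y])
    if maxiter is None:
        maxiter = max(30 * n, 300)
    x, _ = nnls(A_aug, y_aug, maxiter=maxiter)
    residual = float(np.linalg.norm(A @ x - y))
    return AbundanceSolution(x=x, lam=lam, residual=residual, col_meta=col_meta)


def deconvolute(
    system: AugmentedSystem, y: np.ndarray, lam: float = DEFAULT_LAMBDA
) -> AbundanceSolution:
    """Solve an assembled two-k system against a stacked signature."""
    sol = solve_nnreg(system.matrix, y, lam=lam, col_meta=system.col_meta)
    system.y = np.asarray(y, dtype=float)
    return sol


def objective(A: np.ndarray, y: np.ndarray, z: np.ndarray, lam: float) -> float:
    """The regularized objective ‖z‖₁² + λ²‖Az − y‖₂² at a point z ≥ 0."""
    z = np.asarray(z, dtype=float)
    r = np.asarray(A) @ z - np.asarray(y)
    return float(np.sum(z) ** 2 + lam**2 * (r @ r))


def postprocess_abundances(
    sol: AbundanceSolution, eps: float = 1e-4
) -> list[AbundanceEntry]:
    """Prune entries below eps·max(x), renormalize the rest to sum to 1.

    Emits (genome_index, bin, relative abundance) triples aligned with the
    solution's column metadata.  An empty result (everything pruned)
    warns and returns [].
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if sol.col_meta is None:
        raise ValueError("solution carries no column metadata")
    x = sol.x
    mx = x.max() if x.size else 0.0
    keep = x >= eps * mx if mx > 0 else np.zeros_like(x, dtype=bool)
    keep &= x > 0
    total = x[keep].sum()
    if total <= 0:
        warnings.warn("all abundance entries pruned; empty table")
        return []
    return [
        AbundanceEntry(
            genome_index=sol.col_meta[c][0],
            bin=sol.col_meta[c][1],
            abundance=float(x[c] / total),
        )
        for c in np.nonzero(keep)[0]
    ]


def aggregate_by_genome(
    entries: list[AbundanceEntry], n_genomes: int
) -> np.ndarray:
    """Sum relative abundance over all bins of each genome."""
    out = np.zeros(n_genomes)
    for e in entries:
        out[e.genome_index] += e.abundance
    return out
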