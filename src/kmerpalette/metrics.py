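"""Profile-comparison error metrics: divergence and false positives.

divergence = Σ log2(x*_i / x_i) over the taxa where both the true and the
predicted frequency are positive; it measures multiplicative bias and can
cancel across taxa, so an absolute variant Σ |log2(x*_i / x_i)| is exposed
behind a flag.  FP counts taxa a method predicts that are truly absent —
divergence alone never penalizes spurious calls, FP does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .taxonomy import RANKS, TaxProfile

__all__ = ["ProfilePair", "divergence", "false_positives", "align_profiles"]


@dataclass
class ProfilePair:
    """True and predicted frequencies over one shared taxon index."""

    x_true: np.ndarray
    x_pred: np.ndarray

    def __post_init__(self) -> None:
        self.x_true = np.asarray(self.x_true, dtype=float)
        self.x_pred = np.asarray(self.x_pred, dtype=float)
        if self.x_true.shape != self.x_pred.shape:
            raise ValueError("true/predicted vectors differ in length")
        if np.any(self.x_true < 0) or np.any(self.x_pred < 0):
            raise ValueError("frequencies must be nonnegative")


def divergence(pair: ProfilePair, absolute: bool = False) -> float:
    """Signed (default) or absolute sum of log2 prediction/truth ratios.

    Only indices with both entries positive contribute; disjoint support
    yields 0 with a warning.
    """
    both = (pair.x_true > 0) & (pair.x_pred > 0)
    if not both.any():
        warnings.warn("no taxon has both true and predicted frequency > 0")
        return 0.0
    terms = np.log2(pair.x_pred[both] / pair.x_true[both])
    return float(np.abs(terms).sum() if absolute else terms.sum())


def false_positives(pair: ProfilePair) -> int:
    """Number of taxa predicted present (x* > 0) but truly absent (x = 0)."""
    return int(np.sum((pair.x_pred > 0) & (pair.x_true == 0)))


def align_profiles(
    truth: TaxProfile, pred: TaxProfile, rank: str
) -> tuple[ProfilePair, list[str]]:
    """Align two profiles at one rank by taxid (frequencies in [0, 1]).

    Taxa present in only one profile get 0 on the missing side.  Returns
    the aligned pair and the shared taxid order.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    t = truth.at_rank(rank)
    p = pred.at_rank(rank)
    taxids = sorted(set(t) | set(p))
    x_true = np.array([t.get(tid, 0.0) for tid in taxids]) / 100.0
    x_pred = np.array([p.get(tid, 0.0) for tid in taxids]) / 100.0
    return ProfilePair(x_true=x_true, x_pred=x_pred), taxids
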