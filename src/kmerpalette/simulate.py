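"""Deterministic synthetic genomes, diverged strains and shotgun reads.

Everything downstream is testable without downloads: genomes are i.i.d.
base strings at a chosen GC content, related strains are made by per-base
substitution at rate μ (no indels — so the survival law E[pckm_k] ≈ (1−μ)^k
is exact and can serve as an oracle), and samples are error-bearing reads
drawn uniformly from a genome mixture with random strand, matching the
uniform-sampling assumption behind the linear mixture relation A x ≈ y.
Phred strings encode the simulated substitution-error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_core import SequenceRecord, reverse_complement

__all__ = [
    "CommunitySpec",
    "random_genome",
    "mutate_genome",
    "mutate_variable_regions",
    "strain_panel",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))
# index of the 3 substitution alternatives for each base
_ALT = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def random_genome(
    length: int, seed: int, gc: float = 0.5, genome_id: str | None = None
) -> SequenceRecord:
    """I.i.d. random genome with P(G) + P(C) = gc; reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return SequenceRecord(id=genome_id or f"genome_{seed}", seq=seq)


def mutate_genome(
    record: SequenceRecord, mu: float, seed: int, genome_id: str | None = None
) -> SequenceRecord:
    """Substitute each base independently with probability mu (no indels).

    Substitutions are uniform over the three alternative bases, so a
    k-mer survives unchanged with probability (1 − mu)^k.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    hits = np.nonzero(rng.random(len(seq)) < mu)[0]
    for i in hits:
        base = seq[i]
        if base in _ALT:
            seq[i] = _ALT[base][rng.integers(3)]
    return SequenceRecord(
        id=genome_id or f"{record.id}_mu{mu:g}", seq="".join(seq)
    )


def mutate_variable_regions(
    record: SequenceRecord,
    mu: float,
    mask: np.ndarray,
    seed: int,
    genome_id: str | None = None,
) -> SequenceRecord:
    """Substitute at rate mu, but only at positions where ``mask`` is True.

    Models site-heterogeneous evolution at block scale: positions outside
    the mask are perfectly conserved across the panel.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must lie in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(record.seq):
        raise ValueError("mask length does not match the sequence")
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    hits = np.nonzero((rng.random(len(seq)) < mu) & mask)[0]
    for i in hits:
        if seq[i] in _ALT:
            seq[i] = _ALT[seq[i]][rng.integers(3)]
    return SequenceRecord(
        id=genome_id or f"{record.id}_var{mu:g}", seq="".join(seq)
    )


def strain_panel(
    length: int,
    rates: tuple[float, ...],
    seed: int,
    block: int = 500,
    gc: float = 0.5,
    prefix: str = "strain",
) -> tuple[SequenceRecord, list[SequenceRecord], np.ndarray]:
    """Panel of strains sharing a conserved core: base, strains and mask.

    The ancestral genome alternates conserved and variable blocks of
    ``block`` bp; strain i substitutes variable-block positions at
    ``rates[i]``.  This mimics the core/accessory structure of real
    bacterial strain panels: pairwise k-mer sharing is dominated by the
    untouched core, so a further-diverged relative of one strain keeps
    (approximately) its ancestor's sharing pattern with the other strains
    — the assumption behind hypothetical-organism columns.  Uniform
    i.i.d. divergence (``mutate_genome``) deliberately violates that
    assumption and is kept separate.
    """
    if not rates:
        raise ValueError("need at least one strain rate")
    base = random_genome(length, seed, gc=gc, genome_id=f"{prefix}_base")
    mask = np.zeros(length, dtype=bool)
    for s in range(0, length, 2 * block):
        mask[s + block : s + 2 * block] = True
    strains = [
        mutate_variable_regions(
            base, r, mask, seed=seed + 1 + i, genome_id=f"{prefix}{i}"
        )
        for i, r in enumerate(rates)
    ]
    return base, strains, mask


@dataclass
class CommunitySpec:
    """Recipe for a synthetic community sample.

    ``genomes`` lists (genome_id, length, seed) triples; ``mixture`` gives
    the per-genome read proportions (the ground-truth profile x).
    """

    genomes: tuple[tuple[str, int, int], ...]
    mixture: tuple[float, ...]
    n_reads: int
    read_length: int = 100
    error_rate: float = 0.0
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixture, dtype=float)
        if len(mix) != len(self.genomes):
            raise ValueError("mixture length does not match genome count")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixture must be nonnegative and sum to 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        for gid, length, _ in self.genomes:
            if length < self.read_length:
                raise ValueError(
                    f"genome {gid!r} shorter than the read length"
                )

    def build_genomes(self) -> list[SequenceRecord]:
        return [
            random_genome(length, seed, gc=self.gc, genome_id=gid)
            for gid, length, seed in self.genomes
        ]


def _phred_for_error(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, max(2, round(-10 * np.log10(error_rate))))


def simulate_reads(
    spec: CommunitySpec,
    genomes: list[SequenceRecord] | None = None,
) -> tuple[list[SequenceRecord], dict[str, float]]:
    """Draw reads from a genome mixture; returns (reads, truth proportions).

    Read counts per genome are multinomial in the mixture weights, start
    positions uniform over the linear genome (no wrap-around), strand
    random, substitution errors i.i.d. at ``error_rate`` with a constant
    matching Phred string.  Deterministic per spec seed.
    """
    if genomes is None:
        genomes = spec.build_genomes()
    if len(genomes) != len(spec.genomes):
        raise ValueError("genome list does not match spec")
    rng = np.random.default_rng(spec.seed)
    r = spec.read_length
    q = _phred_for_error(spec.error_rate)
    counts = rng.multinomial(spec.n_reads, spec.mixture)
    reads: list[SequenceRecord] = []
    idx = 0
    for g, n_g in zip(genomes, counts):
        L = len(g.seq)
        starts = rng.integers(0, L - r + 1, size=n_g)
        strands = rng.random(n_g) < 0.5
        for s, rev in zip(starts, strands):
            seq = g.seq[s : s + r]
            if rev:
                seq = reverse_complement(seq)
            if spec.error_rate > 0:
                chars = list(seq)
                hits = np.nonzero(rng.random(r) < spec.error_rate)[0]
                for i in hits:
                    if chars[i] in _ALT:
                        chars[i] = _ALT[chars[i]][rng.integers(3)]
                seq = "".join(chars)
            reads.append(
                SequenceRecord(
                    id=f"read_{idx}_{g.id}", seq=seq, qual=(q,) * r
                )
            )
            idx += 1
    truth = {gid: float(w) for (gid, _, _), w in zip(spec.genomes, spec.mixture)}
    return reads, truth
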