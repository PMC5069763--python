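import numpy as np
import pytest

from kmerpalette.kmer_core import SequenceRecord
from kmerpalette.taxonomy import RANKS, TaxonomyTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_kmer_counts(seqs, k, canonical=False):
    """Independent window-scan oracle: dict of k-mer -> count."""
    counts = {}
    n = 0
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            if canonical:
                rc = "".join(_COMP[c] for c in reversed(w))
                w = min(w, rc)
            counts[w] = counts.get(w, 0) + 1
            n += 1
    return counts, n


def naive_pckm(seqs_i, seqs_j, k, canonical=False):
    """Oracle pckm: multiplicity-weighted containment of j's k-mers in i."""
    ci, _ = naive_kmer_counts(seqs_i, k, canonical)
    cj, nj = naive_kmer_counts(seqs_j, k, canonical)
    shared = sum(c for w, c in cj.items() if w in ci)
    return shared / nj


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def make_lineage(*names):
    """Complete 8-rank lineage from per-rank taxon labels."""
    assert len(names) == len(RANKS)
    return tuple((f"{r[:2]}_{n}", f"{r} {n}") for r, n in zip(RANKS, names))


def strain_lineage(strain, species="sp1", genus="g1", family="f1",
                   order="o1", klass="c1", phylum="p1", kingdom="k1"):
    return make_lineage(kingdom, phylum, klass, order, family, genus,
                        species, strain)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def three_genome_taxonomy():
    """Two strains of one species plus one cross-genus genome."""
    return TaxonomyTable(
        {
            "gA": strain_lineage("stA"),
            "gB": strain_lineage("stB"),
            "gC": strain_lineage("stC", species="sp2", genus="g2"),
        }
    )


def records(*seqs):
    return [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)]
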