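"""k-mer enumeration, the pckm containment score, and its matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerpalette.kmer_core import (
    CommonKmerMatrix,
    SequenceRecord,
    build_common_kmer_matrix,
    enumerate_kmers,
    occ,
    pckm,
    reverse_complement,
)
from kmerpalette.simulate import mutate_genome, random_genome

from .conftest import naive_kmer_counts, naive_pckm, random_dna, records


@pytest.mark.parametrize(
    "v,w,expected",
    [
        ("AA", "AAAA", 3),
        ("ACG", "TTTT", 0),
        ("ACGT", "ACGT", 1),
        ("A", "", 0),
        ("AB", "AABAB", 2),
        ("TT", "ATTTA", 2),
    ],
)
def test_occ_counts_overlapping_occurrences(v, w, expected):
    assert occ(v, w) == expected


def test_occ_rejects_empty_query():
    with pytest.raises(ValueError):
        occ("", "ACGT")


class TestEnumerateKmers:
    def test_counts_with_multiplicity(self):
        ms = enumerate_kmers(records("AAAT"), k=2, canonical=False)
        assert dict(ms.counts) == {"AA": 2, "AT": 1}
        assert ms.total == ms.n_windows == 3

    def test_windows_with_non_acgt_are_dropped(self):
        ms = enumerate_kmers(records("ANAT"), k=2, canonical=False)
        assert dict(ms.counts) == {"AT": 1}
        assert ms.total == 1

    def test_no_window_spans_record_boundary(self):
        ms = enumerate_kmers(records("AC", "GT"), k=2, canonical=False)
        assert dict(ms.counts) == {"AC": 1, "GT": 1}

    def test_canonical_collapses_reverse_complements(self):
        # ACG and its revcomp CGT collapse onto ACG
        ms = enumerate_kmers(records("ACG", "CGT"), k=3, canonical=True)
        assert dict(ms.counts) == {"ACG": 2}

    def test_lowercase_input_is_uppercased(self):
        ms = enumerate_kmers(records("aaat"), k=2, canonical=False)
        assert dict(ms.counts) == {"AA": 2, "AT": 1}

    def test_empty_input_gives_empty_multiset(self):
        ms = enumerate_kmers([], k=5)
        assert ms.total == 0 and not ms.counts

    @given(
        st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=60), max_size=4),
        st.sampled_from([1, 2, 3, 7]),
        st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_window_scan(self, seqs, k, canonical):
        ms = enumerate_kmers(
            [SequenceRecord(id=f"r{i}", seq=s) for i, s in enumerate(seqs)],
            k,
            canonical=canonical,
        )
        expected, n = naive_kmer_counts(seqs, k, canonical)
        assert dict(ms.counts) == expected
        assert ms.n_windows == n


class TestPckm:
    def test_self_containment_is_one(self, rng):
        ms = enumerate_kmers(records(random_dna(rng, 100)), k=5)
        assert pckm(ms, ms) == 1.0

    def test_asymmetric_worked_example(self):
        # g_i=AAAT, g_j=AAAA at k=2: all 3 of j's AA-windows are shared;
        # only 2 of i's 3 windows (AA,AA) appear in j.
        ms_i = enumerate_kmers(records("AAAT"), 2, canonical=False)
        ms_j = enumerate_kmers(records("AAAA"), 2, canonical=False)
        assert pckm(ms_i, ms_j) == 1.0
        assert pckm(ms_j, ms_i) == pytest.approx(2 / 3)

    def test_disjoint_kmer_sets_give_zero(self):
        ms_i = enumerate_kmers(records("AAAA"), 2, canonical=False)
        ms_j = enumerate_kmers(records("CCCC"), 2, canonical=False)
        assert pckm(ms_i, ms_j) == 0.0

    def test_mismatched_k_is_an_error(self):
        ms2 = enumerate_kmers(records("ACGT"), 2)
        ms3 = enumerate_kmers(records("ACGT"), 3)
        with pytest.raises(ValueError, match="mismatch"):
            pckm(ms2, ms3)

    def test_empty_reference_is_an_error(self):
        ms = enumerate_kmers(records("ACGT"), 2)
        empty = enumerate_kmers([], 2)
        with pytest.raises(ValueError):
            pckm(ms, empty)

    def test_denominator_counts_only_valid_windows(self):
        # with an N in g_j, self-containment must still be exactly 1
        ms = enumerate_kmers(records("ACGTNACGT"), 3, canonical=False)
        assert pckm(ms, ms) == 1.0


class TestCommonKmerMatrix:
    def test_single_genome_matrix(self, rng):
        m = build_common_kmer_matrix([records(random_dna(rng, 50))], k=4)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1.0

    def test_identical_genomes_all_ones(self, rng):
        g = random_dna(rng, 80)
        m = build_common_kmer_matrix(
            [records(g), records(g)], k=5, genome_ids=["a", "b"]
        )
        assert np.all(m.values == 1.0)

    @pytest.mark.parametrize("k", [3, 5, 11, 31])
    def test_matches_brute_force_oracle(self, rng, k):
        genomes = [[random_dna(rng, int(rng.integers(50, 2000)))] for _ in range(5)]
        recs = [records(*g) for g in genomes]
        m = build_common_kmer_matrix(
            recs, k=k, canonical=False, genome_ids=[f"g{i}" for i in range(5)]
        )
        for i in range(5):
            for j in range(5):
                assert m.values[i, j] == naive_pckm(genomes[i], genomes[j], k)

    def test_diagonal_one_and_range(self, rng):
        recs = [records(random_dna(rng, 300)) for _ in range(4)]
        m = build_common_kmer_matrix(recs, k=7, genome_ids=list("abcd"))
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.all((m.values >= 0) & (m.values <= 1))

    def test_zero_window_genome_error_names_genome(self):
        with pytest.raises(ValueError, match="tiny"):
            build_common_kmer_matrix(
                [records("ACGTACGTAC"), records("NNNN")],
                k=4,
                genome_ids=["ok", "tiny"],
            )

    def test_csv_round_trip(self, rng, tmp_path):
        recs = [records(random_dna(rng, 200)) for _ in range(3)]
        m = build_common_kmer_matrix(recs, k=6, genome_ids=list("xyz"))
        m.to_csv(tmp_path / "m.csv")
        back = CommonKmerMatrix.from_csv(tmp_path / "m.csv", k=6)
        assert back.genome_ids == m.genome_ids
        np.testing.assert_allclose(back.values, m.values, rtol=1e-10)


class TestMutationBehaviour:
    def test_pckm_decays_with_k_for_related_pairs(self):
        base = random_genome(20_000, seed=3)
        mut = mutate_genome(base, 0.02, seed=4)
        vals = []
        for k in (11, 21, 31):
            ms_b = enumerate_kmers([base], k)
            ms_m = enumerate_kmers([mut], k)
            vals.append(pckm(ms_b, ms_m))
        assert vals[0] > vals[1] > vals[2]

    def test_survival_law_small_scale(self):
        """E[pckm_k] tracks (1-mu)^k for substitution-only divergence."""
        mu, k, reps = 0.01, 21, 8
        obs = []
        for r in range(reps):
            g = random_genome(30_000, seed=100 + r)
            m = mutate_genome(g, mu, seed=200 + r)
            obs.append(
                pckm(enumerate_kmers([g], k), enumerate_kmers([m], k))
            )
        obs = np.array(obs)
        expected = (1 - mu) ** k
        se = obs.std(ddof=1) / np.sqrt(reps)
        assert abs(obs.mean() - expected) <= 3 * se + 1e-3


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACG") == "CGTT"
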