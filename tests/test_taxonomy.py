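"""LCA mapping of hypothetical mass and rank-wise profile construction."""

import numpy as np
import pytest

from kmerpalette.kmer_core import CommonKmerMatrix
from kmerpalette.solver import AbundanceEntry
from kmerpalette.taxonomy import (
    RANKS,
    TaxonomyTable,
    build_profile,
    fixed_rank_for_bin,
    lca_rank,
    map_hypothetical,
)

from .conftest import make_lineage, strain_lineage


class TestLcaRank:
    def test_identical_lineages_meet_at_strain(self):
        lin = strain_lineage("st1")
        r, taxon = lca_rank(lin, lin)
        assert RANKS[r] == "strain" and taxon == lin[-1]

    def test_same_genus_different_species_meet_at_genus(self):
        a = strain_lineage("st1", species="sp1")
        b = strain_lineage("st2", species="sp2")
        r, taxon = lca_rank(a, b)
        assert RANKS[r] == "genus"

    def test_different_superkingdoms_have_no_ranked_lca(self):
        a = strain_lineage("st1", kingdom="bact")
        b = strain_lineage("st2", kingdom="arch")
        assert lca_rank(a, b) is None

    def test_malformed_lineage_is_an_error(self):
        with pytest.raises(ValueError):
            lca_rank(strain_lineage("st1"), (("x", "y"),))


@pytest.mark.parametrize(
    "h,rank",
    [
        (1.0, "strain"),
        (0.9, "species"),
        (0.8, "genus"),
        (0.7, "family"),
        (0.6, "order"),
        (0.5, "class"),
        (0.4, "phylum"),
        (0.3, "superkingdom"),
        (0.1, "superkingdom"),
    ],
)
def test_fixed_rank_map(h, rank):
    assert RANKS[fixed_rank_for_bin(h)] == rank


def _matrix(values, ids):
    return CommonKmerMatrix(
        k=30, genome_ids=ids, values=np.asarray(values, dtype=float)
    )


class TestMapHypothetical:
    def test_bin_matching_same_species_partner_maps_to_species(self):
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", species="sp1"),
                "gB": strain_lineage("stB", species="sp1"),
            }
        )
        A30 = _matrix([[1.0, 0.9], [0.9, 1.0]], ["gA", "gB"])
        r, taxon = map_hypothetical((0, 0.9), A30, tax)
        assert RANKS[r] == "species"

    def test_reference_column_maps_to_strain(self):
        tax = TaxonomyTable({"gA": strain_lineage("stA")})
        A30 = _matrix([[1.0]], ["gA"])
        r, taxon = map_hypothetical((0, 1.0), A30, tax)
        assert RANKS[r] == "strain" and taxon[0] == "st_stA"

    def test_cross_kingdom_partner_maps_to_superkingdom_depth(self):
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", kingdom="bact"),
                "gB": strain_lineage("stB", kingdom="arch"),
            }
        )
        A30 = _matrix([[1.0, 0.1], [0.1, 1.0]], ["gA", "gB"])
        r, taxon = map_hypothetical((0, 0.1), A30, tax)
        assert r == 0 and taxon == tax["gA"][0]

    def test_single_genome_falls_back_to_fixed_rank(self):
        tax = TaxonomyTable({"gA": strain_lineage("stA")})
        A30 = _matrix([[1.0]], ["gA"])
        r, _ = map_hypothetical((0, 0.9), A30, tax)
        assert RANKS[r] == "species"

    def test_nearest_partner_fallback_outside_delta(self):
        # no partner within delta of 0.5; nearest (0.8, same species) wins
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", species="sp1"),
                "gB": strain_lineage("stB", species="sp1"),
                "gC": strain_lineage("stC", species="sp2", genus="g2"),
            }
        )
        A30 = _matrix(
            [[1.0, 0.8, 0.05], [0.8, 1.0, 0.05], [0.05, 0.05, 1.0]],
            ["gA", "gB", "gC"],
        )
        r, _ = map_hypothetical((0, 0.5), A30, tax, delta=0.05)
        assert RANKS[r] == "species"


class TestBuildProfile:
    def _two_strain_setup(self):
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", species="sp1"),
                "gB": strain_lineage("stB", species="sp1"),
            }
        )
        A30 = _matrix([[1.0, 0.9], [0.9, 1.0]], ["gA", "gB"])
        return tax, A30

    def test_single_reference_full_lineage_at_100(self):
        tax = TaxonomyTable({"gA": strain_lineage("stA")})
        A30 = _matrix([[1.0]], ["gA"])
        prof = build_profile([AbundanceEntry(0, 1.0, 1.0)], tax, A30)
        assert len(prof.entries) == len(RANKS)
        assert all(e.percentage == pytest.approx(100.0) for e in prof.entries)

    def test_two_strains_sum_to_species(self):
        tax, A30 = self._two_strain_setup()
        prof = build_profile(
            [AbundanceEntry(0, 1.0, 0.5), AbundanceEntry(1, 1.0, 0.5)],
            tax,
            A30,
        )
        species = prof.at_rank("species")
        strains = prof.at_rank("strain")
        assert species == {"sp_sp1": pytest.approx(100.0)}
        assert strains == {
            "st_stA": pytest.approx(50.0),
            "st_stB": pytest.approx(50.0),
        }

    def test_hypothetical_mass_joins_species_level(self):
        tax, A30 = self._two_strain_setup()
        prof = build_profile(
            [AbundanceEntry(0, 1.0, 0.8), AbundanceEntry(0, 0.9, 0.2)],
            tax,
            A30,
        )
        # the 0.9-bin entry maps to species (LCA of gA and gB)
        assert prof.at_rank("species")["sp_sp1"] == pytest.approx(100.0)
        assert prof.at_rank("strain")["st_stA"] == pytest.approx(80.0)

    def test_upward_consistency(self):
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", species="sp1"),
                "gB": strain_lineage("stB", species="sp2"),
            }
        )
        A30 = _matrix([[1.0, 0.55], [0.55, 1.0]], ["gA", "gB"])
        prof = build_profile(
            [
                AbundanceEntry(0, 1.0, 0.4),
                AbundanceEntry(0, 0.5, 0.35),
                AbundanceEntry(1, 1.0, 0.25),
            ],
            tax,
            A30,
        )
        by_rank = {r: prof.at_rank(r) for r in RANKS}
        for parent_rank, child_rank in zip(RANKS, RANKS[1:]):
            for e in prof.entries:
                if e.rank != child_rank:
                    continue
                parent_id = e.taxpath.split("|")[-2]
                assert (
                    by_rank[parent_rank][parent_id]
                    >= e.percentage - 1e-9
                )

    def test_mode_rank_ordering(self):
        # LCA says genus (partner at bin 0.5 is same-genus), fixed says class
        tax = TaxonomyTable(
            {
                "gA": strain_lineage("stA", species="sp1"),
                "gB": strain_lineage("stB", species="sp2"),
            }
        )
        A30 = _matrix([[1.0, 0.5], [0.5, 1.0]], ["gA", "gB"])
        abund = [AbundanceEntry(0, 0.5, 1.0)]

        def deepest_rank(mode):
            prof = build_profile(abund, tax, A30, mode=mode)
            return max(RANKS.index(e.rank) for e in prof.entries)

        d_default = deepest_rank("default")
        assert deepest_rank("sensitive") >= d_default
        assert deepest_rank("specific") <= d_default

    def test_unknown_mode_is_an_error(self):
        tax, A30 = self._two_strain_setup()
        with pytest.raises(ValueError):
            build_profile([AbundanceEntry(0, 1.0, 1.0)], tax, A30, mode="bogus")

    def test_unnormalized_abundances_are_an_error(self):
        tax, A30 = self._two_strain_setup()
        with pytest.raises(ValueError, match="normalized"):
            build_profile([AbundanceEntry(0, 1.0, 0.4)], tax, A30)

    def test_superkingdom_conservation(self):
        tax, A30 = self._two_strain_setup()
        prof = build_profile(
            [
                AbundanceEntry(0, 1.0, 0.3),
                AbundanceEntry(0, 0.9, 0.3),
                AbundanceEntry(1, 0.2, 0.4),
            ],
            tax,
            A30,
        )
        assert sum(prof.at_rank("superkingdom").values()) == pytest.approx(
            100.0, abs=1e-6
        )


def test_taxonomy_tsv_round_trip(tmp_path):
    tax = TaxonomyTable(
        {
            "gA": strain_lineage("stA"),
            "gB": strain_lineage("stB", species="sp2"),
        }
    )
    tax.to_tsv(tmp_path / "tax.tsv")
    back = TaxonomyTable.from_tsv(tmp_path / "tax.tsv")
    assert back.lineages == tax.lineages


def test_incomplete_lineage_rejected():
    with pytest.raises(ValueError):
        TaxonomyTable({"gA": (("k1", "k"),)})
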