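import pytest
from hypothesis import given
from hypothesis import strategies as st

from taxopep import (
    RankedMapping,
    RunConfig,
    ScoredPeptide,
    TaxonMapping,
    aggregate_to_rank,
    filter_peptides,
    select_candidates,
    taxon_weights,
)
from taxopep.taxonomy import TaxonomyError


def _mapping(seq, taxa, proteins=1):
    return TaxonMapping(seq, frozenset(taxa), proteins)


class TestFilterPeptides:
    def test_protein_count_cutoff_is_strict(self, toy_taxonomy):
        cfg = RunConfig(protein_count_cutoff=10_000)
        mappings = [
            _mapping("OVER", {101}, 10_001),
            _mapping("ATCUT", {101}, 10_000),
        ]
        kept = filter_peptides(mappings, toy_taxonomy, cfg)
        assert [m.sequence for m in kept] == ["ATCUT"]

    def test_restriction_to_clade_drops_outside_peptides(self, toy_taxonomy):
        cfg = RunConfig(restrict_taxid=2)  # bacteria only
        mappings = [
            _mapping("BACT", {101}),
            _mapping("EUK", {301}),
            _mapping("BOTH", {101, 301}),
        ]
        kept = filter_peptides(mappings, toy_taxonomy, cfg)
        by_seq = {m.sequence: m.taxa for m in kept}
        assert set(by_seq) == {"BACT", "BOTH"}
        assert by_seq["BOTH"] == {101}  # intersected with the clade

    def test_unknown_restriction_taxid_errors(self, toy_taxonomy):
        with pytest.raises(TaxonomyError):
            filter_peptides([], toy_taxonomy, RunConfig(restrict_taxid=4242))

    def test_unmapped_records_removed(self, toy_taxonomy):
        kept = filter_peptides(
            [_mapping("X", set(), 0), _mapping("Y", {101})], toy_taxonomy, RunConfig()
        )
        assert [m.sequence for m in kept] == ["Y"]


class TestAggregateToRank:
    def test_strains_of_one_species_merge(self, toy_taxonomy):
        (r,) = aggregate_to_rank([_mapping("P", {1011, 1012})], toy_taxonomy, "species")
        assert r.taxa_at_rank == {101}
        assert r.degeneracy == 1

    def test_taxon_without_rank_ancestor_dropped(self, toy_taxonomy):
        # superkingdom node 2 has no species ancestor
        (r,) = aggregate_to_rank([_mapping("P", {2, 101})], toy_taxonomy, "species")
        assert r.taxa_at_rank == {101}

    def test_peptide_with_no_rank_ancestors_removed(self, toy_taxonomy):
        assert aggregate_to_rank([_mapping("P", {2})], toy_taxonomy, "species") == []

    def test_native_rank_is_identity(self, toy_taxonomy):
        (r,) = aggregate_to_rank([_mapping("P", {101, 111})], toy_taxonomy, "species")
        assert r.taxa_at_rank == {101, 111}

    def test_genus_aggregation(self, toy_taxonomy):
        (r,) = aggregate_to_rank([_mapping("P", {101, 102, 111})], toy_taxonomy, "genus")
        assert r.taxa_at_rank == {10, 11}
        assert r.degeneracy == 2


class TestTaxonWeights:
    def test_psm_mass_split_by_degeneracy(self):
        peptides = [ScoredPeptide("P1", 0.9, 2)]
        ranked = [RankedMapping("P1", frozenset({5, 6}))]
        w = taxon_weights(peptides, ranked)
        assert w[5] == pytest.approx(1.0)
        assert w[6] == pytest.approx(1.0)

    def test_weights_accumulate_over_peptides(self):
        peptides = [ScoredPeptide("P1", 0.9, 2), ScoredPeptide("P2", 0.8, 3)]
        ranked = [
            RankedMapping("P1", frozenset({5, 6})),
            RankedMapping("P2", frozenset({5})),
        ]
        assert taxon_weights(peptides, ranked)[5] == pytest.approx(4.0)

    def test_unmapped_taxon_gets_no_entry(self):
        w = taxon_weights([ScoredPeptide("P1", 0.9)], [RankedMapping("P1", frozenset({5}))])
        assert 7 not in w

    def test_missing_score_record_is_consistency_error(self):
        with pytest.raises(ValueError, match="without score"):
            taxon_weights([], [RankedMapping("P1", frozenset({5}))])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=20),  # psm count
                st.sets(st.integers(min_value=1, max_value=9), min_size=1, max_size=5),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_total_weight_conserves_total_psm_mass(self, rows):
        """Each peptide distributes exactly its PSM count across its taxa."""
        peptides = [ScoredPeptide(f"P{i}", 0.5, psm) for i, (psm, _) in enumerate(rows)]
        ranked = [RankedMapping(f"P{i}", frozenset(taxa)) for i, (_, taxa) in enumerate(rows)]
        w = taxon_weights(peptides, ranked)
        assert sum(w.values()) == pytest.approx(sum(p.psm_count for p in peptides), abs=1e-9)

    @given(
        st.sets(st.integers(min_value=1, max_value=6), min_size=1, max_size=4),
        st.integers(min_value=1, max_value=10),
    )
    def test_raising_psm_count_never_lowers_weights(self, taxa, psm):
        ranked = [RankedMapping("P", frozenset(taxa))]
        lo = taxon_weights([ScoredPeptide("P", 0.5, psm)], ranked)
        hi = taxon_weights([ScoredPeptide("P", 0.5, psm + 1)], ranked)
        assert all(hi[t] >= lo[t] for t in taxa)


class TestSelectCandidates:
    def test_top_k_by_weight(self):
        ranked = [
            RankedMapping("P1", frozenset({1, 2})),
            RankedMapping("P2", frozenset({1, 3})),
        ]
        weights = {1: 3.0, 2: 2.0, 3: 1.0}
        # no taxon is a sole mapping, so pure top-k applies
        cs = select_candidates(weights, ranked, RunConfig(taxa_limit=2))
        assert cs.taxids == [1, 2]

    def test_unique_peptide_taxon_always_included(self):
        ranked = [RankedMapping(f"P{t}", frozenset({1, t})) for t in (2, 3, 4, 5)]
        ranked.append(RankedMapping("UNIQ", frozenset({6})))
        weights = {1: 10.0, 2: 5.0, 3: 4.0, 4: 3.0, 5: 2.0, 6: 1.0}  # 6 ranked last
        cs = select_candidates(weights, ranked, RunConfig(taxa_limit=2))
        assert 6 in cs.taxids
        assert len(cs.taxids) >= 3
        assert cs.unique_counts[6] >= 1

    def test_shared_peptide_becomes_unique_when_partner_excluded(self):
        ranked = [
            RankedMapping("SHARED", frozenset({1, 9})),
            RankedMapping("A1", frozenset({1})),
            RankedMapping("B1", frozenset({2})),
        ]
        weights = {1: 5.0, 2: 4.0, 9: 0.5}
        cs = select_candidates(weights, ranked, RunConfig(taxa_limit=2))
        assert 9 not in cs.taxids
        assert cs.peptide_edges["SHARED"] == {1}
        assert cs.unique_counts[1] == 2  # A1 plus SHARED, now unique in-graph

    def test_weight_ties_broken_by_taxid(self):
        ranked = [RankedMapping("P", frozenset({3, 7}))]
        weights = {3: 1.0, 7: 1.0}
        cs = select_candidates(weights, ranked, RunConfig(taxa_limit=1))
        assert cs.taxids[0] == 3

    def test_deterministic(self, default_community):
        from taxopep.model import TaxonInferenceModel

        model = TaxonInferenceModel(
            default_community.peptides,
            default_community.mappings,
            default_community.taxonomy,
        )
        a = model.build_candidates()
        b = model.build_candidates()
        assert a.taxa == b.taxa
        assert a.peptide_edges == b.peptide_edges
        assert a.unique_counts == b.unique_counts
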