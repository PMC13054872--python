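import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from taxopep import (
    CandidateSet,
    GraphParams,
    PosteriorResult,
    RunConfig,
    cluster_taxa,
    posterior_entropy,
    rank_biased_overlap,
    select_parameters,
    taxon_similarity,
)
from taxopep.selection import ENTROPY_FLOOR


def rbo_reference(a, b, p):
    """Direct summation of the extrapolated rank-biased overlap definition,
    computing each prefix overlap with explicit set intersections."""
    d = min(len(a), len(b))
    overlaps = [len(set(a[:k]) & set(b[:k])) for k in range(1, d + 1)]
    tail = sum(overlaps[k - 1] / k * p**k for k in range(1, d + 1))
    return overlaps[d - 1] / d * p**d + (1 - p) / p * tail


class TestTaxonSimilarity:
    def test_identical_sets(self):
        assert taxon_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert taxon_similarity({"a"}, {"b"}) == 0.0

    def test_subset_is_fully_similar_under_min_normalization(self):
        assert taxon_similarity({"p1", "p2", "p3"}, {"p1", "p2"}) == 1.0

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            taxon_similarity(set(), set())


def _candidates(weights):
    return CandidateSet(
        taxa=sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])),
        peptide_edges={},
        unique_counts={t: 0 for t in weights},
    )


class TestClusterTaxa:
    def test_identical_taxa_cluster_under_larger_head(self):
        detected = {1: {"a", "b", "c"}, 2: {"a", "b"}}
        cl = cluster_taxa(_candidates({1: 1.0, 2: 2.0}), detected, threshold=0.9)
        assert cl.heads == [1]  # head has most detected peptides
        assert cl.members[1] == {1, 2}

    def test_threshold_is_inclusive(self):
        # similarity exactly 0.9: joins; just below: separate cluster
        detected_at = {1: set(f"p{i}" for i in range(10)), 2: set(f"p{i}" for i in range(9)) | {"x"}}
        cl = cluster_taxa(_candidates({1: 2.0, 2: 1.0}), detected_at, threshold=0.9)
        assert len(cl.heads) == 1
        detected_below = {1: set(f"p{i}" for i in range(100)),
                          2: set(f"p{i}" for i in range(89)) | set(f"x{i}" for i in range(11))}
        cl = cluster_taxa(_candidates({1: 2.0, 2: 1.0}), detected_below, threshold=0.9)
        assert len(cl.heads) == 2

    def test_single_taxon_is_its_own_head(self):
        cl = cluster_taxa(_candidates({5: 1.0}), {5: {"a"}}, threshold=0.9)
        assert cl.heads == [5] and cl.members[5] == {5}

    def test_heads_ordered_by_weight(self):
        detected = {1: {"a"}, 2: {"b"}, 3: {"c"}}
        cl = cluster_taxa(_candidates({1: 1.0, 2: 3.0, 3: 2.0}), detected, threshold=0.9)
        assert cl.heads == [2, 3, 1]

    @given(
        st.dictionaries(
            st.integers(min_value=1, max_value=12),
            st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6),
            min_size=1,
            max_size=10,
        )
    )
    def test_clusters_partition_all_candidates(self, detected):
        weights = {t: float(len(s)) for t, s in detected.items()}
        cl = cluster_taxa(_candidates(weights), detected, threshold=0.9)
        seen = [t for h in cl.heads for t in cl.members[h]]
        assert sorted(seen) == sorted(detected)  # disjoint cover

    def test_heads_pairwise_below_threshold(self):
        detected = {
            1: {"a", "b", "c", "d"},
            2: {"a", "b", "c"},
            3: {"x", "y", "z"},
            4: {"x", "y", "w"},
        }
        cl = cluster_taxa(_candidates({t: 1.0 for t in detected}), detected, 0.9)
        for h1, h2 in itertools.combinations(cl.heads, 2):
            assert taxon_similarity(detected[h1], detected[h2]) < 0.9


class TestRankBiasedOverlap:
    @pytest.mark.parametrize("p", [0.5, 0.9, 0.99])
    def test_identical_lists(self, p):
        assert rank_biased_overlap([1, 2, 3], [1, 2, 3], p) == pytest.approx(1.0)

    def test_disjoint_lists(self):
        assert rank_biased_overlap([1, 2], [3, 4], 0.9) == 0.0

    def test_swapped_pair_matches_direct_summation(self):
        got = rank_biased_overlap(["A", "B"], ["B", "A"], 0.9)
        assert got == pytest.approx(rbo_reference(["A", "B"], ["B", "A"], 0.9), abs=1e-12)

    def test_nonconjoint_lists_supported(self):
        a, b = [1, 2, 3, 4], [9, 2, 1]
        assert rank_biased_overlap(a, b, 0.9) == pytest.approx(rbo_reference(a, b, 0.9), abs=1e-12)

    @given(
        st.permutations(list(range(4))),
        st.permutations(list(range(4))),
        st.sampled_from([0.5, 0.8, 0.9, 0.95]),
    )
    def test_symmetry_and_agreement_with_definition(self, a, b, p):
        x, y = rank_biased_overlap(a, b, p), rank_biased_overlap(b, a, p)
        assert x == pytest.approx(y, abs=1e-12)
        assert x == pytest.approx(rbo_reference(a, b, p), abs=1e-12)

    def test_moving_toward_agreement_never_decreases(self):
        """Any adjacent swap of b that locally restores a's order cannot
        lower RBO — checked over all permutations of up to 5 items."""
        for n in (3, 4, 5):
            a = list(range(n))
            pos = {v: i for i, v in enumerate(a)}
            for b in itertools.permutations(a):
                b = list(b)
                base = rank_biased_overlap(a, b, 0.9)
                for i in range(n - 1):
                    if pos[b[i]] > pos[b[i + 1]]:  # out of a's order
                        swapped = b[:i] + [b[i + 1], b[i]] + b[i + 2 :]
                        assert rank_biased_overlap(a, swapped, 0.9) >= base - 1e-12

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            rank_biased_overlap([], [1], 0.9)


class TestPosteriorEntropy:
    def test_uniform_gives_log_k(self):
        for k in (2, 5, 10):
            assert posterior_entropy({t: 0.4 for t in range(k)}) == pytest.approx(math.log(k))

    def test_degenerate_distribution_floored(self):
        assert posterior_entropy({1: 1.0, 2: 0.0}) == ENTROPY_FLOOR

    def test_two_equal_nonzero(self):
        assert posterior_entropy({1: 0.5, 2: 0.5, 3: 0.0}) == pytest.approx(math.log(2))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            posterior_entropy({1: 0.0})


def _result(alpha, beta, gamma, marginals):
    return PosteriorResult(GraphParams(alpha, beta, gamma), marginals, True, 1)


class TestSelectParameters:
    CONFIG = RunConfig()

    def _clustered(self, heads):
        from taxopep import ClusteredList

        return ClusteredList(heads=list(heads), members={h: {h} for h in heads})

    def test_single_result_wins(self):
        r = _result(0.9, 0.5, 0.3, {1: 0.9, 2: 0.1})
        winner, scores = select_parameters([r], self._clustered([1, 2]), self.CONFIG)
        assert winner.params is r.params and winner.winner

    def test_lower_entropy_wins_at_equal_rbo(self):
        # same ranking (same RBO), second has double the entropy
        sharp = _result(0.9, 0.5, 0.1, {1: 0.96, 2: 0.01, 3: 0.01})
        flat = _result(0.9, 0.5, 0.5, {1: 0.5, 2: 0.3, 3: 0.2})
        winner, scores = select_parameters(
            [flat, sharp], self._clustered([1, 2, 3]), self.CONFIG
        )
        assert winner.params.gamma == 0.1
        by_gamma = {s.params.gamma: s for s in scores}
        assert by_gamma[0.1].rbo == pytest.approx(by_gamma[0.5].rbo)
        ratio = (by_gamma[0.5].entropy / by_gamma[0.1].entropy) ** 2
        assert by_gamma[0.1].metric == pytest.approx(by_gamma[0.5].metric * ratio)

    def test_metric_rises_as_entropy_falls_at_fixed_rbo(self):
        results = [
            _result(0.9, 0.5, g, {1: hi, 2: 1 - hi})
            for g, hi in [(0.1, 0.99), (0.3, 0.9), (0.5, 0.6)]
        ]
        _, scores = select_parameters(results, self._clustered([1, 2]), self.CONFIG)
        ordered = sorted(scores, key=lambda s: s.entropy)
        assert all(a.metric > b.metric for a, b in zip(ordered, ordered[1:]))

    def test_zero_rbo_flagged_low_confidence_with_tie_rule(self):
        # posterior ranks are the reverse of the weighted heads at depth 1
        results = [
            _result(0.9, 0.7, 0.5, {1: 0.1, 2: 0.9}),
            _result(0.9, 0.5, 0.5, {1: 0.1, 2: 0.9}),
            _result(0.85, 0.5, 0.5, {1: 0.1, 2: 0.9}),
        ]
        clustered = self._clustered([1])  # depth-1 comparison, head never found
        winner, _ = select_parameters(results, clustered, self.CONFIG)
        assert winner.low_confidence
        assert winner.rbo == 0.0
        # ties: lower beta first, then higher alpha
        assert winner.params.beta == 0.5 and winner.params.alpha == 0.9
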