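"""MIS, neighborhood enrichment, cosine similarity and the core filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from netprio import (
    AnnotationCatalog,
    EnrichmentVector,
    GeneRecord,
    SeedSet,
    WeightedNetwork,
    enrichment_score,
    enrichment_vector,
    functional_similarity,
    hypergeometric_enrichment,
    max_function_score,
    max_interaction_score,
    neighborhood,
    select_core_candidates,
)


class TestMaxInteractionScore:
    def test_takes_maximum_over_seed_edges(self):
        net = WeightedNetwork([("g", "s1", 905), ("g", "s2", 990), ("g", "x", 999)])
        assert max_interaction_score("g", SeedSet(genes=("s1", "s2")), net) == 990

    def test_no_seed_edge_gives_zero(self, toy_network):
        assert max_interaction_score("b", SeedSet(genes=("l1",)), toy_network) == 0

    def test_unknown_gene_rejected(self, toy_network):
        with pytest.raises(ValueError, match="not in network"):
            max_interaction_score("zz", SeedSet(genes=("a",)), toy_network)

    def test_bounded_by_global_maximum_weight(self, default_benchmark):
        network, seed_set, _, _ = default_benchmark
        global_max = max(w for _, _, w in network.edges())
        for gene in network.nodes[:50]:
            assert max_interaction_score(gene, seed_set, network) <= global_max


class TestNeighborhood:
    def test_gene_plus_direct_neighbors(self, toy_network):
        hood = neighborhood("c", toy_network)
        assert hood.members == frozenset({"c", "l1", "l2", "a"})
        assert len(hood) == toy_network.degree("c") + 1

    def test_degree_one_gene(self, toy_network):
        assert len(neighborhood("b", toy_network)) == 2


class TestHypergeometricEnrichment:
    def test_hand_enumerated_tail(self):
        # N=10, M=5, n=4, m=4: p = C(5,4) C(5,0) / C(10,4) = 5/210
        expected = -math.log10(5 / 210)
        assert hypergeometric_enrichment(4, 4, 5, 10) == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_is_zero_score(self):
        assert hypergeometric_enrichment(0, 4, 5, 10) == 0.0

    def test_certain_overlap_has_unit_tail(self):
        # m = n = M = N: the full population is drawn, p = 1
        assert hypergeometric_enrichment(6, 6, 6, 6) == 0.0

    def test_monotone_in_overlap(self):
        scores = [hypergeometric_enrichment(m, 8, 10, 30) for m in range(9)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 11, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 5, 10)

    @pytest.mark.parametrize("m,n,M,N", [
        (1, 30, 150, 20000),
        (3, 30, 150, 20000),
        (5, 30, 150, 20000),
        (12, 25, 40, 500),
        (2, 5, 10, 50),
    ])
    def test_agrees_with_scipy_survival_function(self, m, n, M, N):
        """Independent library route: -log10 hypergeom.sf(m-1, N, M, n)."""
        expected = -math.log10(hypergeom.sf(m - 1, N, M, n))
        assert hypergeometric_enrichment(m, n, M, N) == pytest.approx(expected, rel=1e-9)

    def test_extreme_enrichment_capped_not_overflowed(self):
        score = hypergeometric_enrichment(400, 400, 400, 20000)
        assert 0 < score <= 300


class TestEnrichmentVector:
    @pytest.fixture
    def setup(self):
        net = WeightedNetwork([("g", "a", 500), ("g", "b", 500), ("x", "y", 500)])
        catalog = AnnotationCatalog(
            terms={
                "T1": frozenset({"g", "a"}),
                "T2": frozenset({"b"}),
                "T3": frozenset({"x", "y"}),
            },
            background_size=10,
        )
        return net, catalog

    def test_one_component_per_term_in_fixed_order(self, setup):
        net, catalog = setup
        vec = enrichment_vector("g", net, catalog)
        assert vec.terms == ("T1", "T2", "T3")
        assert len(vec.values) == 3

    def test_no_term_overlap_gives_zero_vector(self, setup):
        net, catalog = setup
        hood = neighborhood("x", net)
        assert enrichment_score(hood, "T1", catalog) == 0.0

    def test_identical_neighborhoods_give_identical_vectors(self):
        net = WeightedNetwork([("g1", "a", 500), ("g2", "a", 700)])
        catalog = AnnotationCatalog(terms={"T": frozenset({"a"})}, background_size=5)
        v1 = enrichment_vector("g1", net, catalog)
        v2 = enrichment_vector("g2", net, catalog)
        # both neighborhoods are {gene, a}; same sizes, same overlap
        assert np.array_equal(v1.values, v2.values)


nonneg_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e3, allow_nan=False), min_size=1, max_size=8
)


class TestFunctionalSimilarity:
    def _vec(self, values):
        terms = tuple(f"T{i}" for i in range(len(values)))
        return EnrichmentVector(terms=terms, values=np.asarray(values, dtype=float))

    def test_identical_nonzero_vectors(self):
        v = self._vec([1.0, 2.0, 0.5])
        assert functional_similarity(v, v) == pytest.approx(1.0)

    def test_half_overlapping_supports(self):
        assert functional_similarity(
            self._vec([1, 1, 0]), self._vec([1, 0, 1])
        ) == pytest.approx(0.5)

    def test_zero_vector_convention(self):
        assert functional_similarity(self._vec([0, 0]), self._vec([1, 2])) == 0.0

    def test_term_mismatch_rejected(self):
        v1 = self._vec([1.0])
        v2 = EnrichmentVector(terms=("OTHER",), values=np.array([1.0]))
        with pytest.raises(ValueError, match="term orderings"):
            functional_similarity(v1, v2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(values=nonneg_vectors)
    def test_symmetric_and_bounded(self, values):
        v1 = self._vec(values)
        v2 = self._vec(list(reversed(values)))
        s12 = functional_similarity(v1, v2)
        assert s12 == functional_similarity(v2, v1)
        assert 0.0 <= s12 <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(values=nonneg_vectors, scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, values, scale):
        v1 = self._vec(values)
        scaled = self._vec([scale * x for x in values])
        v2 = self._vec([x + 1.0 for x in values])
        assert functional_similarity(scaled, v2) == pytest.approx(
            functional_similarity(v1, v2), abs=1e-9
        )


class TestMaxFunctionScore:
    def _vectors(self, mapping):
        terms = ("T0", "T1", "T2")
        return {
            g: EnrichmentVector(terms=terms, values=np.asarray(v, dtype=float))
            for g, v in mapping.items()
        }

    def test_maximum_over_seeds(self):
        vectors = self._vectors({
            "g": [1, 0, 0], "s1": [0, 1, 0], "s2": [1, 1, 0], "s3": [1, 0, 0],
        })
        seeds = SeedSet(genes=("s1", "s2", "s3"))
        assert max_function_score("g", seeds, vectors) == pytest.approx(1.0)

    def test_zero_vector_gene_scores_zero(self):
        vectors = self._vectors({"g": [0, 0, 0], "s": [1, 2, 3]})
        assert max_function_score("g", SeedSet(genes=("s",)), vectors) == 0.0

    def test_missing_vector_rejected(self):
        vectors = self._vectors({"g": [1, 0, 0]})
        with pytest.raises(ValueError, match="missing enrichment vector"):
            max_function_score("g", SeedSet(genes=("s",)), vectors)


def _record(symbol="g", mis=950, mfs=0.95, fdr=0.01):
    return GeneRecord(
        symbol=symbol, identifier=symbol, probability=5e-5, fdr=fdr, mis=mis, mfs=mfs
    )


class TestSelectCoreCandidates:
    def test_mis_strictly_below_cutoff_dropped(self):
        assert select_core_candidates([_record(mis=899)]) == []
        assert len(select_core_candidates([_record(mis=900)])) == 1

    def test_mfs_at_reported_precision_passes_boundary(self):
        # a stored 0.900 satisfies "larger than 0.9" at 3-decimal precision
        assert len(select_core_candidates([_record(mfs=0.900)])) == 1
        assert select_core_candidates([_record(mfs=0.89)]) == []

    def test_zero_mis_convention_filtered(self):
        assert select_core_candidates([_record(mis=0)]) == []

    def test_output_subset_preserving_order(self):
        records = [_record(f"g{i}", mis=899 + i) for i in range(5)]
        kept = select_core_candidates(records)
        assert [r.symbol for r in kept] == ["g1", "g2", "g3", "g4"]
        assert all(r in records for r in kept)


class TestGeneRecordInvariants:
    def test_mis_outside_string_scale_rejected(self):
        with pytest.raises(ValueError, match="MIS"):
            _record(mis=100)

    def test_mfs_above_one_rejected(self):
        with pytest.raises(ValueError, match="MFS"):
            _record(mfs=1.5)
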