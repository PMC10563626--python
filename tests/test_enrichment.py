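"""Overrepresentation statistics against independent oracles.

The right-tail p-value is checked against exhaustive enumeration of all
draws; BH q-values against a hand implementation of the step-up rule.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synoverlap.enrichment import (
    EnrichmentInput,
    TermAnnotation,
    apply_inclusion_filters,
    bh_fdr,
    fisher_overrepresentation,
)
from synoverlap.errors import ParameterError, ValidationError
from synoverlap.synthetic_data import AnnotationConfig, simulate_annotation_and_query


def enumerate_right_tail(N: int, K: int, n: int, k: int) -> float:
    """Brute-force P(overlap >= k): enumerate every n-subset of N genes."""
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def step_up_rejections(p_values, alpha: float) -> set[int]:
    """Classic BH step-up rule: largest i with p_(i) <= i/m * alpha."""
    order = sorted(range(len(p_values)), key=lambda i: p_values[i])
    m = len(p_values)
    cut = 0
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= rank / m * alpha:
            cut = rank
    return set(order[:cut])


def _run(query, background, term_genes, domain="CC"):
    terms = [TermAnnotation("T1", "t", set(term_genes), domain)]
    return fisher_overrepresentation(
        EnrichmentInput(set(query), set(background), terms)
    )[0]


class TestFisher:
    def test_worked_example_against_enumeration(self):
        # N=10 background, K=4 term, n=5 query, k=4 overlap
        background = [f"g{i}" for i in range(10)]
        term = background[:4]
        query = background[:4] + [background[9]]
        result = _run(query, background, term)
        assert result.k == 4 and result.expected == pytest.approx(2.0)
        assert result.fold_enrichment == pytest.approx(2.0)
        assert result.p_value == pytest.approx(6 / 252, abs=1e-12)
        assert result.p_value == pytest.approx(enumerate_right_tail(10, 4, 5, 4), abs=1e-12)

    def test_saturated_query_gives_p_one_fe_one(self):
        background = [f"g{i}" for i in range(8)]
        result = _run(background, background, background[:3])
        assert result.k == result.K == 3
        assert result.fold_enrichment == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(6, 2, 3), (8, 4, 4), (9, 3, 5), (10, 5, 2)])
    def test_matches_enumeration_at_every_overlap(self, N, K, n):
        background = [f"g{i}" for i in range(N)]
        term = background[:K]
        for k in range(0, min(n, K) + 1):
            query = background[:k] + background[K:K + n - k]
            result = _run(query, background, term)
            assert result.k == k
            assert result.p_value == pytest.approx(
                enumerate_right_tail(N, K, n, k), abs=1e-12)

    def test_query_outside_background_dropped_with_warning(self):
        background = {f"g{i}" for i in range(6)}
        with pytest.warns(UserWarning, match="dropped"):
            inp = EnrichmentInput(background | {"alien"}, background,
                                  [TermAnnotation("T", "t", set(list(background)[:2]), "CC")])
        assert inp.n_dropped == 1 and len(inp.query) == 6

    def test_empty_background_rejected(self):
        with pytest.raises(ParameterError):
            EnrichmentInput({"a"}, set(), [])

    def test_fe_times_expected_recovers_k(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(60)]
        for _ in range(20):
            term = rng.choice(background, size=12, replace=False)
            query = rng.choice(background, size=18, replace=False)
            result = _run(query, background, term)
            if result.expected > 0:
                assert result.fold_enrichment * result.expected == pytest.approx(
                    result.k, abs=1e-9)
            assert (result.fold_enrichment > 1) == (result.k > result.expected)


class TestBH:
    def test_hand_worked_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=80, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.sampled_from([0.01, 0.05, 0.1, 0.3]))
    def test_rejection_sets_match_step_up_rule(self, p_values, alpha):
        q = bh_fdr(p_values)
        assert {i for i, qi in enumerate(q) if qi <= alpha} == \
            step_up_rejections(p_values, alpha)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_q_dominates_p_and_is_capped(self, p_values):
        q = bh_fdr(p_values)
        assert all(qi >= pi - 1e-12 and qi <= 1.0 for qi, pi in zip(q, p_values))


class TestInclusionFilters:
    def _result(self, domain, K, fe, q):
        from synoverlap.enrichment import EnrichmentResult

        r = EnrichmentResult(term_id="T", label="t", domain=domain, k=1, K=K,
                             n=10, N=100, expected=1.0, fold_enrichment=fe,
                             p_value=q, q_value=q)
        return r

    @pytest.mark.parametrize(
        "domain,K,fe,q,kept",
        [
            ("CC", 12, 4.9, 0.001, False),   # below the CC fold floor of 5
            ("CC", 12, 5.0, 0.001, True),    # floor is inclusive
            ("BP", 9, 20.0, 1e-8, False),    # under 10 annotated genes
            ("BP", 10, 2.0, 0.001, True),
            ("BP", 30, 8.0, 0.06, False),    # not FDR-significant
            ("pathway", 15, 1.2, 0.01, True),  # no floor configured
        ],
    )
    def test_retention_rule(self, domain, K, fe, q, kept):
        results = apply_inclusion_filters(
            [self._result(domain, K, fe, q)],
            min_term_size=10,
            min_fe_by_domain={"CC": 5.0, "BP": 2.0},
            alpha=0.05,
        )
        assert results[0].retained is kept


class TestCalibration:
    def test_null_rejection_fraction_within_fdr_bound(self):
        """Uniform queries with no planted signal: the per-family fraction
        of q<0.05 terms stays near/below the nominal level."""
        config = AnnotationConfig(background_size=400, n_terms=25,
                                  term_size_mean=30.0, query_size=60,
                                  sampling_odds=1.0)
        terms, background, _ = simulate_annotation_and_query(config, seed=123)
        rng = np.random.default_rng(7)
        universe = sorted(background)
        rejected = tested = 0
        for _ in range(500):
            query = set(rng.choice(universe, size=config.query_size, replace=False))
            results = fisher_overrepresentation(
                EnrichmentInput(query, background, terms))
            rejected += sum(r.q_value < 0.05 for r in results)
            tested += len(results)
        fraction = rejected / tested
        mc_error = math.sqrt(0.05 * 0.95 / 500)
        assert fraction <= 0.05 + 2 * mc_error

    def test_planted_term_detected_single_seed(self):
        config = AnnotationConfig()  # odds 5, N=2000, K~100, n=200
        terms, background, query = simulate_annotation_and_query(config, seed=11)
        results = fisher_overrepresentation(
            EnrichmentInput(query, background, terms))
        planted = next(r for r in results if r.term_id == config.planted_term)
        assert planted.q_value < 0.05 and planted.fold_enrichment > 1
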