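"""Gene-set overrepresentation by right-tailed Fisher's exact test.

For a query of n genes drawn from a background of N, a term annotating K
background genes, and an observed overlap k, the right-tail p-value is the
hypergeometric survival probability P(X >= k), identical to a one-sided
Fisher test on the 2x2 table. Fold enrichment is k over its expectation
n*K/N. Multiple testing is controlled with Benjamini-Hochberg step-up
FDR, applied per annotation domain (CC, BP, pathway, protein class treated
as separate families). Inclusion filters retain significant terms with at
least ``min_term_size`` annotated genes and a per-domain fold-enrichment
floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from synoverlap.errors import ParameterError, ValidationError


@dataclass
class TermAnnotation:
    """A term (GO/pathway/protein class) with its annotated gene set."""

    term_id: str
    label: str
    genes: set[str]
    domain: str = "CC"


@dataclass
class EnrichmentInput:
    """Query, background and term collection for one overrepresentation run.

    Query genes absent from the background are dropped (with a warning) and
    counted in ``n_dropped``; term annotation sets are clipped to the
    background.
    """

    query: set[str]
    background: set[str]
    terms: list[TermAnnotation]
    n_dropped: int = field(init=False, default=0)

    def __post_init__(self):
        if not self.background:
            raise ParameterError("background must be non-empty")
        outside = self.query - self.background
        if outside:
            warnings.warn(
                f"{len(outside)} query gene(s) absent from the background were dropped",
                stacklevel=2,
            )
            self.query = self.query - outside
        self.n_dropped = len(outside)
        if not self.query:
            raise ParameterError("query is empty after restriction to the background")
        self.terms = [
            TermAnnotation(t.term_id, t.label, t.genes & self.background, t.domain)
            for t in self.terms
        ]


@dataclass
class EnrichmentResult:
    """Per-term test outcome."""

    term_id: str
    label: str
    domain: str
    k: int
    K: int
    n: int
    N: int
    expected: float
    fold_enrichment: float  # NaN when expected == 0
    p_value: float
    q_value: float = float("nan")
    retained: bool = False


def fisher_overrepresentation(inputs: EnrichmentInput) -> list[EnrichmentResult]:
    """Right-tailed Fisher's exact test for every term in the collection.

    Returns one result per term, in input order, with q-values assigned by
    per-domain BH correction.
    """
    n, N = len(inputs.query), len(inputs.background)
    results = []
    for term in inputs.terms:
        K = len(term.genes)
        k = len(inputs.query & term.genes)
        expected = n * K / N
        fe = k / expected if expected > 0 else float("nan")
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf is exclusive, hence k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term.term_id, label=term.label, domain=term.domain,
                k=k, K=K, n=n, N=N, expected=expected, fold_enrichment=fe,
                p_value=min(p, 1.0),
            )
        )
    for domain in {r.domain for r in results}:
        members = [r for r in results if r.domain == domain]
        qs = bh_fdr([r.p_value for r in members])
        for r, q in zip(members, qs):
            r.q_value = q
    return results


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def apply_inclusion_filters(
    results: list[EnrichmentResult],
    min_term_size: int = 10,
    min_fe_by_domain: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Mark results retained by the presentation filters.

    A term is retained iff q < alpha, its annotated set has at least
    ``min_term_size`` genes, and its fold enrichment reaches the floor for
    its domain (domains absent from the map have no floor). All results are
    returned, in order, with the ``retained`` flag set.
    """
    floors = min_fe_by_domain or {}
    for r in results:
        floor = floors.get(r.domain, 0.0)
        fe_ok = not np.isnan(r.fold_enrichment) and r.fold_enrichment >= floor
        r.retained = bool(r.q_value < alpha and r.K >= min_term_size and fe_ok)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "label": r.label, "domain": r.domain,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "expected": r.expected, "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value, "q_value": r.q_value, "retained": r.retained,
            }
            for r in results
        ]
    )
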