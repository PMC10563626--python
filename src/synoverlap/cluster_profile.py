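"""Annotate PPI clusters with percent membership in curated terms.

For every (term, cluster) pair the table reports the percentage of cluster
members annotated to the term, rounded half-up to one decimal to match the
conventional printed layout; raw fractions are kept alongside for machine
consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from synoverlap.enrichment import TermAnnotation
from synoverlap.errors import ParameterError, ValidationError


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProfileTable:
    """Terms x clusters percent-membership table."""

    terms: list[tuple[str, str]]  # (term_id, label)
    cluster_sizes: dict[int, int]
    percents: dict[tuple[str, int], float]  # rounded, one decimal
    fractions: dict[tuple[str, int], float]  # raw m/n

    def percent(self, term_id: str, cluster_id: int) -> float:
        return self.percents[(term_id, cluster_id)]

    def to_wide(self) -> pd.DataFrame:
        """Terms as rows, clusters as columns (printed-table orientation)."""
        columns = {
            f"cluster_{cid} (n={n})": [
                self.percents[(tid, cid)] for tid, _ in self.terms
            ]
            for cid, n in sorted(self.cluster_sizes.items())
        }
        index = [f"{label} ({tid})" for tid, label in self.terms]
        return pd.DataFrame(columns, index=index)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for tid, label in self.terms:
            for cid, n in sorted(self.cluster_sizes.items()):
                rows.append(
                    {"term_id": tid, "label": label, "cluster_id": cid,
                     "cluster_size": n, "percent": self.percents[(tid, cid)],
                     "fraction": self.fractions[(tid, cid)]}
                )
        return pd.DataFrame(rows)


def annotation_percentages(
    clusters: list[set[str]], terms: list[TermAnnotation]
) -> ProfileTable:
    """Percent of each cluster annotated to each term.

    Clusters must be disjoint and non-empty; terms are reported in input
    order, clusters by their position in the input list.
    """
    if not terms:
        raise ParameterError("need at least one term to profile")
    if any(not c for c in clusters):
        raise ParameterError("clusters must be non-empty")
    everything = [n for c in clusters for n in c]
    if len(everything) != len(set(everything)):
        raise ValidationError("clusters must be disjoint")

    percents, fractions = {}, {}
    for term in terms:
        for cid, cluster in enumerate(clusters):
            m = len(cluster & term.genes)
            frac = m / len(cluster)
            fractions[(term.term_id, cid)] = frac
            percents[(term.term_id, cid)] = round_half_up(100.0 * m / len(cluster), 1)
    return ProfileTable(
        terms=[(t.term_id, t.label) for t in terms],
        cluster_sizes={cid: len(c) for cid, c in enumerate(clusters)},
        percents=percents,
        fractions=fractions,
    )
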