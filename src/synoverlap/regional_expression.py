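"""Region-elevated expression calls from gene x brain-region nTPM matrices.

A gene is "expressed" in a region when its nTPM exceeds 1. A region is
called *elevated* for a gene when the gene is expressed there and its nTPM
is at least ``fold`` times the mean of its nTPM over the remaining regions
(a fold-over-rest rule standing in for an atlas's internal regional-
elevation taxonomy, which is versioned and not restated here). A
pass-through loader for precomputed elevation labels is provided for
fidelity to published label sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from synoverlap.errors import ParameterError, ValidationError
from synoverlap.gwas_ingest import CandidateGeneSet

#: canonical nine-region brain panel
BRAIN_REGIONS = (
    "cerebral cortex",
    "hippocampal formation",
    "amygdala",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "pons",
    "cerebellum",
    "medulla oblongata",
)


@dataclass
class ExpressionMatrix:
    """nTPM values for genes (rows) across brain regions (columns)."""

    values: pd.DataFrame  # genes x regions, float

    def __post_init__(self):
        frame = self.values.astype(float)
        frame.columns = [canonical_region(c) for c in frame.columns]
        if frame.isna().any().any():
            raise ValidationError("expression matrix contains missing cells")
        if (frame.to_numpy() < 0).any():
            raise ValidationError("nTPM values must be non-negative")
        self.values = frame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, impute_missing_as_zero: bool = False) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if impute_missing_as_zero:
            frame = frame.fillna(0.0)
        return cls(values=frame)


def canonical_region(name: str) -> str:
    return " ".join(str(name).strip().lower().replace("_", " ").split())


@dataclass
class ElevationCall:
    """Regions in which one gene is called elevated, with the rule used."""

    gene_id: str
    elevated_regions: set[str]
    rule: dict


def classify_elevated(
    matrix: ExpressionMatrix, expressed_min: float = 1.0, fold: float = 4.0
) -> list[ElevationCall]:
    """Call regionally elevated genes with the fold-over-rest rule.

    Region r is elevated for gene g iff nTPM(g, r) > ``expressed_min`` and
    nTPM(g, r) >= ``fold`` * mean(nTPM of g over the other regions). Genes
    with no elevated region are omitted from the output.
    """
    if len(matrix.regions) < 2:
        raise ParameterError("need at least 2 regions to call elevation")
    values = matrix.values.to_numpy()
    n_regions = values.shape[1]
    rule = {"expressed_min": expressed_min, "fold": fold}
    calls = []
    totals = values.sum(axis=1)
    for i, gene in enumerate(matrix.genes):
        rest_mean = (totals[i] - values[i]) / (n_regions - 1)
        mask = (values[i] > expressed_min) & (values[i] >= fold * rest_mean)
        if mask.any():
            regions = {matrix.regions[j] for j in np.flatnonzero(mask)}
            calls.append(ElevationCall(gene_id=gene, elevated_regions=regions, rule=rule))
    return calls


def load_elevation_labels(path) -> list[ElevationCall]:
    """Pass-through loader for precomputed elevation labels.

    TSV columns: ``gene_id``, ``region`` (one row per elevated region; an
    optional third column is ignored here and used only by crosstab
    renderers).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    calls: dict[str, set[str]] = {}
    for gene, region in zip(frame["gene_id"], frame["region"]):
        calls.setdefault(str(gene), set()).add(canonical_region(region))
    return [
        ElevationCall(gene_id=g, elevated_regions=r, rule={"source": "precomputed"})
        for g, r in sorted(calls.items())
    ]


def regional_crosstab(
    calls: list[ElevationCall], named_sets: dict[str, object]
) -> pd.DataFrame:
    """Cross-tabulate elevated genes against named gene sets.

    Long-format output: one row per (gene, region, set) for every elevated
    gene belonging to at least one named set. A wide rendering (genes x
    regions, comma-joined set labels per cell) is available via
    :func:`crosstab_wide`.
    """
    sets = {
        name: set(g.genes) if isinstance(g, CandidateGeneSet) else set(g)
        for name, g in named_sets.items()
    }
    rows = []
    for call in calls:
        members = [name for name, genes in sets.items() if call.gene_id in genes]
        if not members:
            continue
        for region in sorted(call.elevated_regions):
            for name in members:
                rows.append({"gene_id": call.gene_id, "region": region, "set_label": name})
    return pd.DataFrame(rows, columns=["gene_id", "region", "set_label"])


def crosstab_wide(long: pd.DataFrame, regions=BRAIN_REGIONS) -> pd.DataFrame:
    """Render the long crosstab as genes x regions with joined set labels."""
    genes = sorted(long["gene_id"].unique()) if len(long) else []
    wide = pd.DataFrame("", index=genes, columns=list(regions))
    for (gene, region), group in long.groupby(["gene_id", "region"]):
        if region in wide.columns:
            wide.loc[gene, region] = ",".join(sorted(group["set_label"].unique()))
    return wide
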