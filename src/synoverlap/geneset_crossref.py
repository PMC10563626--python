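"""Set cross-analysis: synapse-annotation subsetting and Venn-style overlap
partitioning of condition gene sets and the interactome.

The central objects are plain harmonized gene-identifier sets. Annotation
sets carry a per-gene species-origin tag so both a single-species view
(e.g. the 89 mouse-synaptic interactors) and a combined-species view
(92) can be reported from one structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from synoverlap.errors import ParameterError
from synoverlap.gwas_ingest import CandidateGeneSet
from synoverlap.id_harmonize import Resolver


@dataclass
class AnnotationSet:
    """A term (e.g. GO "synapse") with its annotated genes.

    ``species_origin`` tags every member as ``human``, ``mouse-ortholog``
    or ``both``.
    """

    term_id: str
    label: str
    genes: set[str]
    species_origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for g in self.genes:
            self.species_origin.setdefault(g, "human")

    def subset(self, species: str) -> set[str]:
        """Members tagged ``species`` or ``both``."""
        return {g for g in self.genes if self.species_origin[g] in (species, "both")}


@dataclass
class OverlapTable:
    """All pairwise overlaps and the full Venn partition of k named sets."""

    set_names: list[str]
    pairwise: dict[tuple[str, str], set[str]]
    venn_partitions: dict[tuple[str, ...], set[str]]

    def partition(self, *names: str) -> set[str]:
        """Genes belonging to exactly the given sets and no others."""
        return self.venn_partitions.get(tuple(sorted(names)), set())

    def overlap(self, a: str, b: str) -> set[str]:
        return self.pairwise[tuple(sorted((a, b)))]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"signature": "&".join(sig), "count": len(genes),
             "genes": ",".join(sorted(genes))}
            for sig, genes in sorted(self.venn_partitions.items())
        ]
        return pd.DataFrame(rows, columns=["signature", "count", "genes"])


def _as_set(genes) -> set[str]:
    if isinstance(genes, CandidateGeneSet):
        return set(genes.genes)
    return set(genes)


def synapse_subset(genes, annotation: AnnotationSet):
    """Restrict a gene set to members of an annotation set.

    Accepts either a plain set of identifiers or a
    :class:`~synoverlap.gwas_ingest.CandidateGeneSet`; the latter keeps its
    report counts and provenance on the survivors. A zero overlap between
    the *namespaces* (no shared identifier style at all) triggers a warning
    since it usually means the inputs were not harmonized.
    """
    members = _as_set(genes)
    if members and annotation.genes and not members & annotation.genes:
        warnings.warn(
            f"no overlap between input genes and annotation {annotation.term_id}: "
            "check that both sides use the same identifier namespace",
            stacklevel=2,
        )
    if isinstance(genes, CandidateGeneSet):
        kept = {g: c for g, c in genes.genes.items() if g in annotation.genes}
        return CandidateGeneSet(
            condition=genes.condition,
            genes=kept,
            namespaces={g: genes.namespaces.get(g, "symbol") for g in kept},
            provenance={**genes.provenance, "annotation": annotation.term_id},
        )
    return members & annotation.genes


def combine_species_annotation(
    human: AnnotationSet, mouse: AnnotationSet, resolver: Resolver
) -> AnnotationSet:
    """Union the human annotation with resolved mouse orthologs.

    Mouse members are translated to the human namespace through the
    resolver; unresolved or ambiguous mouse genes are excluded and recorded
    in the returned set's ``species_origin`` companion log (attribute
    ``exclusions``). Genes present on both sides are tagged ``both``.
    """
    report = resolver.resolve(sorted(mouse.genes), normalize_case=True)
    mouse_resolved = {target for target, _ in report.resolved.values()}
    genes = set(human.genes) | mouse_resolved
    origin = {}
    for g in genes:
        in_h, in_m = g in human.genes, g in mouse_resolved
        origin[g] = "both" if (in_h and in_m) else ("human" if in_h else "mouse-ortholog")
    combined = AnnotationSet(
        term_id=human.term_id,
        label=human.label,
        genes=genes,
        species_origin=origin,
    )
    combined.exclusions = {"unresolved": list(report.unresolved),
                           "ambiguous": dict(report.ambiguous)}
    return combined


def overlap_matrix(named_sets: dict[str, object]) -> OverlapTable:
    """Compute all pairwise overlaps and the 2^k - 1 Venn partition.

    Partitions are keyed by the sorted tuple of set names a gene belongs
    to; they are disjoint and union to the union of all inputs.
    """
    if len(named_sets) < 2:
        raise ParameterError(f"need at least 2 sets, got {len(named_sets)}")
    sets = {name: _as_set(genes) for name, genes in named_sets.items()}
    names = sorted(sets)

    pairwise = {
        tuple(sorted((a, b))): sets[a] & sets[b]
        for a, b in itertools.combinations(names, 2)
    }
    partitions: dict[tuple[str, ...], set[str]] = {}
    for gene in set().union(*sets.values()):
        sig = tuple(sorted(n for n in names if gene in sets[n]))
        partitions.setdefault(sig, set()).add(gene)
    return OverlapTable(set_names=names, pairwise=pairwise, venn_partitions=partitions)


def read_gene_set(path) -> set[str]:
    """Read a one-column TSV (optionally headed ``gene_id``) as a gene set."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    col = "gene_id" if "gene_id" in frame.columns else frame.columns[0]
    return {str(g).strip() for g in frame[col] if str(g).strip()}


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file as term_id -> (description, gene set)."""
    collections = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                collections[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return collections


def write_gmt(collections: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as handle:
        for term, (desc, genes) in collections.items():
            handle.write("\t".join([term, desc, *sorted(genes)]) + "\n")
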