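"""End-to-end orchestration: ingest -> harmonize -> crossref -> enrich ->
cluster -> profile -> regional, with a run manifest and exclusion logs.

The pipeline is driven by a plain dict (or YAML file) naming the input
files for each enabled stage. Every stage is optional; stages run in
dependency order and any failure aborts with the stage name while earlier
outputs are preserved in the bundle. Deterministic stages are bit-
reproducible from the manifest (config hash + seed + input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from synoverlap.errors import ConfigurationError
from synoverlap import gwas_ingest, geneset_crossref, enrichment, ppi_network
from synoverlap.cluster_profile import annotation_percentages
from synoverlap.regional_expression import (
    ExpressionMatrix,
    classify_elevated,
    load_elevation_labels,
    regional_crosstab,
)

log = logging.getLogger("synoverlap")

STAGES = ("ingest", "crossref", "enrich", "cluster", "profile", "regional")


@dataclass
class ReportBundle:
    """Per-stage output tables plus manifest and exclusion logs."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    exclusions: dict[str, object] = field(default_factory=dict)
    partitions: dict[str, ppi_network.Partition] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            _atomic_write_tsv(table, outdir / f"{name}.tsv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        (outdir / "exclusions.json").write_text(
            json.dumps(self.exclusions, indent=1, default=sorted)
        )


def _atomic_write_tsv(frame: pd.DataFrame, path: Path) -> None:
    """Write via temp file + rename so partial tables never land on disk."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        frame.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: dict) -> ReportBundle:
    """Run the enabled stages of the cross-analysis pipeline.

    Config keys (all optional, but at least one stage must be enabled):

    ``ingest``
        ``{"tables": {condition: path}, "min_reports": int}``
    ``crossref``
        ``{"annotation_gmt": path, "synapse_term": term_id}`` — restricts
        the ingested sets to the synapse annotation and partitions them.
    ``enrich``
        ``{"query": path, "background": path, "annotation_gmt": path,
        "min_term_size": int, "min_fe_by_domain": {...}, "alpha": float}``
    ``cluster``
        ``{"edges": path, "min_score": float, "inflation": float,
        "seed": int, "min_cluster_size": int}``
    ``profile``
        ``{"annotation_gmt": path}`` — percent-annotation profile of the
        retained clusters (requires ``cluster``).
    ``regional``
        ``{"matrix": path | "labels": path, "fold": float,
        "expressed_min": float}`` — elevation calls cross-tabbed against
        the ingested (or ``sets``-configured) gene sets.
    """
    enabled = [s for s in STAGES if s in config]
    if not enabled:
        raise ConfigurationError(f"empty config: enable at least one of {STAGES}")
    if "profile" in config and "cluster" not in config:
        raise ConfigurationError("profile stage requires the cluster stage")

    bundle = ReportBundle()
    inputs = {}
    for stage in enabled:
        for key, value in config[stage].items():
            if isinstance(value, (str, Path)) and Path(str(value)).is_file():
                inputs[f"{stage}.{key}"] = _checksum(value)
            elif isinstance(value, dict):
                for sub, path in value.items():
                    if isinstance(path, (str, Path)) and Path(str(path)).is_file():
                        inputs[f"{stage}.{key}.{sub}"] = _checksum(path)
    bundle.manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": enabled,
        "input_checksums": inputs,
        "seed": config.get("cluster", {}).get("seed"),
    }

    genesets: dict[str, gwas_ingest.CandidateGeneSet] = {}
    for stage in enabled:
        log.info("[%s] starting", stage)
        try:
            if stage == "ingest":
                spec = config["ingest"]
                for condition, path in spec["tables"].items():
                    records = gwas_ingest.parse_associations(path)
                    genesets[condition] = gwas_ingest.filter_candidate_genes(
                        records, min_reports=spec.get("min_reports", 2)
                    )
                bundle.tables["candidate_counts"] = pd.DataFrame(
                    {"condition": list(genesets),
                     "n_genes": [len(g) for g in genesets.values()],
                     "n_geneless_associations": [
                         g.provenance["n_geneless"] for g in genesets.values()]}
                )
                bundle.exclusions["geneless_associations"] = {
                    c: g.provenance["n_geneless"] for c, g in genesets.items()}

            elif stage == "crossref":
                spec = config["crossref"]
                collections = geneset_crossref.read_gmt(spec["annotation_gmt"])
                term = spec.get("synapse_term") or next(iter(collections))
                desc, members = collections[term]
                annotation = geneset_crossref.AnnotationSet(term, desc, members)
                subsets = {
                    c: geneset_crossref.synapse_subset(g, annotation)
                    for c, g in genesets.items()
                }
                named = {c: s for c, s in subsets.items()}
                extra_sets = spec.get("sets", {})
                for name, path in extra_sets.items():
                    named[name] = geneset_crossref.read_gene_set(path)
                if len(named) >= 2:
                    table = geneset_crossref.overlap_matrix(named)
                    bundle.tables["overlap_partitions"] = table.to_frame()
                bundle.tables["synapse_subsets"] = pd.DataFrame(
                    {"set": list(named),
                     "n_synaptic": [len(s.genes if hasattr(s, "genes") else s)
                                    for s in named.values()]}
                )

            elif stage == "enrich":
                spec = config["enrich"]
                query = geneset_crossref.read_gene_set(spec["query"])
                background = geneset_crossref.read_gene_set(spec["background"])
                collections = geneset_crossref.read_gmt(spec["annotation_gmt"])
                terms = [
                    enrichment.TermAnnotation(t, d, g, spec.get("domain", "CC"))
                    for t, (d, g) in collections.items()
                ]
                inp = enrichment.EnrichmentInput(query, background, terms)
                results = enrichment.fisher_overrepresentation(inp)
                enrichment.apply_inclusion_filters(
                    results,
                    min_term_size=spec.get("min_term_size", 10),
                    min_fe_by_domain=spec.get("min_fe_by_domain"),
                    alpha=spec.get("alpha", 0.05),
                )
                bundle.tables["enrichment"] = enrichment.results_to_frame(results)
                bundle.exclusions["query_outside_background"] = inp.n_dropped

            elif stage == "cluster":
                spec = config["cluster"]
                universe = None
                if spec.get("node_universe"):
                    universe = geneset_crossref.read_gene_set(spec["node_universe"])
                graph = ppi_network.read_edge_list(
                    spec["edges"], min_score=spec.get("min_score", 0.4),
                    node_universe=universe,
                )
                mcl = ppi_network.mcl_cluster(
                    graph, inflation=spec.get("inflation", 1.3)
                )
                k = sum(1 for c in mcl.clusters if len(c) >= 2)
                km = ppi_network.kmeans_refine(
                    graph, k=max(k, 1), seed=spec.get("seed", 0)
                )
                from sklearn.metrics import adjusted_rand_score

                mcl_labels, km_labels = mcl.labels(), km.labels()
                order = sorted(mcl_labels)
                ari = adjusted_rand_score(
                    [mcl_labels[n] for n in order], [km_labels[n] for n in order]
                ) if len(order) > 1 else 1.0
                bundle.partitions = {"mcl": mcl, "kmeans": km}
                bundle.manifest["mcl_kmeans_ari"] = float(ari)
                bundle.tables["partition_mcl"] = mcl.to_frame()
                bundle.tables["partition_kmeans"] = km.to_frame()
                selected = ppi_network.select_clusters(
                    km, min_size=spec.get("min_cluster_size", 4)
                )
                bundle.manifest["n_retained_clusters"] = len(selected)
                bundle.exclusions["isolated_nodes"] = list(graph.isolated)
                bundle.exclusions["sub_threshold_clusters"] = [
                    sorted(c) for c in km.clusters
                    if len(c) < spec.get("min_cluster_size", 4)
                ]
                bundle._selected_clusters = selected

            elif stage == "profile":
                spec = config["profile"]
                collections = geneset_crossref.read_gmt(spec["annotation_gmt"])
                terms = [
                    enrichment.TermAnnotation(t, d, g)
                    for t, (d, g) in collections.items()
                ]
                profile = annotation_percentages(bundle._selected_clusters, terms)
                bundle.tables["cluster_profile"] = profile.to_long()

            elif stage == "regional":
                spec = config["regional"]
                if "labels" in spec:
                    calls = load_elevation_labels(spec["labels"])
                else:
                    matrix = ExpressionMatrix.from_tsv(spec["matrix"])
                    calls = classify_elevated(
                        matrix,
                        expressed_min=spec.get("expressed_min", 1.0),
                        fold=spec.get("fold", 4.0),
                    )
                named = dict(genesets)
                for name, path in spec.get("sets", {}).items():
                    named[name] = geneset_crossref.read_gene_set(path)
                bundle.tables["regional_crosstab"] = regional_crosstab(calls, named)
                bundle.tables["elevation_calls"] = pd.DataFrame(
                    [{"gene_id": c.gene_id, "region": r}
                     for c in calls for r in sorted(c.elevated_regions)],
                    columns=["gene_id", "region"],
                )
        except Exception as exc:
            log.error("[%s] failed: %s", stage, exc)
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        log.info("[%s] done", stage)
    return bundle
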