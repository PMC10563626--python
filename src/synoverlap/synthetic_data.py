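"""Synthetic inputs with controlled statistical structure.

Every pipeline stage consumes file-based database snapshots; this module
generates statistically controlled stand-ins for all of them so the whole
pipeline is testable offline:

* GWAS-style association tables with per-gene report counts drawn from a
  zero-truncated Poisson, a configurable fraction of gene-less
  associations, and controlled cross-condition gene sharing;
* term -> gene annotation collections over a fixed background, plus query
  sets with one planted overrepresented term (biased sampling odds);
* stochastic-block-model PPI graphs with Beta-distributed combined scores
  split by block membership;
* gene x brain-region nTPM matrices with planted region-elevated genes.

Every generator is a pure function of its config and seed, and emits its
ground truth alongside the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synoverlap.errors import ConfigurationError, ParameterError
from synoverlap.enrichment import TermAnnotation
from synoverlap.regional_expression import BRAIN_REGIONS


@dataclass
class GwasConfig:
    """Association-table generator settings.

    ``report_rate`` is the mean of the zero-truncated Poisson report-count
    law; ``fraction_geneless`` of association rows carry an empty gene
    cell; ``sharing`` maps a pair of condition names to the number of genes
    they share.
    """

    n_genes: int = 500
    report_rate: float = 3.0
    fraction_geneless: float = 0.1
    sharing: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_genes < 0 or self.report_rate <= 0:
            raise ConfigurationError("n_genes must be >= 0 and report_rate > 0")
        if not 0 <= self.fraction_geneless <= 1:
            raise ConfigurationError("fraction_geneless must lie in [0, 1]")


@dataclass
class AnnotationConfig:
    """Annotation-collection and planted-enrichment settings."""

    background_size: int = 2000
    n_terms: int = 50
    term_size_mean: float = 100.0
    query_size: int = 200
    planted_term: str = "T0000"
    sampling_odds: float = 5.0

    def __post_init__(self):
        if self.query_size > self.background_size:
            raise ConfigurationError("query_size cannot exceed background_size")


@dataclass
class PpiConfig:
    """Stochastic-block-model PPI settings.

    Within-block edges appear with probability ``p_in`` and draw scores
    from Beta(``beta_in``); between-block edges with ``p_out`` and
    Beta(``beta_out``). Defaults put essentially all within-block scores
    above the 0.4 confidence threshold and most between-block ones below.
    """

    block_sizes: tuple[int, ...] = (10, 10, 10)
    p_in: float = 0.6
    p_out: float = 0.05
    beta_in: tuple[float, float] = (8.0, 2.0)
    beta_out: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self):
        if sum(self.block_sizes) == 0:
            raise ConfigurationError("block sizes must sum to a positive count")
        for p in (self.p_in, self.p_out):
            if not 0 <= p <= 1:
                raise ConfigurationError("edge probabilities must lie in [0, 1]")


@dataclass
class ExpressionConfig:
    """nTPM-matrix generator settings.

    Baseline cells are lognormal with the given log-mean/log-sigma;
    planted (gene, region) cells are multiplied by ``fold``.
    """

    n_genes: int = 300
    regions: tuple[str, ...] = BRAIN_REGIONS
    baseline_log_mean: float = 0.7
    baseline_log_sigma: float = 0.4
    n_planted: int = 30
    fold: float = 10.0

    def __post_init__(self):
        if len(self.regions) < 2:
            raise ConfigurationError("need at least 2 regions")
        if self.fold <= 1 and self.n_planted > 0:
            raise ConfigurationError("planted fold must exceed 1")


@dataclass
class SimulationConfig:
    """Bundle of all generator settings plus the master seed."""

    seed: int = 0
    gwas: GwasConfig = field(default_factory=GwasConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    ppi: PpiConfig = field(default_factory=PpiConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)


def _zt_poisson(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse-CDF on the truncated law."""
    if size == 0:
        return np.zeros(0, dtype=int)
    from scipy.stats import poisson

    u = rng.uniform(poisson.cdf(0, rate), 1.0, size=size)
    return poisson.ppf(u, rate).astype(int)


def zt_poisson_tail(rate: float, min_count: int) -> float:
    """P(X >= min_count) for a zero-truncated Poisson — closed-form check."""
    from scipy.stats import poisson

    p0 = poisson.pmf(0, rate)
    return float((poisson.sf(min_count - 1, rate)) / (1.0 - p0))


def simulate_gwas(
    config: GwasConfig, condition_names: list[str], seed: int
) -> dict[str, pd.DataFrame]:
    """Generate per-condition association tables.

    Each condition gets ``n_genes`` private genes plus the shared genes its
    ``sharing`` entries demand; every gene's report count is a
    zero-truncated Poisson draw, one association row per report, and a
    ``fraction_geneless`` share of extra rows carries empty gene cells.
    """
    rng = np.random.default_rng(seed)
    shared_pools: dict[tuple[str, str], list[str]] = {}
    for pair, count in sorted(config.sharing.items()):
        key = tuple(sorted(pair))
        shared_pools[key] = [f"SHR_{key[0]}_{key[1]}_{i:04d}" for i in range(count)]

    tables = {}
    for condition in condition_names:
        genes = [f"G{condition[:3].upper()}{i:05d}" for i in range(config.n_genes)]
        for key, pool in shared_pools.items():
            if condition in key:
                genes = genes + pool
        counts = _zt_poisson(rng, config.report_rate, len(genes))
        rows = []
        serial = itertools.count()
        for gene, count in zip(genes, counts):
            for _ in range(int(count)):
                i = next(serial)
                rows.append((f"GCST{i:06d}", f"rs{rng.integers(1, 10**8)}", gene, condition))
        n_geneless = int(round(len(rows) * config.fraction_geneless / max(1e-12, 1 - config.fraction_geneless)))
        for _ in range(n_geneless):
            i = next(serial)
            rows.append((f"GCST{i:06d}", f"rs{rng.integers(1, 10**8)}", "", condition))
        frame = pd.DataFrame(
            rows, columns=["study_accession", "variant_id", "reported_genes", "trait"]
        )
        if len(frame):
            frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        tables[condition] = frame
    return tables


def simulate_annotation_and_query(
    config: AnnotationConfig, seed: int
) -> tuple[list[TermAnnotation], set[str], set[str]]:
    """Generate (annotation collection, background, query set).

    Terms are uniform samples from the background with Poisson-distributed
    sizes. The query of ``query_size`` genes is drawn without replacement
    with per-gene weights ``sampling_odds`` for members of the planted term
    and 1 otherwise; odds of 1 reduce to the uniform null, so the planted
    term's overlap follows the hypergeometric law.
    """
    if config.sampling_odds != 1.0 and config.planted_term is None:
        raise ConfigurationError("a planted term is required when sampling_odds != 1")
    rng = np.random.default_rng(seed)
    background = {f"B{i:05d}" for i in range(config.background_size)}
    universe = sorted(background)
    terms = []
    for t in range(config.n_terms):
        size = int(np.clip(rng.poisson(config.term_size_mean), 5, config.background_size))
        members = set(rng.choice(universe, size=size, replace=False))
        terms.append(TermAnnotation(f"T{t:04d}", f"synthetic term {t}", members, "CC"))
    if config.query_size > config.background_size:
        raise ParameterError("query size exceeds background")
    planted = next((t for t in terms if t.term_id == config.planted_term), None)
    weights = np.ones(len(universe))
    if planted is not None and config.sampling_odds != 1.0:
        member_mask = np.fromiter((g in planted.genes for g in universe), bool, len(universe))
        weights[member_mask] = config.sampling_odds
    probs = weights / weights.sum()
    query = set(rng.choice(universe, size=config.query_size, replace=False, p=probs))
    return terms, background, query


def simulate_ppi(config: PpiConfig, seed: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Generate an SBM edge list with Beta-distributed combined scores.

    Returns the edge-list frame (protein_a, protein_b, combined_score) and
    the ground-truth block label of every node.
    """
    rng = np.random.default_rng(seed)
    nodes, truth = [], {}
    for b, size in enumerate(config.block_sizes):
        for i in range(size):
            name = f"P{b}_{i:03d}"
            nodes.append(name)
            truth[name] = b
    rows = []
    for a, b in itertools.combinations(nodes, 2):
        same = truth[a] == truth[b]
        p = config.p_in if same else config.p_out
        if rng.uniform() < p:
            alpha, beta = config.beta_in if same else config.beta_out
            rows.append((a, b, round(float(rng.beta(alpha, beta)), 4)))
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])
    return edges, truth


def simulate_expression(
    config: ExpressionConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate an nTPM matrix with planted region-elevated genes.

    Baseline cells are lognormal; for each of the first ``n_planted``
    genes one region (round-robin) has its cell multiplied by ``fold``.
    Returns the matrix and the gene -> planted-region truth map.
    """
    rng = np.random.default_rng(seed)
    genes = [f"E{i:05d}" for i in range(config.n_genes)]
    values = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sigma,
        size=(config.n_genes, len(config.regions)),
    )
    truth = {}
    for i in range(min(config.n_planted, config.n_genes)):
        region_idx = i % len(config.regions)
        values[i, region_idx] *= config.fold
        truth[genes[i]] = config.regions[region_idx]
    matrix = pd.DataFrame(values, index=genes, columns=list(config.regions))
    return matrix, truth


def write_simulation(config: SimulationConfig, outdir, condition_names=None) -> None:
    """Write every simulated input (and its truth) under ``outdir``.

    Sub-seeds for the four generators are derived deterministically from
    the master seed.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    conditions = condition_names or ["ASD", "SCZ", "PD", "AD"]
    sub = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    for condition, table in simulate_gwas(config.gwas, conditions, seeds[0]).items():
        table.to_csv(outdir / f"gwas_{condition}.tsv", sep="\t", index=False)

    terms, background, query = simulate_annotation_and_query(config.annotation, seeds[1])
    with open(outdir / "annotation.gmt", "w") as handle:
        for t in terms:
            handle.write("\t".join([t.term_id, t.label, *sorted(t.genes)]) + "\n")
    pd.DataFrame({"gene_id": sorted(background)}).to_csv(
        outdir / "background.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(query)}).to_csv(
        outdir / "query.tsv", sep="\t", index=False)
    pd.DataFrame({"planted_term": [config.annotation.planted_term],
                  "sampling_odds": [config.annotation.sampling_odds]}).to_csv(
        outdir / "truth" / "enrichment.tsv", sep="\t", index=False)

    edges, blocks = simulate_ppi(config.ppi, seeds[2])
    edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    pd.DataFrame({"protein_id": list(blocks), "block": list(blocks.values())}).to_csv(
        outdir / "truth" / "ppi_blocks.tsv", sep="\t", index=False)

    matrix, elevated = simulate_expression(config.expression, seeds[3])
    matrix.to_csv(outdir / "ntpm.tsv", sep="\t")
    pd.DataFrame({"gene_id": list(elevated), "region": list(elevated.values())}).to_csv(
        outdir / "truth" / "elevated.tsv", sep="\t", index=False)
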