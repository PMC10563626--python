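"""Parse GWAS-catalog-style association tables and filter suggestive
candidate genes.

An association record is one SNP-trait association together with the gene
symbols / entrez IDs reported for it. The filtering rule keeps a gene for a
condition when it is reported in more than one association record (default
``min_reports=2``); associations with no gene information are excluded,
while symbols beginning with ``LOC`` are ordinary symbols and are kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from synoverlap.errors import ConfigurationError, ParameterError, ValidationError

#: logical column names every association table must provide
REQUIRED_COLUMNS = ("study_accession", "variant_id", "reported_genes", "trait")

# token separators used by catalog exports: commas, semicolons and the
# " - " convention marking intergenic hits between two flanking genes
_SEPARATORS = re.compile(r"[,;]")
_INTERGENIC = re.compile(r"\s+-\s+|\s+x\s+")

_NA_TOKENS = {"", "NA", "N/A", "NR", "NONE", "INTERGENIC", "NAN"}


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association with its reported gene mentions."""

    study_accession: str
    variant_id: str
    reported_genes: tuple[str, ...]
    trait_label: str


@dataclass
class CandidateGeneSet:
    """Per-condition suggestive candidate genes with report counts."""

    condition: str
    genes: dict[str, int]
    namespaces: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> set[str]:
        return set(self.genes)


def _normalize_token(token: str) -> tuple[str, str] | None:
    """Return ``(gene_id, namespace)`` for one raw gene token, or None.

    Symbols are upper-cased; purely numeric tokens are treated as entrez IDs
    and kept in their own namespace to avoid symbol/ID collisions.
    """
    token = token.strip()
    if token.upper() in _NA_TOKENS:
        return None
    if token.isdigit():
        return token, "entrez"
    return token.upper(), "symbol"


def split_gene_cell(cell: object, split_intergenic: bool = True) -> tuple[str, ...]:
    """Split one raw gene cell into distinct normalized tokens.

    Cells may contain several genes separated by "," or ";"; intergenic
    annotations like ``"GENE1 - GENE2"`` contribute both flanking genes
    unless ``split_intergenic`` is off (then the pair is dropped, since a
    hyphen-joined pair is not itself a gene identifier).
    """
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    raw = str(cell)
    pieces = []
    for part in _SEPARATORS.split(raw):
        if _INTERGENIC.search(part):
            if split_intergenic:
                pieces.extend(_INTERGENIC.split(part))
        else:
            pieces.append(part)
    seen: dict[str, str] = {}
    for piece in pieces:
        norm = _normalize_token(piece)
        if norm is not None and norm[0] not in seen:
            seen[norm[0]] = norm[1]
    return tuple(seen)


def token_namespace(gene_id: str) -> str:
    """Namespace of a normalized gene token (``entrez`` or ``symbol``)."""
    return "entrez" if gene_id.isdigit() else "symbol"


def parse_associations(
    path,
    dialect: dict[str, str] | None = None,
    split_intergenic: bool = True,
) -> list[AssociationRecord]:
    """Read an association table into :class:`AssociationRecord` objects.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Map from the logical column names (``study_accession``,
        ``variant_id``, ``reported_genes``, ``trait``) to the actual column
        names in the file. Identity by default.
    split_intergenic
        Whether ``"A - B"`` intergenic cells contribute both flanking genes.

    Rows with blank or NA gene cells yield records with empty
    ``reported_genes``; they are retained here and excluded downstream by
    :func:`filter_candidate_genes`.
    """
    dialect = dict(dialect or {})
    colmap = {logical: dialect.get(logical, logical) for logical in REQUIRED_COLUMNS}
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read association table {path!r}: {exc}") from exc
    for logical, actual in colmap.items():
        if actual not in table.columns:
            raise ConfigurationError(
                f"association table is missing required column {actual!r} "
                f"(mapped from {logical!r})"
            )
    records = []
    for row in table.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        records.append(
            AssociationRecord(
                study_accession=str(row[colmap["study_accession"]]).strip(),
                variant_id=str(row[colmap["variant_id"]]).strip(),
                reported_genes=split_gene_cell(
                    row[colmap["reported_genes"]], split_intergenic=split_intergenic
                ),
                trait_label=str(row[colmap["trait"]]).strip(),
            )
        )
    return records


def filter_candidate_genes(
    records: list[AssociationRecord],
    min_reports: int = 2,
    count_unit: str = "association",
) -> CandidateGeneSet:
    """Apply the suggestive-candidate-gene filter to one condition's records.

    Associations without gene information are excluded; each remaining
    association contributes at most one report per distinct gene; genes with
    ``report_count >= min_reports`` are retained. ``count_unit`` selects
    whether reports are counted over association records (default) or over
    distinct study accessions.
    """
    if min_reports < 1:
        raise ParameterError(f"min_reports must be >= 1, got {min_reports}")
    if count_unit not in ("association", "study"):
        raise ParameterError(f"count_unit must be 'association' or 'study', got {count_unit!r}")
    traits = {r.trait_label for r in records}
    if len(traits) > 1:
        raise ValidationError(f"records mix trait labels: {sorted(traits)}")
    condition = next(iter(traits)) if traits else ""

    counted: dict[str, set] = {}
    for i, rec in enumerate(records):
        if not rec.reported_genes:
            continue
        unit = rec.study_accession if count_unit == "study" else i
        for gene in rec.reported_genes:
            counted.setdefault(gene, set()).add(unit)
    genes = {g: len(u) for g, u in counted.items() if len(u) >= min_reports}
    return CandidateGeneSet(
        condition=condition,
        genes=dict(sorted(genes.items())),
        namespaces={g: token_namespace(g) for g in genes},
        provenance={"min_reports": min_reports, "count_unit": count_unit,
                    "n_associations": len(records),
                    "n_geneless": sum(1 for r in records if not r.reported_genes)},
    )


def write_candidate_genes(geneset: CandidateGeneSet, path) -> None:
    """Write a candidate gene set as TSV (gene_id, namespace, report_count)."""
    frame = pd.DataFrame(
        {
            "gene_id": list(geneset.genes),
            "namespace": [geneset.namespaces.get(g, token_namespace(g)) for g in geneset.genes],
            "report_count": list(geneset.genes.values()),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
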