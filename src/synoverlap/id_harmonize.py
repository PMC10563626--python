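"""Resolve heterogeneous gene/protein identifiers to a common namespace.

Mirrors a snapshot-based ortholog/ID conversion chain: an ordered list of
mapping tables (e.g. a UniProt export, then a bioDBnet export, then
manually curated HGNC/MGI lookups) is consulted in priority order; the
first table containing an identifier decides its fate. One-to-many
mappings are surfaced as ambiguous rather than silently collapsed, because
the manual-curation step they would require cannot be automated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from synoverlap.errors import ConfigurationError


@dataclass
class MappingSource:
    """One mapping table in the resolution chain.

    ``table`` maps a source identifier to one or more target identifiers;
    ``priority`` ranks the source within the chain (lower = consulted first).
    """

    name: str
    table: dict[str, list[str]]
    priority: int

    @classmethod
    def from_tsv(cls, name: str, path, priority: int,
                 source_col: str = "source_id", target_col: str = "target_id") -> "MappingSource":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        for col in (source_col, target_col):
            if col not in frame.columns:
                raise ConfigurationError(f"mapping table {path!r} lacks column {col!r}")
        table: dict[str, list[str]] = {}
        for src, tgt in zip(frame[source_col], frame[target_col]):
            src, tgt = str(src).strip(), str(tgt).strip()
            table.setdefault(src, [])
            if tgt not in table[src]:
                table[src].append(tgt)
        return cls(name=name, table=table, priority=priority)


@dataclass
class ResolutionReport:
    """Outcome of resolving a batch of identifiers.

    ``resolved``, ``unresolved`` and ``ambiguous`` partition the distinct
    input identifiers.
    """

    resolved: dict[str, tuple[str, str]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)

    def n_inputs(self) -> int:
        return len(self.resolved) + len(self.unresolved) + len(self.ambiguous)

    def targets(self) -> set[str]:
        return {target for target, _ in self.resolved.values()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"input_id": i, "status": "resolved", "target_id": t, "source": s}
            for i, (t, s) in self.resolved.items()
        ]
        rows += [
            {"input_id": i, "status": "ambiguous",
             "target_id": "|".join(ts), "source": ""}
            for i, ts in self.ambiguous.items()
        ]
        rows += [
            {"input_id": i, "status": "unresolved", "target_id": "", "source": ""}
            for i in self.unresolved
        ]
        return pd.DataFrame(rows, columns=["input_id", "status", "target_id", "source"])


class Resolver:
    """An ordered chain of :class:`MappingSource` tables."""

    def __init__(self, sources: list[MappingSource]):
        priorities = [s.priority for s in sources]
        if len(set(priorities)) != len(priorities):
            raise ConfigurationError(f"duplicate priorities in chain: {priorities}")
        self.sources = sorted(sources, key=lambda s: s.priority)

    def resolve(self, ids, normalize_case: bool = False) -> ResolutionReport:
        """Resolve identifiers through the chain.

        Each distinct input is decided by the first source containing it:
        a single target resolves it, several targets flag it ambiguous.
        Identifiers absent from every source are unresolved — a data fact,
        not an error. With ``normalize_case``, a mouse-style symbol is also
        tried in upper case (Nsf -> NSF) within each source.
        """
        report = ResolutionReport()
        seen = set()
        for raw in ids:
            ident = str(raw).strip()
            if not ident or ident in seen:
                continue
            seen.add(ident)
            hit = None
            for source in self.sources:
                targets = source.table.get(ident)
                if targets is None and normalize_case:
                    targets = source.table.get(ident.upper())
                if targets:
                    hit = (source.name, targets)
                    break
            if hit is None:
                report.unresolved.append(ident)
            elif len(hit[1]) == 1:
                report.resolved[ident] = (hit[1][0], hit[0])
            else:
                report.ambiguous[ident] = list(hit[1])
        return report


def build_resolver(sources: list[MappingSource]) -> Resolver:
    """Assemble a resolver; sources may be given in any order."""
    if not sources:
        raise ConfigurationError("resolution chain needs at least one source")
    return Resolver(list(sources))
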