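"""Packaged reference tables transcribed from the published cross-analysis.

The package ships small TSV snapshots of the printed result tables —
the Parkinson-pathway interactor list, the 92-protein synaptic
interactome, the interactome x GWAS overlap genes, the enriched GO terms
with fold enrichments, the regionally elevated gene crosstab and the
named cross-condition synaptic overlaps — together with the pinned scalar
constants (interactome size 483, 89 mouse-synaptic / 92 combined
interactors, the 66-node PPI network with clusters of 23/13/14/16, and
the per-condition filtered candidate-gene counts). Loaders validate each
table against the pinned constants so silent fixture corruption is caught
at load time.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from synoverlap.errors import FixtureError

_DATA = resources.files("synoverlap") / "data"


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_constants() -> dict:
    """Pinned scalar constants of the reference analysis."""
    return json.loads((_DATA / "constants.json").read_text())


def load_table1() -> pd.DataFrame:
    """Interactors annotated to the Parkinson-disease pathway (11 rows)."""
    return _read_tsv("table1_pd_pathway_proteins.tsv")


def load_table3() -> pd.DataFrame:
    """The 92 combined-species synaptic PANX1 interactors."""
    return _read_tsv("table3_synaptic_interactome.tsv")


def load_table4() -> pd.DataFrame:
    """Interactome genes that are also suggestive GWAS candidates."""
    return _read_tsv("table4_interactome_overlap.tsv")


def load_table5() -> pd.DataFrame:
    """Enriched GO terms (CC/BP) for the synaptic interactome."""
    frame = _read_tsv("table5_enriched_terms.tsv")
    frame["fold_enrichment"] = frame["fold_enrichment"].astype(float)
    frame["p_value"] = frame["p_value"].astype(float)
    return frame


def load_table6() -> pd.DataFrame:
    """Regionally elevated genes with their set labels (long format)."""
    return _read_tsv("table6_regional_elevated.tsv")


def load_fig3_overlaps() -> dict[tuple[str, ...], set[str]]:
    """Named cross-condition synaptic overlap partitions."""
    frame = _read_tsv("fig3_condition_overlaps.tsv")
    return {
        tuple(sorted(sig.split("&"))): set(genes.split(","))
        for sig, genes in zip(frame["signature"], frame["genes"])
    }


_VALIDATORS = {}


def _validator(name):
    def register(fn):
        _VALIDATORS[name] = fn
        return fn

    return register


@_validator("table1")
def _check_table1(const) -> dict:
    frame = load_table1()
    if len(frame) != 11 or frame["gene_symbol"].duplicated().any():
        raise FixtureError("table1 must hold 11 unique Parkinson-pathway proteins")
    return {"rows": len(frame)}


@_validator("table3")
def _check_table3(const) -> dict:
    frame = load_table3()
    expected = const["synaptic_interactome_combined"]
    if frame["uniprot_id"].nunique() != expected or len(frame) != expected:
        raise FixtureError(
            f"table3 must hold {expected} unique UniProt accessions, got "
            f"{frame['uniprot_id'].nunique()}"
        )
    if not frame["uniprot_id"].str.fullmatch(r"[A-Z][0-9][A-Z0-9]{3,8}[0-9]").all():
        raise FixtureError("table3 contains malformed UniProt accessions")
    return {"rows": len(frame)}


@_validator("table4")
def _check_table4(const) -> dict:
    frame = load_table4()
    counts = frame.groupby("condition").size().to_dict()
    expected = const["interactome_overlap_counts"]
    observed = {
        "SCZ": counts.get("schizophrenia", 0),
        "PD": counts.get("Parkinson's disease", 0),
        "AD": counts.get("Alzheimer's disease", 0),
        "ASD": int(frame["asd_shared"].astype(int).sum()),
    }
    if observed != expected:
        raise FixtureError(f"table4 counts {observed} != pinned {expected}")
    starred = frame[frame["asd_shared"].astype(int) == 1]
    if not (starred["condition"] == "schizophrenia").all():
        raise FixtureError("every ASD-starred gene must sit in the schizophrenia list")
    return observed


@_validator("table5")
def _check_table5(const) -> dict:
    frame = load_table5()
    cc = frame[frame["domain"] == "CC"]
    bp = frame[frame["domain"] == "BP"]
    if (cc["fold_enrichment"] < 5).any() or (bp["fold_enrichment"] < 2).any():
        raise FixtureError("table5 rows violate the per-domain fold-enrichment floors")
    if (frame["p_value"] >= 0.05).any():
        raise FixtureError("table5 rows must all be FDR-significant")
    return {"rows": len(frame), "cc_min_fe": float(cc["fold_enrichment"].min())}


@_validator("table6")
def _check_table6(const) -> dict:
    frame = load_table6()
    labels = frame.set_index(["gene_id", "region"])["set_labels"].str.split(",")
    per_set = {}
    for name in ("PANX1", "SCZ", "ASD", "PD", "AD"):
        per_set[name] = frame[frame["set_labels"].str.contains(name)]["gene_id"].nunique()
    if per_set["SCZ"] != 16 or per_set["ASD"] != 11:
        raise FixtureError(f"table6 per-condition elevated-gene counts off: {per_set}")
    if labels.index.duplicated().any():
        raise FixtureError("table6 has duplicate (gene, region) rows")
    return per_set


@_validator("fig3")
def _check_fig3(const) -> dict:
    overlaps = load_fig3_overlaps()
    expected = {
        ("AD", "PD"): {"APOE", "MAPT"},
        ("AD", "SCZ"): {"ADAM10", "PTK2B"},
        ("PD", "SCZ"): {"DLG2", "FYN"},
        ("AD", "ASD", "SCZ"): {"CLU", "MEF2C"},
        ("ASD", "PD", "SCZ"): {"IGSF9B"},
    }
    if overlaps != expected:
        raise FixtureError("fig3 overlap partitions do not match the pinned lists")
    return {"partitions": len(overlaps)}


def validate_fixture(name: str) -> dict:
    """Validate one packaged fixture against the pinned constants.

    Returns a small report dict; raises :class:`FixtureError` on any
    inconsistency.
    """
    if name not in _VALIDATORS:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_VALIDATORS)}")
    return _VALIDATORS[name](load_constants())


def validate_all() -> dict[str, dict]:
    return {name: validate_fixture(name) for name in sorted(_VALIDATORS)}
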