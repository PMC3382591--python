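"""Readers and writers for the flat-text formats the pipeline consumes.

Everything is plain TSV / BED-like / SIF / GMT text so that inputs can be
inspected and version-controlled. Coordinates are 0-based half-open
throughout (BED convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catalogue import RegulationCatalogue
from .errors import ContractError
from .matrices import ExpressionMatrix

# float format used by every writer so reruns are byte-identical
_FFMT = "%.10g"


# ---------------------------------------------------------------- expression

def read_expression(expr_path, samples_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id).

    ``samples_path`` is a two-column TSV mapping sample id -> cell line;
    when omitted every column is treated as its own line.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if samples_path is None:
        return ExpressionMatrix.from_single_samples(values)
    smap = pd.read_csv(samples_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values, smap)


def write_expression(expr: ExpressionMatrix, expr_path, samples_path=None) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t", float_format=_FFMT)
    if samples_path is not None:
        smap = expr.sample_to_line.rename("line")
        smap.index.name = "sample"
        smap.to_csv(samples_path, sep="\t")


# ----------------------------------------------------------------- catalogue

def read_catalogue(path) -> RegulationCatalogue:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return RegulationCatalogue(df)


def write_catalogue(catalogue: RegulationCatalogue, path) -> None:
    catalogue.entries.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- regions

def read_regions(regions_path, values_path):
    """GISTIC-style significant regions.

    ``regions_path``: BED-like TSV with columns chrom, start, end,
    region_id, type (amp|del), q. ``values_path``: one row per peak with a
    region_id column followed by per-sample log2-ratio columns; several
    peak rows may share a region_id.
    """
    regions = pd.read_csv(regions_path, sep="\t")
    need = {"chrom", "start", "end", "region_id", "type", "q"}
    if not need.issubset(regions.columns):
        raise ContractError(f"region table missing columns {sorted(need - set(regions.columns))}")
    if (regions["start"] >= regions["end"]).any():
        raise ContractError("region table has start >= end (coordinates are 0-based half-open)")
    if ((regions["q"] < 0) | (regions["q"] > 1)).any():
        raise ContractError("region q-values must lie in [0, 1]")
    values = pd.read_csv(values_path, sep="\t")
    if "region_id" not in values.columns:
        raise ContractError("region values table needs a region_id column")
    return regions, values


def write_regions(regions: pd.DataFrame, values: pd.DataFrame, regions_path, values_path) -> None:
    cols = ["chrom", "start", "end", "region_id", "type", "q"]
    regions[cols].to_csv(regions_path, sep="\t", index=False, float_format=_FFMT)
    values.to_csv(values_path, sep="\t", index=False, float_format=_FFMT)


def read_gene_locations(path) -> pd.DataFrame:
    """BED4: chrom, start, end, gene id; 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
                     comment="#")
    if df["gene"].duplicated().any():
        raise ContractError("duplicate gene ids in location table")
    if (df["start"] >= df["end"]).any():
        raise ContractError("gene locations have start >= end")
    return df


def write_gene_locations(locations: pd.DataFrame, path) -> None:
    locations[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------------- PPI

def read_ppi_edges(path) -> pd.DataFrame:
    """PPI edge list: SIF (``a interacts b``) or TSV (a, b, evidence).

    Returns a DataFrame with columns a, b, evidence (SIF edges get
    evidence 1, the minimum).
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    sif = len(first.split("\t")) == 3 and first.split("\t")[1] == "interacts"
    if sif:
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "rel", "b"])
        df = df[["a", "b"]].assign(evidence=1)
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "evidence"],
                         comment="#")
    return df


def write_sif(edges, path) -> None:
    """Write (a, b) pairs as a SIF file."""
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tinteracts\t{b}\n")


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT-like: set name <tab> description <tab> gene ids..."""
    sets: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ContractError(f"GMT line with <3 fields: {line[:60]!r}")
        sets[fields[0]] = frozenset(g for g in fields[2:] if g)
    if not sets:
        raise ContractError("empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, frozenset[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


# ---------------------------------------------------------- phenotype/clinic

def read_phenotypes(path) -> pd.Series:
    """Sample id -> phenotype (cancer | inflammation | healthy)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_phenotypes(phenotypes: pd.Series, path) -> None:
    s = phenotypes.rename("phenotype")
    s.index.name = "sample"
    s.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Patient id (index), follow-up time (>0) and event status in {0,1}."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ContractError("duplicate patients in clinical table")
    if (df["time"] <= 0).any():
        raise ContractError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ContractError("event status must be 0 or 1")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical[["time", "event"]].copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t", float_format=_FFMT)


# ------------------------------------------------------------------ manifest

def write_manifest(manifest: Mapping, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
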