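"""Readers and writers for the pipeline's external table formats.

Everything on disk is a small standard text dialect: tab-delimited
tables with explicit headers, GMT for the category database, and one-id-
per-line presence lists.  Loading validates the schema and reports the
offending file, line and column instead of silently coercing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dea import CountMatrix
from .errors import SchemaError
from .synthdata import TruthTable, sha256_file
from .wspp import CategoryDB

log = logging.getLogger(__name__)


def parse_gmt(path: str | Path) -> CategoryDB:
    """Parse a GMT file: name, description, tab-separated members.

    Duplicate members within a line are deduplicated; a duplicated
    category name or a line with fewer than three fields is an error
    naming the line.
    """
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise SchemaError(f"{path}: line {lineno}: duplicate category name {name!r}")
            members = frozenset(m for m in members if m)
            if not members:
                raise SchemaError(f"{path}: line {lineno}: category {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return CategoryDB(sets, descriptions)


def write_gmt(db: CategoryDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(db.sets):
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(db.sets[name])]) + "\n")


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read the gene x sample count table and the sample -> group design."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    for j, col in enumerate(counts.columns):
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            gene = counts.index[bad.to_numpy().argmax()]
            raise SchemaError(
                f"{counts_path}: invalid count at gene {gene!r}, sample {col!r} (column {j + 2})"
            )
        counts[col] = vals.astype(np.int64)
    design_df = pd.read_csv(design_path, sep="\t")
    if list(design_df.columns[:2]) != ["sample", "group"]:
        raise SchemaError(f"{design_path}: expected columns 'sample' and 'group'")
    design = design_df.set_index("sample")["group"]
    return CountMatrix(counts, design)


def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.design.rename_axis("sample").rename("group").to_csv(design_path, sep="\t")


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read the spectrum-level quantification table."""
    df = pd.read_csv(path, sep="\t")
    required = ["spectrum_id", "peptide_id", "protein_id", "log2_ratio", "weight", "comparison"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad = w.isna() | (w <= 0)
    if bad.any():
        line = int(bad.to_numpy().argmax()) + 2  # header + 1-based
        raise SchemaError(f"{path}: line {line}: non-positive weight")
    x = pd.to_numeric(df["log2_ratio"], errors="coerce")
    if x.isna().any():
        line = int(x.isna().to_numpy().argmax()) + 2
        raise SchemaError(f"{path}: line {line}: non-numeric log2_ratio")
    df["weight"] = w.astype(float)
    df["log2_ratio"] = x.astype(float)
    return df


def write_spectra(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["spectrum_id", "peptide_id", "protein_id", "log2_ratio", "weight", "comparison"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_compartments(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["entity", "compartment"]:
        raise SchemaError(f"{path}: expected columns 'entity' and 'compartment'")
    dup = df["entity"].duplicated()
    if dup.any():
        line = int(dup.to_numpy().argmax()) + 2
        raise SchemaError(f"{path}: line {line}: duplicate entity id")
    return df.set_index("entity")["compartment"]


def write_compartments(compartments: pd.Series, path: str | Path) -> None:
    compartments.rename_axis("entity").rename("compartment").to_csv(path, sep="\t")


def read_presence(path: str | Path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_presence(ids, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity in sorted(ids):
            fh.write(f"{entity}\n")


@dataclass
class Bundle:
    """All typed pipeline inputs loaded from one directory."""

    count_matrix: CountMatrix
    spectra: pd.DataFrame
    categories: CategoryDB
    compartments: pd.Series
    whole_extract: dict[str, frozenset]
    membrane_fraction: dict[str, frozenset]
    manifest: dict | None = None
    truth: TruthTable | None = None


def load_bundle(directory: str | Path) -> Bundle:
    """Load a fixture bundle written by ``write_fixture_bundle``.

    Validates every table on load; the optional truth tables and the
    manifest are attached when present.
    """
    d = Path(directory)
    cm = read_counts(d / "counts.tsv", d / "design.tsv")
    spectra = read_spectra(d / "spectra.tsv")
    categories = parse_gmt(d / "categories.gmt")
    compartments = read_compartments(d / "compartments.tsv")
    whole_extract: dict[str, frozenset] = {}
    membrane_fraction: dict[str, frozenset] = {}
    for p in sorted((d / "presence").glob("whole_extract_*.txt")):
        whole_extract[p.stem.removeprefix("whole_extract_")] = read_presence(p)
    for p in sorted((d / "presence").glob("membrane_fraction_*.txt")):
        membrane_fraction[p.stem.removeprefix("membrane_fraction_")] = read_presence(p)
    if not whole_extract:
        raise SchemaError(f"{d}: no presence lists found under presence/")
    manifest = None
    if (d / "manifest.json").exists():
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
    truth = None
    if (d / "truth_entities.tsv").exists():
        ent = pd.read_csv(d / "truth_entities.tsv", sep="\t", index_col=0)
        cats = pd.read_csv(d / "truth_categories.tsv", sep="\t", index_col=0)
        truth = TruthTable(entities=ent, categories=cats)
    return Bundle(cm, spectra, categories, compartments, whole_extract, membrane_fraction, manifest, truth)


__all__ = [
    "Bundle",
    "load_bundle",
    "parse_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_spectra",
    "write_spectra",
    "read_compartments",
    "write_compartments",
    "read_presence",
    "write_presence",
    "sha256_file",
]
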