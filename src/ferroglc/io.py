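"""Readers and writers for the pipeline's tabular interchange formats.

All on-disk formats are plain TSV: an abundance table (rows = proteins,
first column ``protein_id``, an ``n_unique_peptides`` column, one column per
sample), a sample-metadata table, annotation-set tables
(``set_id, label, member``) and ortholog-map tables
(``species, gene_id, group_id``). Outputs are TSV plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    AbundanceMatrix,
    AnnotationSet,
    OrthologMap,
    PipelineConfig,
    SampleRecord,
)

log = logging.getLogger("ferroglc")

_TRUE = {"1", "true", "yes", "y", "t"}


def _parse_level(value, column: str) -> int:
    text = str(value).strip().lower()
    if text in {"+", "+1", "1", "plus", "pos"}:
        return 1
    if text in {"-", "-1", "minus", "neg"}:
        return -1
    raise ValueError(f"cannot parse {column}={value!r} as a +/- level")


def read_sample_metadata(path) -> list[SampleRecord]:
    """Read the ``sample_id,strain,fe,glc,replicate,batch,excluded`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "fe", "glc", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                strain=row.strain,
                fe=_parse_level(row.fe, "fe"),
                glc=_parse_level(row.glc, "glc"),
                replicate=int(row.replicate),
                batch=getattr(row, "batch", "") or "",
                excluded=str(getattr(row, "excluded", "0")).strip().lower() in _TRUE,
            )
        )
    return records


def read_abundance_table(
    path,
    metadata_path,
    config: PipelineConfig | None = None,
    values_are_log2: bool = False,
) -> AbundanceMatrix:
    """Read an abundance TSV plus its sample metadata into an AbundanceMatrix.

    Excluded samples are dropped on read. Empty/NA cells become missing
    values; zeros and negative abundances are rejected (log2 must be
    defined). ``values_are_log2`` must be set explicitly when the file
    stores log2 abundances — they are de-logged so the matrix is always on
    the linear scale; there is no auto-detection.
    """
    del config  # reserved for future format options
    samples = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "protein_id":
        raise ValueError("first abundance column must be 'protein_id'")
    if "n_unique_peptides" not in df.columns:
        raise ValueError("abundance table requires an 'n_unique_peptides' column")
    df = df.set_index("protein_id")
    peptides = df.pop("n_unique_peptides").astype(int)

    known = {s.sample_id for s in samples}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"abundance columns without sample metadata: {unknown}")

    kept = [s for s in samples if not s.excluded and s.sample_id in df.columns]
    values = df[[s.sample_id for s in kept]].astype(float)
    if values_are_log2:
        values = np.power(2.0, values)
    return AbundanceMatrix(values, kept, peptides)


def write_abundance_matrix(matrix: AbundanceMatrix, abundance_path, metadata_path) -> None:
    """Write a matrix back to the TSV dialect :func:`read_abundance_table` reads."""
    out = matrix.values.copy()
    out.insert(0, "n_unique_peptides", matrix.unique_peptides)
    out = out.sort_index()
    out.to_csv(abundance_path, sep="\t", index_label="protein_id", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "strain": [s.strain for s in matrix.samples],
            "fe": [s.fe for s in matrix.samples],
            "glc": [s.glc for s in matrix.samples],
            "replicate": [s.replicate for s in matrix.samples],
            "batch": [s.batch for s in matrix.samples],
            "excluded": [int(s.excluded) for s in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_annotation_sets(path) -> dict[str, AnnotationSet]:
    """Read a ``set_id, label, member[, score]`` TSV into AnnotationSets."""
    df = pd.read_csv(path, sep="\t", dtype={"set_id": str, "label": str, "member": str})
    required = {"set_id", "member"}
    if required - set(df.columns):
        raise ValueError("annotation table requires 'set_id' and 'member' columns")
    sets: dict[str, AnnotationSet] = {}
    for set_id, grp in df.groupby("set_id", sort=True):
        label = str(grp["label"].iloc[0]) if "label" in grp.columns else str(set_id)
        scores = None
        if "score" in grp.columns:
            scores = dict(zip(grp["member"], grp["score"].astype(float)))
        sets[str(set_id)] = AnnotationSet.from_members(str(set_id), grp["member"], label, scores)
    return sets


def read_ortholog_maps(path) -> dict[str, OrthologMap]:
    """Read a ``species, gene_id, group_id`` TSV into per-species OrthologMaps."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"species", "gene_id", "group_id"} - set(df.columns):
        raise ValueError("ortholog map requires species, gene_id, group_id columns")
    maps = {}
    for species, grp in df.groupby("species", sort=True):
        if grp["gene_id"].duplicated().any():
            dup = grp.loc[grp["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"gene {dup!r} maps to more than one group in {species!r}")
        maps[str(species)] = OrthologMap(str(species), dict(zip(grp["gene_id"], grp["group_id"])))
    return maps


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    overwrite: bool = False,
    extra_manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a JSON run manifest.

    Rows are sorted by protein id (first column) where present and columns
    are written in their given order, so identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
        out = table.copy()
        if "protein_id" in out.columns:
            out = out.sort_values("protein_id", kind="mergesort")
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = path
        log.info("wrote %s (%d rows)", path.name, len(out))

    manifest = {
        "config": (config or PipelineConfig()).to_dict(),
        "seed": seed,
        "tables": {name: {"rows": int(len(tables[name])), "sha256_16": _digest(p)}
                   for name, p in paths.items()},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["run_manifest"] = manifest_path
    return paths
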