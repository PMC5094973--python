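"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as plain TSV (genes in rows, header = sample ids)
or GCT v1.2; sample annotation and ortholog maps as two-column TSV; gene sets
as GMT. Values are assumed already log2-normalized — loaders never transform
them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .containers import ExpressionMatrix, GeneSet, OrthologMap, ValidationError

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("strict", "drop")


def read_annotation(path) -> pd.Series:
    """Read a two-column (sample_id, label) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValidationError(f"annotation file {path} must have exactly 2 columns")
    ann = pd.Series(df[1].values, index=df[0].values, name="label")
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValidationError(f"annotation lists sample(s) more than once: {dups}")
    return ann


def _finalize_matrix(values: pd.DataFrame, annotation: pd.Series,
                     missing_policy: str) -> ExpressionMatrix:
    if missing_policy not in MISSING_POLICIES:
        raise ValidationError(f"missing_policy must be one of {MISSING_POLICIES}")
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s): {dups}")
    if values.isna().any().any():
        if missing_policy == "strict":
            n_bad = int(values.isna().any(axis=1).sum())
            raise ValidationError(
                f"{n_bad} gene row(s) contain missing values (missing_policy=strict)"
            )
        before = len(values)
        values = values.dropna(axis=0)
        logger.info("dropped %d gene row(s) with missing values", before - len(values))
    unmatched = [s for s in values.columns if s not in annotation.index]
    if unmatched:
        raise ValidationError(f"annotation missing sample(s): {unmatched}")
    values.index.name = "gene_id"
    values.columns.name = None
    return ExpressionMatrix(values.astype(float), annotation)


def read_expression(path, annotation_path, fmt: str = "tsv",
                    missing_policy: str = "strict") -> ExpressionMatrix:
    """Load an expression matrix (TSV or GCT v1.2) with its annotation.

    ``missing_policy='drop'`` removes gene rows with any missing value;
    ``'strict'`` raises instead.
    """
    annotation = read_annotation(annotation_path)
    if fmt == "tsv":
        values = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "gct":
        values = _read_gct(path)
    else:
        raise ValidationError(f"unknown expression format {fmt!r}; use 'tsv' or 'gct'")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return _finalize_matrix(values, annotation, missing_policy)


def _read_gct(path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValidationError(f"GCT file {path} must start with '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValidationError(f"GCT file {path}: malformed dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ValidationError(
            f"GCT file {path}: declared dims ({n_genes},{n_samples}) "
            f"do not match data {df.shape}"
        )
    return df


def write_expression(matrix: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = matrix.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")


def write_annotation(annotation: pd.Series, path) -> None:
    annotation.to_csv(path, sep="\t", header=False)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name, description, members per tab-separated line.

    Names suffixed _UP/_DN get the corresponding direction.
    """
    sets: list[GeneSet] = []
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet.from_members(name, members))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{description}\t{members}\n")


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column (source_gene, target_gene) TSV; one-to-many allowed."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValidationError(f"ortholog map {path} must have exactly 2 columns")
    pairs: dict = {}
    for src, tgt in df.itertuples(index=False):
        pairs.setdefault(src, set()).add(tgt)
    return OrthologMap({k: frozenset(v) for k, v in pairs.items()})


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        for src in sorted(omap.pairs):
            for tgt in sorted(omap.pairs[src]):
                fh.write(f"{src}\t{tgt}\n")
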