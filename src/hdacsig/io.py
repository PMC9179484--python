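"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: GMT (Broad dialect) for gene sets and up/down signatures, RNK for
ranked gene lists, and tab-delimited UTF-8 tables for expression, response,
mutation, score and report payloads.  Floats are written with 12 significant
digits so write-then-read round-trips reproduce values exactly at that
precision.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MutationTable,
    ResponseTable,
    Signature,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

FLOAT_FMT = "%.12g"
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene TAB gene...

    Duplicate genes within one line are dropped (first occurrence wins) with
    a logged warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    names_seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in names_seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names_seen.add(name)
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: set %r listed %d duplicate gene(s); deduplicated",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets.append(GeneSet(name=name, description=description, genes=tuple(deduped)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression(
    path: PathLike, max_missing_fraction: float = 0.5
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column = gene id).

    Genes with more than ``max_missing_fraction`` missing values are dropped
    (logged); remaining missing values are imputed with the per-gene median.
    Non-numeric, non-missing cells raise a ParseError naming the coordinates.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, encoding="utf-8",
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene id(s): {dupes[:5]}")

    values = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell in _MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None

    missing_frac = np.isnan(values).mean(axis=1)
    keep = missing_frac <= max_missing_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d gene(s) with >%.0f%% missing values",
            path, n_dropped, 100 * max_missing_fraction,
        )
    values = values[keep]
    index = df.index[keep]

    # per-gene median imputation for the survivors
    nan_rows = np.isnan(values).any(axis=1)
    if nan_rows.any():
        medians = np.nanmedian(values[nan_rows], axis=1)
        for row, med in zip(np.where(nan_rows)[0], medians):
            values[row, np.isnan(values[row])] = med
        logger.info("%s: imputed missing values in %d gene(s)", path, int(nan_rows.sum()))

    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=df.columns))


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    _write_frame(expr.data, path, index_label="gene")


# ---------------------------------------------------------------------------
# Response / mutation tables


def read_response(path: PathLike, unit: str = "percent_death") -> ResponseTable:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    return ResponseTable(df.astype(float), unit=unit)


def write_response(table: ResponseTable, path: PathLike) -> None:
    _write_frame(table.data, path, index_label="sample")


def read_mutations(path: PathLike) -> MutationTable:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    return MutationTable(df)


def write_mutations(table: MutationTable, path: PathLike) -> None:
    table.flags.to_csv(path, sep="\t", index_label="sample", encoding="utf-8")


# ---------------------------------------------------------------------------
# Signatures (two-line GMT dialect, _UP / _DN suffixes)

UP_SUFFIX = "_UP"
DOWN_SUFFIX = "_DN"


def write_signature(signature: Signature, path: PathLike) -> None:
    """Write a signature as a GMT with up to two lines: NAME_UP and NAME_DN."""
    sets = []
    if signature.up_genes:
        sets.append(
            GeneSet(signature.name + UP_SUFFIX, "up-regulated genes", signature.up_genes)
        )
    if signature.down_genes:
        sets.append(
            GeneSet(signature.name + DOWN_SUFFIX, "down-regulated genes", signature.down_genes)
        )
    write_gmt(GeneSetCollection(sets), path)


def read_signature(path: PathLike) -> Signature:
    collection = read_gmt(path)
    up: tuple[str, ...] = ()
    down: tuple[str, ...] = ()
    name = None
    for s in collection:
        if s.name.endswith(UP_SUFFIX):
            up = s.genes
            name = s.name[: -len(UP_SUFFIX)]
        elif s.name.endswith(DOWN_SUFFIX):
            down = s.genes
            name = s.name[: -len(DOWN_SUFFIX)]
        else:
            raise ParseError(
                f"{path}: signature set {s.name!r} lacks {UP_SUFFIX}/{DOWN_SUFFIX} suffix"
            )
    if name is None:
        raise ParseError(f"{path}: empty signature file")
    return Signature(name=name, up_genes=up, down_genes=down)


# ---------------------------------------------------------------------------
# RNK ranked lists


def write_rnk(gene_ids, metric, path: PathLike) -> None:
    pd.DataFrame({"gene": list(gene_ids), "metric": np.asarray(metric, dtype=float)}).to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT, encoding="utf-8"
    )


def read_rnk(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"], encoding="utf-8")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene in RNK file")
    return pd.Series(df["metric"].to_numpy(dtype=float), index=df["gene"].astype(str))


# ---------------------------------------------------------------------------
# shared helpers


def _write_frame(df: pd.DataFrame, path: PathLike, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT, encoding="utf-8")


def write_table(df: pd.DataFrame, path: PathLike, index_label: str = "id") -> None:
    """Write any report table with the package-wide float format."""
    _write_frame(df, path, index_label=index_label)
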