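"""Readers and writers for the plain-text formats used across the pipeline.

MTX triplets (MatrixMarket coordinate + genes.tsv + barcodes.tsv, CellRanger
orientation: genes x cells), GMT gene-set files, and the CSV conventions for
HTO/ADT tables, contig annotations, bulk expression and clinical records.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# MTX triplet (genes x cells on disk; AnnData is cells x genes in memory)
# ---------------------------------------------------------------------------

def write_mtx_dir(adata: ad.AnnData, directory: str | os.PathLike) -> dict[str, str]:
    """Write an expression AnnData as matrix.mtx + genes.tsv + barcodes.tsv.

    Cell metadata (obs) is written alongside as cells.csv so the triplet
    round-trips through :func:`read_mtx_dir`.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "matrix": os.path.join(directory, "matrix.mtx"),
        "genes": os.path.join(directory, "genes.tsv"),
        "barcodes": os.path.join(directory, "barcodes.tsv"),
        "cells": os.path.join(directory, "cells.csv"),
    }
    mat = adata.X
    if not sp.issparse(mat):
        mat = sp.csr_matrix(np.asarray(mat))
    scipy.io.mmwrite(paths["matrix"], mat.T.astype(mat.dtype))
    pd.Series(adata.var_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    adata.obs.to_csv(paths["cells"])
    return paths


def read_mtx_dir(directory: str | os.PathLike) -> ad.AnnData:
    """Read a genes x cells MTX triplet back into a cells x genes AnnData."""
    directory = os.fspath(directory)
    mat = scipy.io.mmread(os.path.join(directory, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(directory, "barcodes.tsv"), sep="\t", header=None)[0]
    adata = ad.AnnData(
        X=mat.tocsr(),
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str), name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes.astype(str), name="gene")),
    )
    cells_path = os.path.join(directory, "cells.csv")
    if os.path.exists(cells_path):
        meta = pd.read_csv(cells_path, index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(signatures: Iterable, path: str | os.PathLike) -> str:
    """Write gene sets as GMT lines ``name<TAB>description<TAB>gene...``.

    Accepts objects with ``.name``/``.genes`` (and optional ``.description``)
    or ``(name, description, genes)`` tuples. Empty gene lists are refused.
    """
    lines = []
    for sig in signatures:
        if isinstance(sig, tuple):
            name, desc, genes = sig
        else:
            name = sig.name
            desc = getattr(sig, "description", "") or "na"
            genes = list(sig.genes)
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty; refusing to write")
        lines.append("\t".join([str(name), str(desc or "na"), *map(str, genes)]))
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(os.fspath(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = fields[2:]
    return sets


# ---------------------------------------------------------------------------
# CSV conventions
# ---------------------------------------------------------------------------

def read_tag_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tags x barcodes count table (wide CSV, tags as rows)."""
    df = pd.read_csv(os.fspath(path), index_col=0)
    return df


def write_tag_counts(df: pd.DataFrame, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    df.to_csv(path)
    return path


def read_contigs(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 10x-style filtered-contig CSV (barcode, chain, cdr3, cdr3_nt, productive)."""
    return pd.read_csv(os.fspath(path))


def read_bulk_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x patients log2 expression CSV."""
    return pd.read_csv(os.fspath(path), index_col=0)


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Read a clinical CSV indexed by patient (os_months, os_event, stage, ...)."""
    return pd.read_csv(os.fspath(path), index_col=0)


def write_fixture_csvs(tables: Mapping[str, pd.DataFrame], directory: str | os.PathLike) -> dict[str, str]:
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    out = {}
    for name, df in tables.items():
        out[name] = os.path.join(directory, f"{name}.csv")
        df.to_csv(out[name])
    return out
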