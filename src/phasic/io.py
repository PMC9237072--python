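"""Readers and writers for count matrices, annotations and call tables.

On-disk formats are deliberately plain: TSV (tab-separated, UTF-8, header
row) and Matrix Market coordinate files with two companion one-column label
files.  The reader accepts matrices stored in either orientation and uses
the label files to decide which axis is genes.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, ValidationError, normalize_phase

NA_REP = "NA"


def _label_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return Path(str(base) + ".genes.txt"), Path(str(base) + ".units.txt")


def read_count_matrix(path, format: str | None = None,
                      layer_name: str = "umi") -> CountMatrix:
    """Read a count matrix from TSV or MTX.

    For ``format="tsv"`` the first column holds gene ids and the header row
    unit ids.  For ``format="mtx"`` the companion files ``<base>.genes.txt``
    and ``<base>.units.txt`` must exist next to the matrix; the matrix may be
    stored genes x units or units x genes and is re-oriented using the label
    file lengths.  If *format* is omitted it is inferred from the suffix.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as e:
            raise ValidationError(f"malformed TSV {path}: {e}") from e
        return CountMatrix(df.index.to_numpy(dtype=str),
                           df.columns.to_numpy(dtype=str),
                           df.to_numpy(), layer_name)
    if format != "mtx":
        raise ValidationError(f"unknown format {format!r}")
    gpath, upath = _label_paths(path)
    for p in (gpath, upath):
        if not p.exists():
            raise ValidationError(f"missing companion label file {p}")
    genes = np.loadtxt(gpath, dtype=str, ndmin=1)
    units = np.loadtxt(upath, dtype=str, ndmin=1)
    try:
        mat = scipy.io.mmread(path)
    except Exception as e:
        raise ValidationError(f"malformed MTX {path}: {e}") from e
    mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    if mat.shape == (genes.size, units.size):
        pass
    elif mat.shape == (units.size, genes.size):
        mat = mat.T
    else:
        raise ValidationError(
            f"matrix shape {mat.shape} matches neither orientation of "
            f"{genes.size} genes x {units.size} units")
    return CountMatrix(genes, units, mat, layer_name)


def write_count_matrix(cm: CountMatrix, path, format: str | None = None) -> None:
    """Write a count matrix as TSV or MTX (+ label files); genes as rows."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format != "mtx":
        raise ValidationError(f"unknown format {format!r}")
    gpath, upath = _label_paths(path)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts), field="integer")
    np.savetxt(gpath, cm.gene_ids, fmt="%s")
    np.savetxt(upath, cm.unit_ids, fmt="%s")


def read_annotations(path) -> pd.DataFrame:
    """Read a per-unit annotation TSV.

    Requires columns ``unit_id`` and ``phase``; ``lineage``, ``genotype``,
    ``stage`` and ``replicate`` are optional.  Phase labels are normalized to
    the canonical {G1, G2M} pair.  Derived QC fields are not computed here
    (see :func:`phasic.containers.compute_qc_fields`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("unit_id", "phase"):
        if col not in df.columns:
            raise ValidationError(f"annotation table missing required column {col!r}")
    if df["unit_id"].duplicated().any():
        raise ValidationError("duplicated unit_id in annotation table")
    df["phase"] = normalize_phase(df["phase"])
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a per-gene call table as TSV with a stable column order.

    Missing values are serialized as ``NA``.  ``gene_id`` comes first,
    followed by the canonical effect/p-value columns when present, then any
    remaining (e.g. per-lineage) columns in their existing order.
    """
    if table.empty:
        raise ValidationError("refusing to write an empty results table")
    lead = [c for c in ("gene_id", "log2fc", "p_value", "adj_p", "phasic_call")
            if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    table = table[lead + rest]
    try:
        table.to_csv(path, sep="\t", index=False, na_rep=NA_REP)
    except OSError as e:
        raise OSError(f"cannot write results to {path}: {e}") from e


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    if "phasic_call" in df.columns:
        df["phasic_call"] = df["phasic_call"].astype(bool)
    return df
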