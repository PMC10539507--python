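"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression and activity matrices travel as GCT 1.2 or TSV (genes/TFs in
rows, samples in columns); phenotype and survival tables as TSV with a
``sample_id`` column.
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import ValidationError

__all__ = [
    "read_gct",
    "write_gct",
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
]


def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GCT 1.2 file into a genes x samples DataFrame.

    The Description column is discarded; row identifiers come from the
    Name column.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValidationError(f"not a GCT 1.2 file: {path!r} (header {version!r})")
        dims = fh.readline().split()
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise ValidationError(
            f"GCT dimension line says {n_rows}x{n_cols} but table is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    df.index.name = "gene_id"
    return df


def write_gct(df: pd.DataFrame, path: str | os.PathLike, descriptions=None) -> None:
    """Write a genes x samples DataFrame as GCT 1.2."""
    n_rows, n_cols = df.shape
    desc = descriptions if descriptions is not None else ["na"] * n_rows
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for (name, row), d in zip(df.iterrows(), desc):
            fh.write(str(name) + "\t" + str(d) + "\t" + "\t".join(repr(v) for v in row) + "\n")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a matrix from GCT (by ``.gct`` extension) or TSV (first column = row ids)."""
    if str(path).endswith(".gct"):
        return read_gct(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    if str(path).endswith(".gct"):
        write_gct(df, path)
    else:
        df.to_csv(path, sep="\t")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV table (phenotype or survival); sample_id stays a column."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
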