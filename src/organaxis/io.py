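"""Tabular I/O helpers for the command-line interface.

Observation tables travel as tidy TSV (one row per spot/cell, coordinate
columns ``x_um``/``y_um``); feature matrices as dense TSV/CSV
(observations × features) or as a MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv`` + ``observations.tsv``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["read_table", "write_table", "read_matrix", "write_matrix_mtx"]


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Dense TSV/CSV, or a MatrixMarket file whose directory holds
    ``features.tsv`` and ``observations.tsv`` (one name per line)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        m = scipy.io.mmread(path)
        m = m.toarray() if scipy.sparse.issparse(m) else np.asarray(m)
        features = (path.parent / "features.tsv").read_text().split()
        obs = (path.parent / "observations.tsv").read_text().split()
        return pd.DataFrame(m, index=obs, columns=features)
    return read_table(path)


def write_matrix_mtx(df: pd.DataFrame, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", scipy.sparse.csr_matrix(df.to_numpy()))
    (directory / "features.tsv").write_text("\n".join(map(str, df.columns)) + "\n")
    (directory / "observations.tsv").write_text("\n".join(map(str, df.index)) + "\n")
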