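"""Readers and writers for the package's tabular interchange formats.

Per-cell tables travel as CSV with booleans encoded 0/1; count matrices as
MatrixMarket (.mtx) plus gene/cell name text files (dense CSV works for toy
matrices); gene lists as one symbol per line; run configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as sio
from scipy import sparse

BOOL_COLUMNS = ("gfp", "cycling", "brdu", "edu", "ki67", "mcm2", "pvim")


def write_population_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in BOOL_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return table


def write_counts_mtx(adata: AnnData, outdir) -> None:
    """Write counts as matrix.mtx (genes x cells) + genes.txt/cells.txt/meta.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csr_matrix(X) if not sparse.issparse(X) else X
    sio.mmwrite(str(outdir / "matrix.mtx"), mat.T.astype(int))
    (outdir / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    (outdir / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cell_metadata.csv")


def read_counts_mtx(indir) -> AnnData:
    indir = Path(indir)
    mat = sio.mmread(str(indir / "matrix.mtx")).tocsr().T
    genes = (indir / "genes.txt").read_text().splitlines()
    cells = (indir / "cells.txt").read_text().splitlines()
    adata = AnnData(
        X=np.asarray(mat.todense()),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )
    meta = indir / "cell_metadata.csv"
    if meta.exists():
        adata.obs = pd.read_csv(meta, index_col=0).loc[cells]
    return adata


def read_gene_list(path) -> list:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
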