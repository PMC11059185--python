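"""Readers and writers for the pipeline's plain-text interchange formats.

TSV for tabular inputs/outputs, Matrix-Market plus barcode/feature
sidecars for droplet matrices, GMT for gene-set collections, JSON for
reports.  Writes are atomic (temp file + rename) so an interrupted run
never leaves a truncated output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_tsv",
    "write_tsv",
    "write_json",
    "read_gmt",
    "write_gmt",
    "read_droplets",
    "write_droplets",
]


def _atomic(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    _atomic(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=index))


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    _atomic(
        Path(path),
        lambda tmp: tmp.write_text(json.dumps(obj, indent=2, default=default) + "\n"),
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    def writer(tmp: Path) -> None:
        with open(tmp, "w") as fh:
            for name, members in sets.items():
                fh.write("\t".join([name, "na", *members]) + "\n")

    _atomic(Path(path), writer)


def write_droplets(adata: ad.AnnData, directory: str | Path) -> None:
    """Write a droplet matrix as matrix.mtx + barcodes.tsv + features.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    def write_mtx(tmp: Path) -> None:
        with open(tmp, "wb") as fh:
            spio.mmwrite(fh, sparse.coo_matrix(X.T), field="integer")

    _atomic(directory / "matrix.mtx", write_mtx)
    _atomic(directory / "barcodes.tsv",
            lambda tmp: tmp.write_text("\n".join(adata.obs_names) + "\n"))
    _atomic(directory / "features.tsv",
            lambda tmp: tmp.write_text("\n".join(adata.var_names) + "\n"))


def read_droplets(directory: str | Path) -> ad.AnnData:
    """Read a matrix.mtx + barcodes.tsv + features.tsv droplet directory."""
    directory = Path(directory)
    X = spio.mmread(str(directory / "matrix.mtx")).T.tocsr()
    barcodes = (directory / "barcodes.tsv").read_text().split()
    features = (directory / "features.tsv").read_text().split()
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
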