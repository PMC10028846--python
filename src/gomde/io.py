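"""Readers, writers and preprocessing filters.

Count matrices are accepted as MatrixMarket coordinate files (with optional
row/column label files, one label per line) or dense TSV.  10x-style files
on disk are features x cells and are transposed on read so that the
in-memory orientation is always cells x features.  On-disk MatrixMarket
coordinates are 1-based per the standard; in-memory indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from . import __version__
from .gom_de import GoMDEResult
from .topic_model import CountMatrix, PoissonNMFFit, TopicModelFit

__all__ = [
    "read_counts",
    "write_counts",
    "binarize",
    "filter_nonvarying",
    "write_results",
    "write_fit",
    "structure_export",
    "write_provenance",
]


def _read_labels(path):
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(
    path,
    layout: str = "cells-by-features",
    cell_file=None,
    feature_file=None,
) -> CountMatrix:
    """Read a count matrix, oriented cells x features regardless of the
    on-disk layout.

    MatrixMarket input (.mtx) may come with label files; dense TSV input
    uses the header row for column names and treats a non-numeric first
    column as row identifiers.
    """
    if layout not in ("cells-by-features", "features-by-cells"):
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    row_labels = col_labels = None
    if path.suffix == ".mtx":
        X = sp.csr_matrix(sio.mmread(path))
        data = X.data
        if data.size and not np.allclose(data, np.round(data)):
            bad = np.argmax(~np.isclose(data, np.round(data)))
            coo = X.tocoo()
            raise ValueError(
                "non-integer entry at coordinate "
                f"({coo.row[bad] + 1}, {coo.col[bad] + 1})"
            )
    else:
        df = pd.read_csv(path, sep="\t", header=0)
        first = df.columns[0]
        if not pd.api.types.is_numeric_dtype(df[first]):
            row_labels = df[first].astype(str).tolist()
            df = df.drop(columns=[first])
        col_labels = [str(c) for c in df.columns]
        arr = df.to_numpy(dtype=float)
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(f"non-integer entry at coordinate ({i + 1}, {j + 1})")
        X = sp.csr_matrix(arr)
    if cell_file is not None:
        cells = _read_labels(cell_file)
    else:
        cells = None
    if feature_file is not None:
        features = _read_labels(feature_file)
    else:
        features = None

    if layout == "features-by-cells":
        X = sp.csr_matrix(X.T)
        row_labels, col_labels = col_labels, row_labels
    n, m = X.shape
    cells = cells if cells is not None else row_labels
    features = features if features is not None else col_labels
    if cells is not None and len(cells) != n:
        raise ValueError(f"{len(cells)} cell labels for {n} cells")
    if features is not None and len(features) != m:
        raise ValueError(f"{len(features)} feature labels for {m} features")
    cm = CountMatrix.from_array(X, cell_ids=cells, feature_ids=features)
    if np.any(cm.size_factors == 0):
        warnings.warn("some cells have zero total count (size factor 0)")
    return cm


def write_counts(X: CountMatrix, prefix) -> None:
    """Write <prefix>counts.mtx plus cells.tsv / features.tsv label files.

    ``prefix`` is a raw path prefix: pass "dir/" to write into a directory
    or "dir/run1_" to tag the file names.
    """
    prefix = str(prefix)
    parent = Path(prefix + "counts.mtx").parent
    parent.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(prefix + "counts.mtx", X.counts.tocoo(), field="integer")
    Path(prefix + "cells.tsv").write_text(
        "\n".join(map(str, X.cell_ids)) + "\n"
    )
    Path(prefix + "features.tsv").write_text(
        "\n".join(map(str, X.feature_ids)) + "\n"
    )


def binarize(X: CountMatrix) -> CountMatrix:
    """Map entries to 1{x > 0} (binarized accessibility); size factors are
    recomputed.  Idempotent."""
    B = X.counts.copy()
    B.data = (B.data > 0).astype(B.data.dtype)
    B.eliminate_zeros()
    return CountMatrix(sp.csr_matrix(B), list(X.cell_ids), list(X.feature_ids))


def filter_nonvarying(X: CountMatrix):
    """Drop features whose counts are identical across all cells.

    This removes all-zero columns and constant nonzero columns alike.
    Returns the filtered matrix and the removed feature ids.
    """
    C = sp.csc_matrix(X.counts)
    n, m = C.shape
    colmax = np.asarray(C.max(axis=0).todense()).ravel()
    colmin = np.asarray(C.min(axis=0).todense()).ravel()
    varying = colmax != colmin
    removed = [fid for fid, keep in zip(X.feature_ids, varying) if not keep]
    if not varying.any():
        raise ValueError("all features are non-varying; empty output")
    kept = CountMatrix(
        sp.csr_matrix(C[:, varying]),
        list(X.cell_ids),
        [fid for fid, keep in zip(X.feature_ids, varying) if keep],
    )
    return kept, removed


_RESULT_COLUMNS = [
    "feature_id",
    "topic",
    "postmean_lfc",
    "hpd_lower",
    "hpd_upper",
    "se",
    "shrunk_lfc",
    "shrunk_se",
    "zscore",
    "lfsr",
    "svalue",
    "p0",
    "f_map",
]


def result_frame(result: GoMDEResult) -> pd.DataFrame:
    """Tidy table, one row per gene x topic (HPD bounds are pre-shrinkage)."""
    m, K = result.postmean_lfc.shape
    rows = {
        "feature_id": np.repeat(result.feature_ids, K),
        "topic": np.tile([f"k{k + 1}" for k in range(K)], m),
        "postmean_lfc": result.postmean_lfc.ravel(),
        "hpd_lower": result.hpd_lower.ravel(),
        "hpd_upper": result.hpd_upper.ravel(),
        "se": result.se.ravel(),
        "shrunk_lfc": result.shrunk_lfc.ravel(),
        "shrunk_se": result.shrunk_se.ravel(),
        "zscore": result.zscore.ravel(),
        "lfsr": result.lfsr.ravel(),
        "svalue": result.svalue.ravel(),
        "p0": np.repeat(result.p0, K),
        "f_map": result.f_map.ravel(),
    }
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(result: GoMDEResult, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result_frame(result).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_fit(
    fit: TopicModelFit,
    prefix,
    cell_ids=None,
    feature_ids=None,
    nmf: PoissonNMFFit | None = None,
    seed=None,
) -> None:
    """Write fitted L and F as TSV plus a JSON sidecar with diagnostics.

    ``prefix`` is a raw path prefix (see :func:`write_counts`).
    """
    prefix = str(prefix)
    Path(prefix + "L.tsv").parent.mkdir(parents=True, exist_ok=True)
    K = fit.L.shape[1]
    topics = [f"k{k + 1}" for k in range(K)]
    Ldf = pd.DataFrame(fit.L, columns=topics)
    Fdf = pd.DataFrame(fit.F, columns=topics)
    if cell_ids is not None:
        Ldf.insert(0, "cell_id", cell_ids)
    if feature_ids is not None:
        Fdf.insert(0, "feature_id", feature_ids)
    Ldf.to_csv(prefix + "L.tsv", sep="\t", index=False, float_format="%.17g")
    Fdf.to_csv(prefix + "F.tsv", sep="\t", index=False, float_format="%.17g")
    sidecar = {"K": K, "seed": seed}
    if nmf is not None:
        sidecar.update(
            method=nmf.method, loglik_trace=list(map(float, nmf.loglik_trace))
        )
    Path(prefix + "fit.json").write_text(json.dumps(sidecar, indent=2))


def structure_export(L, labels, path, cell_ids=None) -> None:
    """Export per-cell topic proportions grouped by a label column, for
    external stacked-bar (Structure) plotting."""
    L = np.asarray(L, dtype=float)
    n, K = L.shape
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(
            f"got {len(labels)} labels for {n} cells; provide one label per cell"
        )
    if cell_ids is None:
        cell_ids = [f"cell{i + 1}" for i in range(n)]
    df = pd.DataFrame(L, columns=[f"k{k + 1}" for k in range(K)])
    df.insert(0, "label", labels)
    df.insert(0, "cell_id", cell_ids)
    df = df.sort_values("label", kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_provenance(path, config: dict) -> None:
    """JSON record (configuration, seeds, package version) beside outputs,
    sufficient to reproduce the run."""
    record = {"gomde_version": __version__, **config}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
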