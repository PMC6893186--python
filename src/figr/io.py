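"""Delimited-text file formats for circuits, trajectories and labels.

Everything is plain tab-separated text so files diff cleanly and survive
version control: circuits as one row per gene (T row, threshold, rates,
diffusion constant, upstream flag), trajectory data in tidy long form
(trajectory, time, gene, concentration), spatial data in wide form (one
row per nucleus and time class, genes as columns -- the layout of the
integrated blastoderm expression tables this package targets).  Floats are
written with 17 significant digits, so a write/read round trip is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from figr.model import ExpressionDataset, GeneCircuit, SpatialDataset
from figr.onoff import StateLabels

__all__ = [
    "TableLayout",
    "read_circuit",
    "write_circuit",
    "read_expression_table",
    "write_expression_table",
    "write_labels",
]

_FLOAT_FMT = "%.17g"


def write_circuit(circuit: GeneCircuit, path) -> None:
    """Write a circuit as one row per gene: T row, h, R, lam, D, upstream."""
    G = circuit.G
    cols = {}
    for f in range(G):
        cols[f"T_{circuit.genes[f]}"] = circuit.T[:, f]
    cols["h"] = circuit.h
    cols["R"] = circuit.R
    cols["lam"] = circuit.lam
    cols["D"] = circuit.D if circuit.D is not None else np.zeros(G)
    cols["upstream"] = [int(g in circuit.upstream) for g in range(G)]
    df = pd.DataFrame(cols, index=pd.Index(circuit.genes, name="gene"))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_circuit(path) -> GeneCircuit:
    df = pd.read_csv(path, sep="\t", index_col="gene", comment="#",
                     float_precision="round_trip")
    genes = tuple(df.index.astype(str))
    G = len(genes)
    tcols = [c for c in df.columns if c.startswith("T_")]
    if len(tcols) != G:
        raise ValueError(f"{path}: expected {G} T_* columns, found {len(tcols)}")
    T = df[[f"T_{g}" for g in genes]].to_numpy(dtype=float)
    D = df["D"].to_numpy(dtype=float)
    upstream = frozenset(int(i) for i in np.nonzero(df["upstream"].to_numpy())[0])
    return GeneCircuit(T=T, h=df["h"].to_numpy(dtype=float),
                       R=df["R"].to_numpy(dtype=float),
                       lam=df["lam"].to_numpy(dtype=float),
                       D=None if not D.any() else D,
                       upstream=upstream, genes=genes)


@dataclass(frozen=True)
class TableLayout:
    """Descriptor mapping a delimited table onto a dataset.

    ``kind="tidy"`` expects long-form rows (id, time, gene, value) and
    yields an ExpressionDataset; ``kind="wide"`` expects one row per
    (position-or-id, time) with one column per gene and yields a
    SpatialDataset when ``spatial`` is true.  Any column dialect can be
    mapped by renaming here, without code changes.
    """

    kind: str = "tidy"
    id_col: str = "trajectory"
    time_col: str = "time"
    gene_col: str = "gene"
    value_col: str = "concentration"
    spatial: bool = False
    genes: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("tidy", "wide"):
            raise ValueError("kind must be 'tidy' or 'wide'")


def _check_numeric(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric values in column {c!r} at rows "
                f"{list(bad[:5])}")
        if df[c].isna().any():
            raise ValueError(f"{path}: missing values in column {c!r} at rows "
                             f"{list(df.index[df[c].isna()][:5])}")


def read_expression_table(path, layout: TableLayout | None = None):
    """Read a delimited expression table into a dataset.

    Row order is irrelevant: observations are keyed by (id-or-position,
    time, gene).  Duplicated keys, missing columns and non-numeric cells
    raise with row-level diagnostics.
    """
    layout = layout or TableLayout()
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    if layout.kind == "tidy":
        need = [layout.id_col, layout.time_col, layout.gene_col, layout.value_col]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        _check_numeric(df, [layout.time_col, layout.value_col], path)
        dup = df.duplicated([layout.id_col, layout.time_col, layout.gene_col])
        if dup.any():
            raise ValueError(f"{path}: duplicated (id, time, gene) keys at rows "
                             f"{list(df.index[dup][:5])}")
        wide = df.pivot(index=[layout.id_col, layout.time_col],
                        columns=layout.gene_col, values=layout.value_col)
        if wide.isna().any().any():
            raise ValueError(f"{path}: gene set is inconsistent across rows")
        genes = (layout.genes if layout.genes is not None
                 else tuple(wide.columns.astype(str)))
        wide = wide[list(genes)]
        ids = sorted(wide.index.get_level_values(0).unique())
        times = np.sort(wide.index.get_level_values(1).unique().to_numpy(float))
        X = np.empty((len(ids), times.size, len(genes)))
        for i, tid in enumerate(ids):
            block = wide.xs(tid, level=0).sort_index()
            if block.shape[0] != times.size:
                raise ValueError(f"{path}: series {tid!r} does not cover every "
                                 "timepoint")
            X[i] = block.to_numpy(float)
        return ExpressionDataset(times=times, X=X,
                                 conditions=tuple(str(i) for i in ids),
                                 genes=genes)
    # wide layout: one row per (position/id, time), genes as columns
    key = layout.id_col
    need = [key, layout.time_col]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    gene_cols = (list(layout.genes) if layout.genes is not None
                 else [c for c in df.columns if c not in need])
    _check_numeric(df, [key, layout.time_col] + gene_cols, path)
    dup = df.duplicated([key, layout.time_col])
    if dup.any():
        raise ValueError(f"{path}: duplicated ({key}, time) keys at rows "
                         f"{list(df.index[dup][:5])}")
    df = df.sort_values([layout.time_col, key])
    positions = np.sort(df[key].unique().astype(float))
    times = np.sort(df[layout.time_col].unique().astype(float))
    X = np.empty((positions.size, times.size, len(gene_cols)))
    for j, t in enumerate(times):
        block = df[df[layout.time_col] == t].sort_values(key)
        if block.shape[0] != positions.size:
            raise ValueError(f"{path}: time {t} does not cover every position")
        X[:, j, :] = block[gene_cols].to_numpy(float)
    if layout.spatial:
        return SpatialDataset(positions=positions, times=times, X=X,
                              genes=tuple(gene_cols))
    return ExpressionDataset(
        times=times, X=X, genes=tuple(gene_cols),
        conditions=tuple(str(p) for p in positions))


def write_expression_table(data, path, layout: TableLayout | None = None) -> None:
    """Write a dataset in the tidy or wide dialect described by ``layout``."""
    if layout is None:
        layout = TableLayout(kind="wide", id_col="position", spatial=True) \
            if isinstance(data, SpatialDataset) else TableLayout()
    if layout.kind == "tidy":
        ids = (data.positions if isinstance(data, SpatialDataset)
               else data.conditions)
        rows = []
        for i, tid in enumerate(ids):
            for j, t in enumerate(data.times):
                for g, gene in enumerate(data.genes):
                    rows.append((tid, t, gene, data.X[i, j, g]))
        df = pd.DataFrame(rows, columns=[layout.id_col, layout.time_col,
                                         layout.gene_col, layout.value_col])
    else:
        ids = (data.positions if isinstance(data, SpatialDataset)
               else np.arange(data.X.shape[0], dtype=float))
        rows = []
        for j, t in enumerate(data.times):
            for i, pos in enumerate(ids):
                rows.append([pos, t, *data.X[i, j, :]])
        df = pd.DataFrame(rows, columns=[layout.id_col, layout.time_col,
                                         *data.genes])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_labels(data, labels: StateLabels, path) -> None:
    """Serialize ON/OFF calls next to their observations (tidy long form)."""
    ids = (data.positions if isinstance(data, SpatialDataset)
           else data.conditions)
    rows = []
    for i, tid in enumerate(ids):
        for j, t in enumerate(data.times):
            for g, gene in enumerate(data.genes):
                rows.append((tid, t, gene, data.X[i, j, g],
                             labels.v[i, j, g], labels.y[i, j, g]))
    df = pd.DataFrame(rows, columns=["series", "time", "gene", "x", "v", "y"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
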