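"""Reading and writing the delimited-text formats used by the CLI.

Expression matrices are genes-as-rows TSV/CSV with the gene identifier in
the first column and one column per time point; each file holds one
replicate series.  Edge lists are headerless two-column TSV (source, target)
with an optional third column carrying the entry lambda.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lagged import DirectedNetwork, ExpressionDataset, RegularizationPath
from .semisupervised import PriorNetwork


class UnknownGeneError(KeyError):
    """An edge list refers to genes absent from the expression dataset."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(
            "unknown gene name(s): " + ", ".join(self.names)
        )


def _sep(path):
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(paths, dt=1.0):
    """Load one or more series files into an ExpressionDataset.

    All files must list the same genes in the same order (first column).
    """
    if isinstance(paths, (str, bytes)) or not hasattr(paths, "__iter__"):
        paths = [paths]
    series = []
    gene_names = None
    for path in paths:
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
        names = tuple(str(g) for g in df.index)
        if gene_names is None:
            gene_names = names
        elif names != gene_names:
            raise ValueError(
                f"{path} lists different genes (or a different order) than "
                "the first series file"
            )
        series.append(df.to_numpy(dtype=float))
    return ExpressionDataset(gene_names=gene_names, series=tuple(series), dt=dt)


def write_expression(data, path, series_index=0):
    mat = data.series[series_index]
    df = pd.DataFrame(
        mat,
        index=pd.Index(data.gene_names, name="gene"),
        columns=[f"t{t}" for t in range(mat.shape[1])],
    )
    df.to_csv(path, sep=_sep(path))


def read_edge_list(path, gene_names):
    """Read a headerless source/target TSV into index pairs.

    Unknown gene names are a hard error listing the offenders.
    """
    df = pd.read_csv(
        path, sep=_sep(path), header=None, usecols=[0, 1],
        names=["source", "target"], dtype=str, comment="#",
    )
    index = {g: k for k, g in enumerate(gene_names)}
    unknown = {
        g
        for col in ("source", "target")
        for g in df[col]
        if g not in index
    }
    if unknown:
        raise UnknownGeneError(unknown)
    return frozenset(
        (index[s], index[t]) for s, t in zip(df["source"], df["target"])
    )


def read_network(path, gene_names):
    return DirectedNetwork(tuple(gene_names), read_edge_list(path, gene_names))


def read_prior(path, gene_names):
    return PriorNetwork(tuple(gene_names), read_edge_list(path, gene_names))


def write_edge_list(network, path):
    with open(path, "w") as fh:
        for src, tgt in network.named_edges():
            fh.write(f"{src}\t{tgt}\n")


def write_entry_path(path_obj, path, only_entered=False):
    """Write a regularization path as source/target/entry-lambda TSV
    (never-entering pairs get an empty third field unless dropped)."""
    names = path_obj.gene_names
    with open(path, "w") as fh:
        items = sorted(
            path_obj.entry_value.items(),
            key=lambda kv: (-(kv[1] if kv[1] is not None else -np.inf), kv[0]),
        )
        for (j, i), val in items:
            if val is None:
                if only_entered:
                    continue
                fh.write(f"{names[j]}\t{names[i]}\t\n")
            else:
                fh.write(f"{names[j]}\t{names[i]}\t{val:.8g}\n")


def read_entry_path(path, gene_names):
    """Inverse of :func:`write_entry_path` (grid is reconstructed from the
    distinct entry values; adequate for ROC scoring)."""
    df = pd.read_csv(
        path, sep=_sep(path), header=None,
        names=["source", "target", "entry"],
    )
    index = {g: k for k, g in enumerate(gene_names)}
    unknown = {
        g
        for col in ("source", "target")
        for g in df[col].astype(str)
        if g not in index
    }
    if unknown:
        raise UnknownGeneError(unknown)
    entry = {}
    for r in df.itertuples():
        val = None if pd.isna(r.entry) else float(r.entry)
        entry[(index[str(r.source)], index[str(r.target)])] = val
    vals = sorted({v for v in entry.values() if v is not None}, reverse=True)
    if len(vals) < 2:  # RegularizationPath needs a grid of length >= 2
        vals = vals + [min(vals, default=1.0) / 10.0]
        if len(vals) < 2:
            vals = [1.0, 0.1]
    return RegularizationPath(tuple(gene_names), np.asarray(vals), entry)
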