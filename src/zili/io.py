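"""Reading and writing the standard on-disk formats.

Abundance tables are delimited text (TSV by default; comma when the file
extension is ``.csv``) with a header row of taxon labels and a first column
of sample labels — the canonical orientation is samples × taxa, and a
taxa-in-rows table can be transposed on read with an explicit flag.
Networks go to two-column edge lists (isolated nodes listed in a header
comment) or GraphML via networkx.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, Network, StateMatrix
from .simulate import to_relative_abundance

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_network",
    "write_network",
    "write_states",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance(
    path, orientation: str = "samples", normalize: bool = False
) -> AbundanceMatrix:
    """Read a labeled abundance table.

    ``orientation='samples'`` expects samples in rows (canonical);
    ``orientation='taxa'`` transposes a taxa-in-rows table.  With
    ``normalize=True`` rows are total-sum-scaled to relative abundances;
    otherwise the matrix is returned as absolute values.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    seen: set[str] = set()
    for label in header:
        if label in seen:
            raise ValueError(f"duplicate column label {label!r} in {path}")
        seen.add(label)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "taxa":
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample label {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate taxon label {dup!r} in {path}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = map(int, next(zip(*np.nonzero(np.isnan(values)))))
        raise ValueError(
            f"missing value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = map(int, next(zip(*np.nonzero(values < 0))))
        raise ValueError(
            f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    matrix = AbundanceMatrix(
        values=values,
        mode="absolute",
        samples=[str(s) for s in df.index],
        taxa=[str(t) for t in df.columns],
    )
    if normalize:
        return to_relative_abundance(matrix)
    rowsum = values.sum(axis=1)
    if np.allclose(rowsum, 1.0, atol=1e-9):
        matrix.mode = "relative"
    return matrix


def write_abundance(X: AbundanceMatrix, path) -> None:
    X.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample")


def _to_networkx(net: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for a, b in net.edges():
        attrs = {}
        if net.directed_support is not None:
            i, j = net.nodes.index(a), net.nodes.index(b)
            attrs["support"] = (
                "both"
                if net.directed_support[i, j] and net.directed_support[j, i]
                else "one-directional"
            )
        g.add_edge(a, b, **attrs)
    return g


def write_network(net: Network, path, fmt: str = "edgelist") -> None:
    """Write a network as a two-column edge list or GraphML.

    Both formats preserve the full node set (including isolated nodes) and
    read back to an identical adjacency.
    """
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("# nodes:\t" + "\t".join(net.nodes) + "\n")
            for a, b in net.edges():
                fh.write(f"{a}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(_to_networkx(net), path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "edgelist") -> Network:
    path = Path(path)
    if fmt == "edgelist":
        nodes: list[str] = []
        edges: list[tuple[str, str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# nodes:"):
                    nodes = [x for x in line.split("\t")[1:] if x]
                elif line and not line.startswith("#"):
                    a, b = line.split("\t")
                    edges.append((a, b))
        if not nodes:
            nodes = sorted({x for e in edges for x in e})
        return Network.from_edges(nodes, edges)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes())
        return Network.from_edges(nodes, list(g.edges()))
    raise ValueError(f"unknown network format {fmt!r}")


def write_states(states: StateMatrix, path, summary_path=None, X=None) -> None:
    """Write the estimated state matrix (samples × taxa, integers) and,
    optionally, a per-taxon summary (K, class means, loss)."""
    states.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample")
    if summary_path is not None:
        from .states import partition_summary

        if X is None:
            raise ValueError("abundance matrix required for the state summary")
        rows = partition_summary(X, states)
        df = pd.DataFrame(
            [
                {
                    "taxon": r["taxon"],
                    "K": r["K"],
                    "class_means": ";".join(f"{m:.6g}" for m in r["class_means"]),
                    "loss": r["loss"],
                }
                for r in rows
            ]
        )
        df.to_csv(summary_path, sep="\t", index=False)
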