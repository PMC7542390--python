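"""Shared in-memory containers: latent-state matrices, abundance matrices, networks.

These are thin, validated wrappers around numpy arrays with taxon/sample
labels.  They are deliberately free of any model logic so that every module
(sampler, simulator, estimators, baselines, I/O) can depend on them without
circular imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _default_labels(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class StateMatrix:
    """n x p matrix of latent (or estimated) discrete states.

    ``values[i, j]`` is the state of taxon ``j`` in sample ``i`` and lies in
    ``{0, ..., levels[j] - 1}``.  Taxa with a single level are *degenerate*
    (constant) and are excluded from neighborhood regressions.
    """

    values: np.ndarray
    levels: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("state matrix must be two-dimensional")
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.shape != (self.values.shape[1],):
            raise ValueError("levels must have one entry per taxon")
        if not self.taxa:
            self.taxa = _default_labels("taxon", self.values.shape[1])
        if len(self.taxa) != self.values.shape[1]:
            raise ValueError("taxon labels do not match matrix width")
        if np.any(self.levels < 1):
            raise ValueError("every taxon needs at least one level")
        if np.any(self.values < 0) or np.any(self.values >= self.levels):
            raise ValueError("state values outside [0, K_j - 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of taxa with a single state level."""
        return self.levels == 1

    def to_dataframe(self) -> pd.DataFrame:
        idx = _default_labels("sample", self.n_samples)
        return pd.DataFrame(self.values, index=idx, columns=self.taxa)


@dataclass
class AbundanceMatrix:
    """n x p nonnegative abundance matrix, absolute counts or proportions.

    In ``relative`` mode every row sums to one (total sum scaling).
    """

    values: np.ndarray
    mode: str = "absolute"
    samples: list[str] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance matrix must be two-dimensional")
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        n, p = self.values.shape
        if not self.samples:
            self.samples = _default_labels("sample", n)
        if not self.taxa:
            self.taxa = _default_labels("taxon", p)
        if len(self.samples) != n or len(self.taxa) != p:
            raise ValueError("labels do not match matrix shape")
        if self.mode == "relative":
            rowsum = self.values.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                bad = int(np.argmax(np.abs(rowsum - 1.0)))
                raise ValueError(
                    f"relative abundance rows must sum to 1; sample "
                    f"{self.samples[bad]!r} sums to {rowsum[bad]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.taxa)


@dataclass
class Network:
    """Undirected taxon interaction network (symmetric boolean adjacency).

    ``directed_support[j, t]`` optionally records, for estimators built from
    per-node regressions, whether the regression of taxon ``j`` selected
    taxon ``t`` — the raw material for the OR/AND edge rules.
    """

    nodes: list[str]
    adjacency: np.ndarray
    directed_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        p = len(self.nodes)
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency shape must match node count")
        if np.any(self.adjacency != self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        if self.directed_support is not None:
            self.directed_support = np.asarray(self.directed_support, dtype=bool)
            if self.directed_support.shape != (p, p):
                raise ValueError("directed_support shape must match node count")

    @classmethod
    def from_edges(cls, nodes: list[str], edges) -> "Network":
        index = {name: i for i, name in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for a, b in edges:
            i, j = index[a], index[b]
            if i == j:
                raise ValueError(f"self-loop on node {a!r}")
            adj[i, j] = adj[j, i] = True
        return cls(nodes=list(nodes), adjacency=adj)

    @classmethod
    def cycle(cls, nodes: list[str]) -> "Network":
        """The p-cycle 1-2-...-p-1 (ground truth of the chain simulator)."""
        p = len(nodes)
        adj = np.zeros((p, p), dtype=bool)
        for j in range(p):
            adj[j, (j - 1) % p] = adj[(j - 1) % p, j] = True
        return cls(nodes=list(nodes), adjacency=adj)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj)]

    def has_edge(self, a: str, b: str) -> bool:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return bool(self.adjacency[i, j])

    def subnetwork(self, nodes: list[str]) -> "Network":
        """Induced subgraph on a subset of nodes (order preserved)."""
        idx = [self.nodes.index(a) for a in nodes]
        sub = self.adjacency[np.ix_(idx, idx)]
        supp = None
        if self.directed_support is not None:
            supp = self.directed_support[np.ix_(idx, idx)]
        return Network(nodes=list(nodes), adjacency=sub, directed_support=supp)
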