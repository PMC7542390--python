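"""Step 1 — latent state estimation by optimal univariate partitioning.

Each taxon's abundances are sorted and split into K contiguous classes
minimizing the within-class sum of squares (Fisher's exact dynamic program,
O(K n^2) with O(1) interval costs from prefix sums).  Class index − 1 is the
estimated latent state, so the empirical class means automatically satisfy
the increasing-mean identifiability ordering.  The class number K is chosen
per taxon by an elbow rule on the loss decrements, with a separate
zero/nonzero rule for very sparse taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import AbundanceMatrix, StateMatrix

__all__ = [
    "PartitionResult",
    "optimal_partition",
    "select_num_states",
    "estimate_states",
]


@dataclass
class PartitionResult:
    """Optimal contiguous K-partition of a sorted sample.

    ``boundaries`` holds the 0-based start indices of classes 2..K in the
    sorted order, i.e. class k (1-based) is ``sorted_x[b[k-1]:b[k]]`` with
    the conventions b[0] = 0 and b[K] = n.  ``sort_index`` (when the input
    came unsorted through ``estimate_states``) maps sorted positions back to
    original sample positions.
    """

    K: int
    boundaries: np.ndarray
    class_means: np.ndarray
    loss: float
    sort_index: np.ndarray | None = None

    def labels_sorted(self, n: int) -> np.ndarray:
        """State labels (class index − 1) in sorted order."""
        labels = np.zeros(n, dtype=np.int64)
        edges = np.concatenate([[0], self.boundaries, [n]])
        for k in range(self.K):
            labels[edges[k] : edges[k + 1]] = k
        return labels


def _interval_cost_matrix(x: np.ndarray) -> np.ndarray:
    """D[i, j] = within-class sum of squares of x[i..j] (inclusive), i <= j."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        D = (ss[j + 1] - ss[i]) - (s[j + 1] - s[i]) ** 2 / cnt
    D[cnt < 1] = np.inf
    # guard against tiny negative round-off
    np.maximum(D, 0.0, out=D, where=np.isfinite(D))
    return D


def _dp_tables(x: np.ndarray, K_max: int):
    """Loss table L[k, j] = optimal loss of splitting x[0..j] into k classes,
    and split table B[k, j] = start index of the k-th (last) class.

    Ties in the minimizing split are broken toward the smaller start index,
    so equal values never straddle a boundary unless strictly beneficial.
    """
    n = len(x)
    D = _interval_cost_matrix(x)
    L = np.full((K_max + 1, n), np.inf)
    B = np.zeros((K_max + 1, n), dtype=np.int64)
    L[1] = D[0]
    for k in range(2, K_max + 1):
        # candidate start i of the last class: L[k-1, i-1] + D[i, j], i >= k-1
        prev = L[k - 1, : n - 1]  # L[k-1, i-1] for i = 1..n-1
        cand = prev[:, None] + D[1:, :]  # rows i = 1..n-1
        cand[: k - 2, :] = np.inf  # need at least k-1 points before i
        best = np.argmin(cand, axis=0)  # first minimizer → smallest i
        L[k] = cand[best, np.arange(n)]
        B[k] = best + 1
        L[k, : k - 1] = np.inf
    return L, B


def _backtrack(B: np.ndarray, K: int, n: int) -> np.ndarray:
    bounds = np.zeros(K - 1, dtype=np.int64)
    j = n - 1
    for k in range(K, 1, -1):
        i = B[k, j]
        bounds[k - 2] = i
        j = i - 1
    return bounds


def optimal_partition(x: np.ndarray, K: int) -> PartitionResult:
    """Globally optimal K-class contiguous partition of a sorted vector.

    Minimizes the total within-class sum of squared deviations from class
    means over all contiguous partitions, by dynamic programming.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not (1 <= K <= n):
        raise ValueError(f"K must lie in [1, n]; got K={K}, n={n}")
    if np.any(np.diff(x) < 0):
        raise ValueError("input vector must be sorted nondecreasing")
    L, B = _dp_tables(x, K)
    bounds = _backtrack(B, K, n) if K > 1 else np.zeros(0, dtype=np.int64)
    edges = np.concatenate([[0], bounds, [n]])
    means = np.array([x[edges[k] : edges[k + 1]].mean() for k in range(K)])
    return PartitionResult(
        K=K, boundaries=bounds, class_means=means, loss=float(L[K, n - 1])
    )


def select_num_states(
    x: np.ndarray, K_max: int = 6, convention: str = "elbow"
) -> int:
    """Pick the class number by the loss-decrement rule.

    The optimal loss L(K) is computed for K = 2..K_max; decrements
    d_K = L(K) − L(K+1) ≥ 0 (the gain from allowing one more class) are
    formed for K = 2..K_max−1, and the smallest K whose gain falls to or
    below the mean gain is selected — the elbow of the loss curve.  The
    ``literal`` convention instead uses the signed differences
    d_K = L(K+1) − L(K) with the same first-K-below-mean scan (kept for
    reference; it degenerates to always selecting K = 2).

    Returns 1 for a constant vector (degenerate taxon).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if K_max < 3:
        raise ValueError("K_max must be >= 3 (need at least two decrements)")
    if n < K_max:
        warnings.warn(
            f"n={n} < K_max={K_max}; reducing the class-number upper bound to n"
        )
        K_max = n
        if K_max < 3:
            return 1 if x[0] == x[-1] else min(2, n)
    if x[0] == x[-1]:
        return 1
    L, _ = _dp_tables(x, K_max)
    losses = L[2 : K_max + 1, n - 1]  # L(2), ..., L(K_max)
    if convention == "elbow":
        d = losses[:-1] - losses[1:]  # d_K = L(K) - L(K+1) >= 0
    elif convention == "literal":
        d = losses[1:] - losses[:-1]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    dbar = d.mean()
    for idx, dk in enumerate(d):
        if dk <= dbar:
            return idx + 2
    return K_max - 1


def estimate_states(
    X: AbundanceMatrix,
    K_max: int = 6,
    rare_threshold: float = 0.01,
    K_fixed: int | None = None,
    convention: str = "elbow",
) -> StateMatrix:
    """Estimate the latent state matrix from relative abundances.

    Per taxon:

    - nonzero fraction below ``rare_threshold`` → two classes split at
      zero/nonzero (state = 1 iff the abundance is positive);
    - constant column → degenerate, K_j = 1 (excluded downstream);
    - otherwise, K_j from ``select_num_states`` (or ``K_fixed``) and states
      from the optimal partition, mapped back to the original sample order
      through the stable sorting permutation.

    States are invariant under strictly increasing transforms of a column,
    and the zeros of a zero-inflated column land in the lowest class.
    """
    if X.mode != "relative":
        raise ValueError("state estimation expects relative abundances")
    n, p = X.values.shape
    states = np.zeros((n, p), dtype=np.int64)
    levels = np.ones(p, dtype=np.int64)
    for j in range(p):
        col = X.values[:, j]
        if col.max() == col.min():
            continue  # degenerate, K_j = 1
        nonzero_frac = np.count_nonzero(col) / n
        if nonzero_frac < rare_threshold:
            states[:, j] = (col > 0).astype(np.int64)
            levels[j] = 2
            continue
        order = np.argsort(col, kind="stable")
        xs = col[order]
        if K_fixed is not None:
            K = min(K_fixed, n)
        else:
            K = select_num_states(xs, K_max=K_max, convention=convention)
        if K <= 1:
            continue
        part = optimal_partition(xs, K)
        states[order, j] = part.labels_sorted(n)
        levels[j] = K
    return StateMatrix(values=states, levels=levels, taxa=list(X.taxa))


def partition_summary(X: AbundanceMatrix, states: StateMatrix):
    """Per-taxon summary (K_j, class means, within-class loss) as records."""
    rows = []
    for j, taxon in enumerate(states.taxa):
        col = X.values[:, j]
        z = states.values[:, j]
        K = int(states.levels[j])
        means = [float(col[z == k].mean()) if np.any(z == k) else float("nan")
                 for k in range(K)]
        loss = float(
            sum(((col[z == k] - means[k]) ** 2).sum() for k in range(K) if np.any(z == k))
        )
        rows.append({"taxon": taxon, "K": K, "class_means": means, "loss": loss})
    return rows
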