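"""Step 2 — neighborhood selection via group-penalized multinomial logistic
regression.

For each taxon j, its estimated states are regressed on indicator encodings
of every other taxon's states under the baseline-category logit model

    log P(Z_j = l | rest) / P(Z_j = 0 | rest)
        = θ_{j;l} + Σ_{t≠j} Σ_h θ_{jt;lh} I[Z_t = h],

with the group penalty λ Σ_t √m_jt ‖θ_jt‖₂, m_jt = (K_j−1)(K_t−1), which
shrinks whole per-taxon coefficient blocks to zero.  The path is solved by
block coordinate descent with quadratic majorization and an active-set
strategy; λ is tuned by the extended BIC; the network is assembled from the
p neighborhoods by the OR (default) or AND rule.  Only the selected support
matters — coefficient magnitudes play no role in edge calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .containers import AbundanceMatrix, Network, StateMatrix
from .states import estimate_states

__all__ = [
    "FitConfig",
    "PathPoint",
    "NeighborhoodFit",
    "build_design",
    "fit_group_logistic_path",
    "neighborhood_select",
    "fit_zili",
]


@dataclass
class FitConfig:
    """Tuning knobs shared by the latent-Ising, dichotomous-Ising and
    Gaussian neighborhood estimators.

    ``ebic_gamma`` is the extended-BIC weight γ ∈ [0, 1] on the model-space
    term (γ = 0 recovers the ordinary BIC); ``n_lambda`` values are
    log-spaced from λ_max (smallest λ with an empty model) down to
    ``lambda_min_ratio``·λ_max.  ``df_max`` truncates the path once a fit
    exceeds that many nonzero coefficients (default: the sample size n);
    such saturated models are far beyond any EBIC optimum, and truncating
    them keeps path cost bounded.
    """

    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    lambda_path: np.ndarray | None = None
    ebic_gamma: float = 0.5
    max_iter: int = 1000
    tol: float = 1e-5
    df_max: int | None = None
    edge_rule: str = "or"
    rare_threshold: float = 0.01
    K_max: int = 6
    K_fixed: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.edge_rule not in ("or", "and"):
            raise ValueError("edge_rule must be 'or' or 'and'")
        if not (0 <= self.ebic_gamma <= 1):
            raise ValueError("ebic_gamma must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lambda_path is not None:
            lam = np.asarray(self.lambda_path, dtype=float)
            if np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
                raise ValueError("lambda_path must be strictly decreasing and positive")
            self.lambda_path = lam

    def to_json(self, path) -> None:
        raw = asdict(self)
        if raw["lambda_path"] is not None:
            raw["lambda_path"] = list(map(float, raw["lambda_path"]))
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("lambda_path") is not None:
            raw["lambda_path"] = np.asarray(raw["lambda_path"], dtype=float)
        return cls(**raw)


@dataclass
class PathPoint:
    """One λ on the regularization path of a single neighborhood fit."""

    lam: float
    intercepts: np.ndarray
    blocks: list[np.ndarray]  # per group, shape (group cols, K_j - 1)
    loglik: float
    df: int
    ebic: float
    converged: bool


@dataclass
class NeighborhoodFit:
    """Result of one taxon's penalized regression: the full path plus the
    EBIC-optimal point and the selected neighbor taxa."""

    taxon: int
    group_taxa: list[int]
    path: list[PathPoint]
    best_index: int
    response_levels: np.ndarray  # observed response levels, in order

    @property
    def best(self) -> PathPoint:
        return self.path[self.best_index]

    @property
    def selected(self) -> list[int]:
        point = self.best
        return [
            t
            for t, block in zip(self.group_taxa, point.blocks)
            if np.any(block != 0.0)
        ]


def build_design(states: StateMatrix, j: int):
    """Design matrix for taxon j's neighborhood regression.

    Returns ``(response, predictors, group_taxa, group_slices)`` where the
    predictor column for (t, h) is the indicator I[Z_t = h] (h = 1..K_t−1),
    columns are grouped by taxon t, and degenerate taxa (a single level)
    are omitted entirely.
    """
    if not (0 <= j < states.n_taxa):
        raise ValueError(f"taxon index {j} out of range")
    if states.levels[j] < 2:
        raise ValueError(f"taxon {states.taxa[j]!r} is degenerate (single level)")
    n = states.n_samples
    cols: list[np.ndarray] = []
    group_taxa: list[int] = []
    group_slices: list[slice] = []
    start = 0
    for t in range(states.n_taxa):
        if t == j or states.levels[t] < 2:
            continue
        Kt = int(states.levels[t])
        block = np.zeros((n, Kt - 1))
        for h in range(1, Kt):
            block[:, h - 1] = states.values[:, t] == h
        cols.append(block)
        group_taxa.append(t)
        group_slices.append(slice(start, start + Kt - 1))
        start += Kt - 1
    predictors = np.hstack(cols) if cols else np.zeros((n, 0))
    return states.values[:, j].copy(), predictors, group_taxa, group_slices


def _encode_response(y: np.ndarray):
    """Reindex observed response levels to 0..R; returns (codes, levels)."""
    levels = np.unique(y)
    codes = np.searchsorted(levels, y)
    return codes, levels


def _softmax_probs(eta: np.ndarray) -> np.ndarray:
    """P(level l | eta) for the nonreference levels, eta of shape (n, R)."""
    m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    num = np.exp(eta - m)
    denom = np.exp(-m) + num.sum(axis=1, keepdims=True)
    return num / denom


def _loglik(eta: np.ndarray, codes: np.ndarray) -> float:
    m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    lse = (m + np.log(np.exp(-m) + np.exp(eta - m).sum(axis=1, keepdims=True))).ravel()
    picked = np.where(codes > 0, eta[np.arange(len(codes)), codes - 1], 0.0)
    return float(picked.sum() - lse.sum())


try:  # pragma: no cover - trivial import guard
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _inner_bcd(X, Rres, B, b, starts, ends, active, cg, thr, tol, max_sweeps):
    """Group coordinate descent on the quadratic surrogate (in place).

    Minimizes (a/2)‖Rres‖² + Σ_g λw_g‖B_g‖ in the working-residual
    parameterization: ``Rres`` is the residual of the working response,
    ``thr[g]`` = λ w_g / a.  Returns the largest coefficient change of the
    last completed sweep.
    """
    n, R = Rres.shape
    delta = 0.0
    for _sweep in range(max_sweeps):
        delta = 0.0
        for l in range(R):
            m = 0.0
            for i in range(n):
                m += Rres[i, l]
            m /= n
            if m != 0.0:
                b[l] += m
                for i in range(n):
                    Rres[i, l] -= m
                if abs(m) > delta:
                    delta = abs(m)
        for gi in range(active.shape[0]):
            g = active[gi]
            s0 = starts[g]
            s1 = ends[g]
            dg = s1 - s0
            V = np.empty((dg, R))
            norm2 = 0.0
            for c in range(dg):
                for l in range(R):
                    acc = 0.0
                    for i in range(n):
                        acc += X[i, s0 + c] * Rres[i, l]
                    v = B[s0 + c, l] + acc / cg[g]
                    V[c, l] = v
                    norm2 += v * v
            norm = np.sqrt(norm2)
            t = thr[g] / cg[g]
            scale = 0.0 if norm <= t else 1.0 - t / norm
            for c in range(dg):
                for l in range(R):
                    newv = scale * V[c, l]
                    d = newv - B[s0 + c, l]
                    if d != 0.0:
                        B[s0 + c, l] = newv
                        for i in range(n):
                            Rres[i, l] -= X[i, s0 + c] * d
                        if abs(d) > delta:
                            delta = abs(d)
        if delta < tol:
            break
    return delta


def _penalized_objective(eta, codes, blocks, lam, weights) -> float:
    nll = -_loglik(eta, codes)
    pen = lam * sum(
        w * np.linalg.norm(blk) for w, blk in zip(weights, blocks)
    )
    return float(nll + pen)


def fit_group_logistic_path(
    response: np.ndarray,
    predictors: np.ndarray,
    group_slices: list[slice],
    config: FitConfig | None = None,
    group_weights: np.ndarray | None = None,
    track_objective: bool = False,
):
    """Solve the group-penalized multinomial pseudo-likelihood path.

    Minimizes  −ℓ(θ) + λ Σ_g w_g ‖θ_g‖₂  over a descending λ path with warm
    starts, where ℓ is the baseline-category multinomial log-likelihood,
    intercepts are unpenalized, and w_g = √m_g with m_g the number of
    coefficients in group g (columns × nonreference response levels).

    The optimizer is majorize–minimize: each outer step replaces the
    multinomial loss by its global quadratic upper bound with curvature
    ½ I per sample (Böhning's bound), and the resulting penalized least
    squares problem is solved by group coordinate descent with exact
    groupwise proximal steps.  A zero block stays zero iff its loss-gradient
    norm is at most λ w_g; inactive groups enter through a
    Karush–Kuhn–Tucker violation scan, so per-λ cost scales with the active
    set.  Warm starts carry coefficients down the path; λ_max (the smallest
    λ with an empty model) is computed from the null-model gradient.

    Returns a list of :class:`PathPoint` in descending-λ order.  With
    ``track_objective`` each point also carries the penalized objective
    after every outer step (monotone nonincreasing, a solver sanity probe).
    """
    config = config or FitConfig()
    y = np.asarray(response)
    codes, levels = _encode_response(y)
    R = len(levels) - 1
    if R < 1:
        raise ValueError("response must have at least two observed levels")
    X = np.ascontiguousarray(np.asarray(predictors, dtype=float))
    n = X.shape[0]
    G = len(group_slices)
    sizes = np.array([sl.stop - sl.start for sl in group_slices], dtype=np.int64)
    starts = np.array([sl.start for sl in group_slices], dtype=np.int64)
    ends = np.array([sl.stop for sl in group_slices], dtype=np.int64)
    if group_weights is None:
        group_weights = np.sqrt(sizes * R).astype(float)
    group_weights = np.asarray(group_weights, dtype=float)

    Y = np.zeros((n, R))
    Y[np.arange(n)[codes > 0], codes[codes > 0] - 1] = 1.0
    a = 0.5  # per-sample curvature bound of the multinomial loss
    # exact largest eigenvalue of each small within-group Gram matrix
    cg = np.array(
        [
            max(float(np.linalg.eigvalsh(X[:, sl].T @ X[:, sl]).max()), 1e-12)
            for sl in group_slices
        ]
    )

    # null model: intercept-only MLE in closed form
    freq = np.bincount(codes, minlength=R + 1) / n
    with np.errstate(divide="ignore"):
        b = np.log(freq[1:] / freq[0]).astype(float)
    B = np.zeros((X.shape[1], R))
    eta = np.tile(b, (n, 1))
    P = _softmax_probs(eta)
    grad0 = X.T @ (P - Y)
    gnorms0 = np.array(
        [np.linalg.norm(grad0[sl]) for sl in group_slices]
    )
    lam_max = float(np.max(gnorms0 / group_weights)) if G else 1.0
    if config.lambda_path is not None:
        lam_path = config.lambda_path
    else:
        lam_path = np.geomspace(
            lam_max, max(lam_max * config.lambda_min_ratio, 1e-12), config.n_lambda
        )

    q_total = int((sizes * R).sum())
    # A point with df·(log n + 2γ·log q) above the null model's EBIC can
    # never minimize EBIC (−2ℓ ≥ 0), so the path can stop there; this keeps
    # the saturated small-λ tail from dominating runtime.
    ll_null = _loglik(np.tile(b, (n, 1)), codes)
    penalty_rate = np.log(n) + (
        2.0 * config.ebic_gamma * np.log(q_total) if q_total > 0 else 0.0
    )
    ebic_bound = int(np.ceil(-2.0 * ll_null / penalty_rate)) + 1
    df_max = config.df_max if config.df_max is not None else min(n, ebic_bound)
    path: list[PathPoint] = []
    active = np.zeros(G, dtype=bool)
    any_nonconverged = False
    truncated = False

    for lam in lam_path:
        thr = lam * group_weights / a
        converged = False
        trace: list[float] = []
        for _outer in range(config.max_iter):
            P = _softmax_probs(eta)
            Gr = P - Y
            if track_objective:
                blocks_now = [B[sl] for sl in group_slices]
                trace.append(
                    _penalized_objective(eta, codes, blocks_now, lam, group_weights)
                )
            # KKT scan: inactive groups whose loss gradient exceeds the
            # penalty threshold must enter the active set
            full_grad = X.T @ Gr
            had_violation = False
            for g in range(G):
                if not active[g] and (
                    np.linalg.norm(full_grad[starts[g] : ends[g]])
                    > lam * group_weights[g] * (1.0 + 1e-9)
                ):
                    active[g] = True
                    had_violation = True
            Rres = -Gr / a
            act_idx = np.nonzero(active)[0].astype(np.int64)
            B_before = B.copy()
            b_before = b.copy()
            _inner_bcd(
                X, Rres, B, b, starts, ends, act_idx, cg, thr,
                config.tol, min(config.max_iter, 100),
            )
            eta = b + X @ B
            # prune groups shrunk exactly to zero
            for g in act_idx:
                if not np.any(B[starts[g] : ends[g]] != 0.0):
                    active[g] = False
            outer_delta = max(
                float(np.abs(B - B_before).max()),
                float(np.abs(b - b_before).max()),
            )
            if np.count_nonzero(B) > df_max:
                truncated = True
                break
            if not had_violation and outer_delta < config.tol:
                converged = True
                break
        if truncated:
            break
        if not converged:
            any_nonconverged = True
        ll = _loglik(eta, codes)
        df = int(np.count_nonzero(B))
        ebic = -2.0 * ll + df * np.log(n)
        if q_total > 0:
            ebic += 2.0 * config.ebic_gamma * df * np.log(q_total)
        point = PathPoint(
            lam=float(lam),
            intercepts=b.copy(),
            blocks=[B[sl].copy() for sl in group_slices],
            loglik=ll,
            df=df,
            ebic=float(ebic),
            converged=converged,
        )
        if track_objective:
            point.objective_trace = trace  # type: ignore[attr-defined]
        path.append(point)
    if any_nonconverged:
        bad = [f"{pt.lam:.3g}" for pt in path if not pt.converged]
        warnings.warn(
            "group coordinate descent hit the iteration cap at "
            f"{len(bad)} of {len(path)} path points (λ: {', '.join(bad[:5])}...)"
        )
    return path


def kkt_residuals(
    response: np.ndarray,
    predictors: np.ndarray,
    group_slices: list[slice],
    point: PathPoint,
    group_weights: np.ndarray | None = None,
):
    """Karush–Kuhn–Tucker residuals of a path point.

    Returns ``(zero_excess, active_residual, intercept_grad)``: the largest
    amount by which a zero group's gradient norm exceeds λw_g, the largest
    stationarity violation ‖∇_g + λ w_g θ_g/‖θ_g‖‖ over active groups, and
    the max-norm of the intercept gradient.  All should be ≤ solver
    tolerance at an exact solution.
    """
    y = np.asarray(response)
    codes, _ = _encode_response(y)
    X = np.asarray(predictors, dtype=float)
    n = X.shape[0]
    R = point.intercepts.shape[0]
    sizes = np.array([sl.stop - sl.start for sl in group_slices])
    if group_weights is None:
        group_weights = np.sqrt(sizes * R).astype(float)
    Y = np.zeros((n, R))
    Y[np.arange(n)[codes > 0], codes[codes > 0] - 1] = 1.0
    eta = np.tile(point.intercepts, (n, 1))
    for sl, blk in zip(group_slices, point.blocks):
        eta += X[:, sl] @ blk
    P = _softmax_probs(eta)
    Gr = P - Y
    zero_excess = 0.0
    active_resid = 0.0
    for g, (sl, blk) in enumerate(zip(group_slices, point.blocks)):
        grad = X[:, sl].T @ Gr
        if np.any(blk != 0.0):
            norm = np.linalg.norm(blk)
            resid = grad + point.lam * group_weights[g] * blk / norm
            active_resid = max(active_resid, float(np.abs(resid).max()))
        else:
            excess = np.linalg.norm(grad) - point.lam * group_weights[g]
            zero_excess = max(zero_excess, float(excess))
    return zero_excess, active_resid, float(np.abs(Gr.sum(axis=0)).max())


def neighborhood_select(states: StateMatrix, config: FitConfig | None = None):
    """Fit all p neighborhood regressions and assemble the network.

    Each non-degenerate taxon is regressed on the others; λ is chosen per
    regression by minimum EBIC; the adjacency is the OR (default) or AND
    combination of the two directed selections.  Degenerate taxa are kept
    as isolated nodes.

    Returns ``(network, fits)`` with ``fits`` a dict taxon-index → fit.
    """
    config = config or FitConfig()
    p = states.n_taxa
    if int((states.levels >= 2).sum()) < 2:
        raise ValueError("need at least two non-degenerate taxa")
    directed = np.zeros((p, p), dtype=bool)
    fits: dict[int, NeighborhoodFit] = {}
    for j in range(p):
        if states.levels[j] < 2:
            continue
        y, Xd, group_taxa, group_slices = build_design(states, j)
        codes, levels = _encode_response(y)
        if len(levels) < 2:
            continue
        path = fit_group_logistic_path(y, Xd, group_slices, config)
        best = int(np.argmin([pt.ebic for pt in path]))
        fit = NeighborhoodFit(
            taxon=j,
            group_taxa=group_taxa,
            path=path,
            best_index=best,
            response_levels=levels,
        )
        fits[j] = fit
        for t in fit.selected:
            directed[j, t] = True
    if config.edge_rule == "or":
        adjacency = directed | directed.T
    else:
        adjacency = directed & directed.T
    np.fill_diagonal(adjacency, False)
    net = Network(
        nodes=list(states.taxa), adjacency=adjacency, directed_support=directed
    )
    return net, fits


def coefficients_table(fits: dict, states: StateMatrix):
    """Estimated coefficients at each taxon's EBIC-optimal λ as a flat
    (j, t, l, h, value) table (1-based indices; t/h empty for intercepts),
    the same layout :class:`~zili.potts.PottsParameters` serializes to.
    Only nonzero groups are written."""
    import pandas as pd

    rows = []
    for j, fit in sorted(fits.items()):
        point = fit.best
        for l, value in enumerate(point.intercepts, start=1):
            rows.append((j + 1, pd.NA, l, pd.NA, float(value)))
        for t, block in zip(fit.group_taxa, point.blocks):
            if not np.any(block != 0.0):
                continue
            # block rows index predictor levels h, columns response levels l
            for h in range(block.shape[0]):
                for l in range(block.shape[1]):
                    rows.append((j + 1, t + 1, l + 1, h + 1, float(block[h, l])))
    return pd.DataFrame(rows, columns=["j", "t", "l", "h", "value"])


@dataclass
class ZiliFit:
    """End-to-end two-step fit: estimated states, network, diagnostics."""

    network: Network
    states: StateMatrix
    fits: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def fit_zili(X: AbundanceMatrix, config: FitConfig | None = None) -> ZiliFit:
    """The full two-step algorithm on a relative abundance matrix.

    Step 1 categorizes each taxon's abundances into latent states (optimal
    partitioning with data-driven K, or zero/nonzero for very sparse taxa);
    Step 2 runs the penalized neighborhood regressions and assembles the
    interaction network.
    """
    config = config or FitConfig()
    states = estimate_states(
        X,
        K_max=config.K_max,
        rare_threshold=config.rare_threshold,
        K_fixed=config.K_fixed,
    )
    network, fits = neighborhood_select(states, config)
    diagnostics = {
        "levels": states.levels.copy(),
        "degenerate_taxa": [states.taxa[j] for j in np.nonzero(states.degenerate)[0]],
        "nonconverged": [
            states.taxa[j]
            for j, fit in fits.items()
            if not fit.best.converged
        ],
    }
    return ZiliFit(network=network, states=states, fits=fits, diagnostics=diagnostics)
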