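"""Multiclass Ising (Potts) Markov random field over latent abundance states.

Each of ``p`` taxa carries a discrete state variable Z_j taking values in
{0, ..., K-1}; state 0 is the reference level.  The joint distribution is

    P(z) ∝ exp{ Σ_j φ_j(z_j) + Σ_{(j,t)} φ_jt(z_j, z_t) },

where the node potential φ_j(l) = θ_{j;l} for l ≥ 1 (zero at the reference
level) and, for every *stored ordered pair* (j, t), the pair potential
φ_jt(l, h) = θ_{jt;lh} for l, h ≥ 1.  Each stored pair contributes one term
to the joint; the full conditional of Z_j therefore picks up both the groups
θ_jt stored as (j, t) and those stored as (t, j).  The normalizing constant
is never computed — only conditionals, the unnormalized log-density, and a
Gibbs sampler are exposed, which is all neighborhood selection needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import StateMatrix

__all__ = [
    "PottsParameters",
    "conditional_state_probs",
    "log_unnormalized_density",
    "gibbs_sample",
]


@dataclass
class PottsParameters:
    """Parameters of the multiclass Ising model with a reference level.

    Parameters
    ----------
    p : int
        Number of taxa.
    K : int
        Number of states per taxon (uniform, >= 2).
    main_effects : (p, K-1) array
        θ_{j;l}: log odds of Z_j = l (vs the reference 0) when all other
        taxa sit at the reference level.  Row j, column l-1.
    pairwise : dict[(j, t)] -> (K-1, K-1) array
        θ_{jt;lh}: log odds ratios coupling Z_j = l with Z_t = h, indexed
        ``[l-1, h-1]``.  Keys are ordered pairs of distinct 0-based taxon
        indices; a pair is *inactive* (no edge) iff neither orientation is
        stored with a nonzero entry.
    """

    p: int
    K: int
    main_effects: np.ndarray | None = None
    pairwise: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.p < 1:
            raise ValueError("p must be positive")
        if self.main_effects is None:
            self.main_effects = np.zeros((self.p, self.K - 1))
        self.main_effects = np.asarray(self.main_effects, dtype=float)
        if self.main_effects.shape != (self.p, self.K - 1):
            raise ValueError("main_effects must have shape (p, K-1)")
        clean: dict[tuple[int, int], np.ndarray] = {}
        for (j, t), block in self.pairwise.items():
            if j == t:
                raise ValueError("self-interactions are undefined")
            if not (0 <= j < self.p and 0 <= t < self.p):
                raise ValueError(f"pair ({j}, {t}) out of range")
            block = np.asarray(block, dtype=float)
            if block.shape != (self.K - 1, self.K - 1):
                raise ValueError("pairwise blocks must have shape (K-1, K-1)")
            clean[(j, t)] = block
        self.pairwise = clean

    def group(self, j: int, t: int) -> np.ndarray:
        """The length-(K-1)^2 vector θ_jt in (l, h) row-major order."""
        block = self.pairwise.get((j, t))
        if block is None:
            return np.zeros((self.K - 1) ** 2)
        return block.ravel().copy()

    def active_pairs(self) -> set[tuple[int, int]]:
        """Unordered pairs {j, t} with any nonzero coupling in either orientation."""
        pairs: set[tuple[int, int]] = set()
        for (j, t), block in self.pairwise.items():
            if np.any(block != 0.0):
                pairs.add((min(j, t), max(j, t)))
        return pairs

    # -- serialization ----------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        """Flat table with columns (j, t, l, h, value); t/h empty for main effects.

        Indices are written 1-based to match the conventional θ_{j;l},
        θ_{jt;lh} notation.  Round-trips exactly through ``from_table``.
        """
        rows = []
        for j in range(self.p):
            for l in range(1, self.K):
                rows.append((j + 1, pd.NA, l, pd.NA, self.main_effects[j, l - 1]))
        for (j, t), block in sorted(self.pairwise.items()):
            for l in range(1, self.K):
                for h in range(1, self.K):
                    rows.append((j + 1, t + 1, l, h, block[l - 1, h - 1]))
        return pd.DataFrame(rows, columns=["j", "t", "l", "h", "value"])

    @classmethod
    def from_table(cls, table: pd.DataFrame, p: int, K: int) -> "PottsParameters":
        main = np.zeros((p, K - 1))
        pairwise: dict[tuple[int, int], np.ndarray] = {}
        for row in table.itertuples(index=False):
            j = int(row.j) - 1
            l = int(row.l) - 1
            if pd.isna(row.t):
                main[j, l] = float(row.value)
            else:
                key = (j, int(row.t) - 1)
                block = pairwise.setdefault(key, np.zeros((K - 1, K - 1)))
                block[l, int(row.h) - 1] = float(row.value)
        return cls(p=p, K=K, main_effects=main, pairwise=pairwise)

    def save(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path, p: int, K: int) -> "PottsParameters":
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls.from_table(table, p=p, K=K)


def _check_states(theta: PottsParameters, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.int64)
    if np.any(z < 0) or np.any(z >= theta.K):
        raise ValueError("state values must lie in {0, ..., K-1}")
    return z


def _conditional_logits(theta: PottsParameters, j: int, z_full: np.ndarray) -> np.ndarray:
    """Logits (length K, reference fixed at 0) of Z_j given the rest.

    Both orientations of a stored pair feed the conditional: the term
    φ_jt(z_j, z_t) contributes θ_{jt;l h} I[z_t = h] and φ_tj(z_t, z_j)
    contributes θ_{tj;h l} I[z_t = h], so the Gibbs sampler built on these
    conditionals targets exactly ``log_unnormalized_density``.
    """
    logits = np.zeros(theta.K)
    logits[1:] = theta.main_effects[j]
    for (a, b), block in theta.pairwise.items():
        if a == j and b != j:
            h = z_full[b]
            if h > 0:
                logits[1:] += block[:, h - 1]
        elif b == j and a != j:
            h = z_full[a]
            if h > 0:
                logits[1:] += block[h - 1, :]
    return logits


def conditional_state_probs(
    theta: PottsParameters, j: int, z_others: np.ndarray
) -> np.ndarray:
    """Full conditional P(Z_j = l | Z_{-j} = z_others) for l = 0..K-1.

    ``z_others`` lists the states of the other p-1 taxa in taxon order with
    taxon ``j`` removed.  Baseline-category logits with the reference-level
    logit fixed at zero, then softmax.
    """
    if not (0 <= j < theta.p):
        raise ValueError(f"taxon index {j} out of range")
    z_others = _check_states(theta, z_others)
    if z_others.shape != (theta.p - 1,):
        raise ValueError("z_others must have length p - 1")
    z_full = np.insert(z_others, j, 0)
    logits = _conditional_logits(theta, j, z_full)
    logits -= logits.max()
    probs = np.exp(logits)
    return probs / probs.sum()


def log_unnormalized_density(theta: PottsParameters, z: np.ndarray) -> float:
    """log P(z) up to the (intractable) log normalizing constant."""
    z = _check_states(theta, z)
    if z.shape != (theta.p,):
        raise ValueError("state vector must have length p")
    total = 0.0
    nz = np.nonzero(z)[0]
    for j in nz:
        total += theta.main_effects[j, z[j] - 1]
    for (j, t), block in theta.pairwise.items():
        if z[j] > 0 and z[t] > 0:
            total += block[z[j] - 1, z[t] - 1]
    return float(total)


def _neighbor_tables(theta: PottsParameters):
    """Per taxon, a list of (partner, lookup) with lookup[z_partner] the
    additive contribution (length K-1) to that taxon's nonreference logits."""
    K = theta.K
    tables: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(theta.p)]
    for (j, t), block in theta.pairwise.items():
        fwd = np.vstack([np.zeros((1, K - 1)), block.T])  # indexed by z_t
        tables[j].append((t, fwd))
        rev = np.vstack([np.zeros((1, K - 1)), block])  # indexed by z_j
        tables[t].append((j, rev))
    return tables


def gibbs_sample(
    theta: PottsParameters,
    n: int,
    sweeps: int = 200,
    seed: int | np.random.Generator | None = None,
) -> StateMatrix:
    """Draw n independent configurations by systematic-scan Gibbs sampling.

    Each of the n chains starts from states sampled independently and
    uniformly over {0, ..., K-1}, then performs ``sweeps`` full coordinate
    sweeps (taxa updated in index order) from the full conditionals; the
    final configuration of each chain becomes one sample row.  Chains are
    advanced in lockstep from a single seeded generator, so output is
    reproducible bit-for-bit given the seed.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, K = theta.p, theta.K
    states = rng.integers(0, K, size=(n, p))
    tables = _neighbor_tables(theta)
    for _ in range(sweeps):
        for j in range(p):
            logits = np.tile(np.concatenate([[0.0], theta.main_effects[j]]), (n, 1))
            for t, lookup in tables[j]:
                logits[:, 1:] += lookup[states[:, t]]
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            states[:, j] = (u > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    return StateMatrix(values=states, levels=np.full(p, K))
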