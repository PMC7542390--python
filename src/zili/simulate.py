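"""Synthetic data generator for the chain-structured latent Ising benchmark.

The generative pipeline mirrors the model's data-generating process:

1.  Draw one 6-vector of chain parameters (two main effects, four couplings)
    from N6(mu, diag(sd^2)); the same vector is shared by every taxon within
    a replication, and only the cyclic neighbor couplings θ_{j(j-1)}
    (θ_{1p} for the first taxon) are populated, so the ground-truth network
    is the p-cycle.
2.  Sample latent states by Gibbs sampling (independent chains, 200 sweeps).
3.  Emit absolute abundances X_j | Z_j = z ~ Normal(mu_z, sigma^2) with
    strictly increasing state means (identifiability ordering).
4.  Zero-inflate each taxon column: draw u_j ~ Uniform[0, tau] and replace
    entries strictly below the empirical u_j-quantile with zero.
5.  Total-sum-scale each sample row to relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .containers import AbundanceMatrix, Network, StateMatrix
from .potts import PottsParameters, gibbs_sample

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "sample_chain_parameters",
    "emit_absolute_abundance",
    "inflate_zeros",
    "to_relative_abundance",
    "simulate_dataset",
]

#: Chain parameter means (θ_{j;1}, θ_{j;2}, θ_{j(j-1);11}, θ_{j(j-1);12},
#: θ_{j(j-1);21}, θ_{j(j-1);22}) of the benchmark generator.
DEFAULT_PARAM_MEAN = (-1.0, 3.0, -0.8, 2.0, -3.0, -4.0)
DEFAULT_PARAM_SD = (0.1, 0.3, 0.08, 0.2, 0.3, 0.4)


@dataclass
class SimulationConfig:
    """Knobs of the chain-structured benchmark generator.

    ``emission_means`` are in (arbitrary) absolute-abundance units and must
    be strictly increasing so that latent states are identifiable from
    abundances.  ``tau`` bounds the per-taxon zero-inflation rank
    u_j ~ Uniform[0, tau], so the expected zero fraction per taxon is tau/2.
    """

    p: int = 60
    n: int = 120
    K: int = 3
    param_mean: tuple = DEFAULT_PARAM_MEAN
    param_sd: tuple = DEFAULT_PARAM_SD
    emission_means: tuple = (10.0, 15.0, 20.0)
    emission_sd: float = 10.0
    tau: float = 0.5
    sweeps: int = 200
    clamp_negative: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must lie in (0, 1]")
        means = np.asarray(self.emission_means, dtype=float)
        if len(means) != self.K:
            raise ValueError("emission_means must have one entry per state")
        if np.any(np.diff(means) <= 0):
            raise ValueError("emission_means must be strictly increasing")
        if len(self.param_mean) != 6 or len(self.param_sd) != 6:
            raise ValueError("param_mean and param_sd must have length 6")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("param_mean", "param_sd", "emission_means"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationResult:
    abundance: AbundanceMatrix
    truth: Network
    states: StateMatrix
    parameters: PottsParameters


def sample_chain_parameters(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> PottsParameters:
    """One replication's chain parameters: a single N6(mu, diag(sd^2)) draw.

    The draw (θ_{j;1}, θ_{j;2}, θ_{j(j-1);11}, θ_{j(j-1);12}, θ_{j(j-1);21},
    θ_{j(j-1);22}) is shared by all taxa; only the couplings to the cyclic
    predecessor are populated, so exactly p ordered groups are nonzero and
    the truth network is the p-cycle.
    """
    if config.K != 3:
        raise ValueError("the 6-vector chain parameterization requires K = 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = rng.normal(np.asarray(config.param_mean), np.asarray(config.param_sd))
    main = np.tile(draw[:2], (config.p, 1))
    coupling = draw[2:].reshape(2, 2)  # [l-1, h-1]
    pairwise = {
        (j, (j - 1) % config.p): coupling.copy() for j in range(config.p)
    }
    return PottsParameters(p=config.p, K=config.K, main_effects=main, pairwise=pairwise)


def emit_absolute_abundance(
    states: StateMatrix,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Gaussian emission: X_ij | Z_ij = z ~ Normal(emission_means[z], sd^2).

    Negative draws are retained by default (the zero-inflation step removes
    the left tail and the downstream categorization is scale-agnostic); set
    ``clamp_negative`` to floor them at zero.
    """
    if np.any(states.levels > len(config.emission_means)):
        raise ValueError("state levels exceed the number of emission means")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.asarray(config.emission_means, dtype=float)[states.values]
    X = rng.normal(means, config.emission_sd)
    if config.clamp_negative:
        X = np.maximum(X, 0.0)
    return AbundanceMatrix(values=X, mode="absolute", taxa=list(states.taxa))


def inflate_zeros(
    X: AbundanceMatrix,
    tau: float,
    seed: int | np.random.Generator | None = None,
    u_override: np.ndarray | None = None,
) -> AbundanceMatrix:
    """Left-tail censoring: zero out each taxon's smallest abundances.

    For each taxon j, a rank u_j ~ Uniform[0, tau] is drawn (or taken from
    ``u_override``); the threshold is the nearest-rank empirical u_j-quantile
    (the (floor(u_j * n) + 1)-th order statistic) and entries *strictly
    below* it become zero, so ties at the threshold survive and the realized
    zero fraction is floor(u_j * n) / n for distinct values.
    """
    if X.mode != "absolute":
        raise ValueError("zero inflation applies to absolute abundances only")
    if not (0 <= tau <= 1):
        raise ValueError("tau must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = X.values.shape
    if u_override is not None:
        u = np.broadcast_to(np.asarray(u_override, dtype=float), (p,)).copy()
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("u_override entries must lie in [0, 1]")
    else:
        u = rng.uniform(0.0, tau, size=p)
    values = X.values.copy()
    for j in range(p):
        k = int(np.floor(u[j] * n))
        if k < 1:
            continue
        k = min(k, n - 1)
        threshold = np.partition(values[:, j], k)[k]
        values[values[:, j] < threshold, j] = 0.0
    return AbundanceMatrix(
        values=values, mode="absolute", samples=list(X.samples), taxa=list(X.taxa)
    )


def to_relative_abundance(X: AbundanceMatrix) -> AbundanceMatrix:
    """Total sum scaling: divide every entry by its sample's row sum."""
    rowsum = X.values.sum(axis=1)
    bad = np.nonzero(rowsum <= 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {X.samples[bad[0]]!r} has nonpositive total abundance; "
            "cannot normalize to relative abundances"
        )
    return AbundanceMatrix(
        values=X.values / rowsum[:, None],
        mode="relative",
        samples=list(X.samples),
        taxa=list(X.taxa),
    )


def simulate_dataset(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> SimulationResult:
    """Full benchmark pipeline: parameters → Gibbs states → emission →
    zero inflation → total sum scaling.  Deterministic given the seed
    (``seed`` overrides ``config.seed`` when given)."""
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = sample_chain_parameters(config, rng)
    states = gibbs_sample(theta, n=config.n, sweeps=config.sweeps, seed=rng)
    absolute = emit_absolute_abundance(states, config, rng)
    inflated = inflate_zeros(absolute, config.tau, rng)
    relative = to_relative_abundance(inflated)
    truth = Network.cycle(relative.taxa)
    return SimulationResult(
        abundance=relative, truth=truth, states=states, parameters=theta
    )
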