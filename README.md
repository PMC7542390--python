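# zili — microbial interaction networks from zero-inflated relative abundances

Relative abundance tables from 16S/metagenomic surveys are a hostile
substrate for conditional-dependence analysis: total-sum scaling imposes a
unit-sum constraint that manufactures spurious correlations, most taxa are
zero in most samples, and the taxon count routinely exceeds the sample
count.  `zili` estimates a **microbial interaction network** — a graph
whose edges encode conditional dependence between taxa — by assuming each
taxon's abundance is driven by a small number of latent discrete states
(absent/low/…/high) and modeling the state vector
`Z = (Z_1, …, Z_p)` with a **multiclass Ising (Potts) Markov random
field**:

```
P(z) ∝ exp{ Σ_j φ_j(z_j) + Σ_(j,t) φ_jt(z_j, z_t) },     φ_jt(l,h) = θ_{jt;lh}
```

Taxa j, t share an edge iff the coupling group θ_jt = (θ_{jt;lh}) is
nonzero in either orientation.  Because the estimator works on *states*
rather than proportions, the unit-sum constraint and the zero excess stop
being modeling obstacles: zeros simply populate the lowest state.

Estimation is a two-step algorithm:

1. **State estimation** — per taxon, the sorted abundances are split into
   K contiguous classes by an exact dynamic program minimizing
   within-class sum of squares (Fisher's optimal partition); K is chosen
   by an elbow rule on the loss decrements (upper bound 6), with a
   zero/nonzero rule for taxa under 1 % prevalence.
2. **Neighborhood selection** — each taxon's states are regressed on
   indicator encodings of all other taxa's states by group-lasso penalized
   baseline-category logistic regression
   (`penalty λ Σ_t √m_jt ‖θ_jt‖₂`), λ tuned per regression by the
   extended BIC; edges assembled by the OR rule.

Included besides the estimator: the chain-structured synthetic benchmark
generator (Gibbs-sampled Potts states → Gaussian emission → percentile
zero-inflation → total-sum scaling), Gaussian-graphical-model and
dichotomous-Ising baselines, TPR/FPR scoring, a replicated simulation-study
driver, and a χ²-based network comparison.  See `docs/methods.md` for the
full model and algorithmic detail.

Intended users: statisticians and computational biologists studying
co-occurrence/interaction structure in compositional microbiome data, and
anyone needing a clean reference implementation of latent-state graphical
model selection for abundance tables.

## Worked example

```python
import zili

# simulate a 20-taxon community, 300 samples, cyclic interaction truth
config = zili.SimulationConfig(p=20, n=300, emission_sd=1.0, tau=0.1)
result = zili.simulate_dataset(config, seed=42)

fit = zili.fit_zili(result.abundance)          # two-step estimator
tpr, fpr = zili.tpr_fpr(fit.network, result.truth)
print(f"edges: {fit.network.n_edges}  TPR: {tpr:.3f}  FPR: {fpr:.3f}")
print("states per taxon:", sorted(set(map(int, fit.states.levels))))
```

Output:

```
edges: 20  TPR: 1.000  FPR: 0.000
states per taxon: [3, 4]
```

All 20 true cycle edges are recovered with no false positives (low
emission noise, light zero inflation, ample samples); the class-number
rule settles on 3–4 states per taxon — the three emission components plus,
for some taxa, a separate zero-spike class.  At higher noise the same
pipeline degrades gracefully; the driver maps the whole regime grid:

```python
table = zili.run_simulation_study(sigmas=(1.0, 10.0), ns=(60, 120),
                                  taus=(0.5,), replications=20,
                                  methods=("zili", "dis", "ggm"), seed=0)
```

The same functionality is scriptable from the shell:

```bash
zili simulate --p 20 --n 300 --sigma 1 --tau 0.1 --seed 42 \
     --out x.tsv --truth-out truth.tsv
zili fit --input x.tsv --output net/          # writes edge list + GraphML
zili states --input x.tsv --out states.tsv --summary-out ktable.tsv
zili compare --net-a net/network.tsv --net-b truth.tsv
```

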