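# sbmcircuit

Connectivity-based neuronal classification and mesoscale circuit analysis.
Starting from a directed, weighted potential connectome (integer
axonal–dendritic overlap counts), the package:

1. **binarize** — converts strengths to connection probabilities
   (`a_p = 1 − (1 − p_conn)^a_c`, with `p_conn` auto-selected so the mean
   nonzero probability is 0.5) and samples an ensemble of `G` trimmed
   binary connectomes.
2. **embed** — clusters each binary connectome by adjacency spectral
   embedding (rank-`d` SVD, `[X|Y]` latent positions, profile-likelihood
   elbow dimension selection) plus GMM/EM with BIC model selection,
   initialized from Ward agglomerative partitions.
3. **consensus** — merges the `G` clusterings via modified iterative
   voting consensus, τ-chain equivalence on the co-clustering similarity
   matrix, and a minimum-class-size filter.
4. **blockmodel** — estimates the class-to-class connection probability
   matrix, floors small entries (keeping every class covered) into a
   circuit, and extracts subset-restricted (e.g. per-neurotransmitter)
   pathways and top-fraction edge filters.
5. **walks / metrics / annotate / growth** — random-walk absorption and
   driftiness (exhaustive enumeration oracle + importance-weighted
   sampling), hub detection (weighted degree × betweenness), binomial
   goodness-of-fit, histogram intersection, biomarker posterior tables,
   entropy/MI/NMI/ARI scheme comparison, and cumulative daily growth
   percentages with critical-period detection.
6. **synth** — planted stochastic-block-model connectome generator with
   long-tailed integer strengths and tunable-association categorical
   metadata, so every stage is testable without external data.

## CLI

```sh
# generate a synthetic 6-block connectome
sbmcircuit simulate --n 2000 --kappa 6 --out data/

# full pipeline (Matrix Market strengths + optional metadata CSV)
sbmcircuit full data/strengths.mtx --metadata data/metadata.csv \
    -G 10 --c-size 10 --k-max 10 --out runs/demo

# individual stages
sbmcircuit binarize data/strengths.mtx -G 10 --out runs/bin
sbmcircuit walks runs/demo/circuit.graphml --out runs/walks
```

`full` writes the consensus partition, block probability matrix, floored
circuit (GraphML + edge list), walk statistics, hub report, biomarker
posterior/NMI tables, growth profiles and a reproducibility manifest.

## Python API

```python
from sbmcircuit import (
    SBMSpec, generate_sbm_strengths, PipelineConfig, run_pipeline,
)

ds = generate_sbm_strengths(SBMSpec(n=2000, kappa=6, rho=(1/6,)*6, P=P))
run_pipeline(ds.strengths, "runs/demo",
             PipelineConfig(p_conn=None, d=None, G=10, c_size=10, seed=0))
```

Reference full-scale parameters are `{p_conn=0.15, d=11, G=100, tau=0.95,
c_size=100}` (the `PipelineConfig` defaults); `p_conn=None` / `d=None`
switch on data-driven selection.

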