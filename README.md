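# tissuegraph

Spatial-graph tissue phenotyping for spatial single-cell omics.

Multiplexed imaging assays (IMC, CODEX) measure dozens of protein markers
per cell in intact tissue, so a tissue image can be modeled as a **spatial
proximity graph**: nodes are cells with molecular or cell-type features,
and an edge connects cells whose Euclidean distance is below a radius `r`
(`a_ij = 1 if ||z_i - z_j||_2 < r else 0`). `tissuegraph` asks, and lets
you ask, a precise question about such data: *how much of a tissue-level
phenotype (tumor grade, immune-infiltration anatomy) is predictable from
composition alone, from dissociated single cells, from density structure,
or only from the full spatial graph?*

The package provides:

- **`tissuegraph.simulate`** — synthetic cohorts (patients × images × cells)
  whose class labels are encoded through exactly one tunable channel:
  composition, density, spatial arrangement (aggregated vs. diffuse immune
  cells), cell-type interaction, or an ordinal grade driven by a latent
  severity that also drives right-censored survival. At signal strength 0
  the class-conditional laws are identical.
- **`tissuegraph.graphs`** — radius graphs, degree histograms, symmetrized
  kNN graphs, spectral clustering, neighboring-cluster composition targets,
  the node-feature permutation control, expression-correlation graphs.
- **`tissuegraph.models`** — the ablation ladder's model families on a
  small NumPy autodiff core: bulk MLP / random forest / logistic
  regression, multi-instance networks, GCN (symmetric and sum
  aggregation), GIN (`h_i' = MLP((1-eps) h_i + sum_{j in N(i)} h_j)`, mean
  pooling of concatenated layer embeddings), dot-product GAT
  (`alpha_ij = softmax_j(x_i^T W_Q W_K^T x_j)`), a neighboring-cluster
  composition self-supervision head, multi-task heads, and the loss menu
  including a right-censored MSE.
- **`tissuegraph.evaluate`** — patient-grouped nested cross-validation
  (3 test × 3 validation splits), grid search, step-wise AUPR
  (`sum_i (R_i - R_{i-1}) P_i`, macro-averaged), unpaired two-sided t-test
  arm comparisons, prevalence baselines, and the `run_ablation` driver.
- **`tissuegraph.interpret`** — graph-embedding manifolds (quantile
  normalization + PCA), right-censored concordance, attention-derived
  cell-type interaction matrices, filter-gradient context, input-gradient
  cell saliency with degree/immune-fraction stratification, and
  neighborhood-composition contrasts.

See `docs/methods.md` for model definitions, generator assumptions and
statistical caveats.

## Worked example

Simulate a cohort in which the two classes share composition, density and
marker statistics and differ *only* in whether immune cells aggregate into
compact structures, then run a three-arm ablation:

```python
import numpy as np
import tissuegraph as tg

cfg = tg.SimConfig(n_patients=28, images_per_patient=4, cells_per_image=500,
                   signal=tg.SignalConfig(channel="arrangement", strength=1.0))
cohort = tg.simulate_cohort(cfg, seed=13)

ladder = [
    {"arm": "spatial_gin", "view": "graph_immune_binary", "family": "gin",
     "view_params": {"r": 50}, "spec": {"depth_node": 2, "width_node": 8}},
    {"arm": "fractions", "view": "bulk_fractions", "family": "logreg",
     "view_params": {"space": "immune_binary"}},
    {"arm": "permuted", "view": "graph_permuted", "family": "gin",
     "view_params": {"r": 50, "space": "immune_binary", "seed": 7},
     "spec": {"depth_node": 2, "width_node": 8}},
]
report = tg.run_ablation(cohort, ladder, mode="train_test", seed=0,
                         train_kwargs={"batch_size": None,
                                       "fixed_epochs": 40, "lr": 1e-2})
for arm, vals in report["selected_aupr"].items():
    print(f"{arm:12s} mean AUPR {np.mean(vals):.3f}")
print(report["comparisons"][["arm_a", "arm_b", "delta_aupr", "p"]].round(4))
```

Output (seed 13):

```
spatial_gin  mean AUPR 1.000
fractions    mean AUPR 0.405
permuted     mean AUPR 0.471
         arm_a      arm_b  delta_aupr       p
0  spatial_gin  fractions      0.5951  0.0000
1  spatial_gin   permuted      0.5293  0.0000
2    fractions   permuted     -0.0658  0.0501
```

The spatial GIN recovers the planted arrangement signal perfectly, while
the cell-type-fractions baseline and the permuted-features control hover
around the prevalence baseline (0.5, within small-test-fold noise): the
label is carried by *where* the immune cells are, which only the graph
model can see. The per-arm values are the mean test AUPRs of the nine
nested-CV winners; `p` is the unpaired two-sided t-test between arms.

## Command line

```bash
tissuegraph simulate --config sim.yaml --seed 1 --out cohort_dir/
tissuegraph ablate --config run.yaml --cohort cohort_dir/ --seed 1 --out results/
tissuegraph interpret embed --cohort cohort_dir/ --checkpoint model_dir/ --out emb.csv
```

Cohorts are stored as a columnar cell table (`cells.csv`) plus a JSON
metadata sidecar; results are tidy CSV tables.

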