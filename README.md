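# lagnet

Gene regulatory network (GRN) inference from time-course expression data
with the **time-lagged Ordered Lasso**: a per-gene l1-penalized
autoregression whose coefficient magnitudes are constrained to decay with
the lag.

## The problem

Given expression trajectories x_1(t) … x_p(t) sampled every Δt (one or more
replicate series), which gene regulates which?  `lagnet` fits, for every
target gene *i*,

    min  1/2 Σ_t ( x_i(t) − Σ_j Σ_{k=1..l_max} w_{ji,k} x_j(t−kΔt) )²  +  λ Σ_{j,k} |w_{ji,k}|
    s.t. |w_{ji,1}| ≥ |w_{ji,2}| ≥ … ≥ |w_{ji,l_max}|  for each predictor j,

and predicts the edge *j → i* when any lag coefficient of *j* is non-zero
(under the constraint: when the first one is).  The order constraint says
that recent expression is more informative than older expression; it lets
the model pick each regulator's maximum effective lag automatically, so
results are robust to the choice of `l_max`.  Edges are ranked by the
penalty at which they first enter along a descending λ path ("entry value"),
and ranked networks are scored with merged-path ROC AUC or
precision/recall/F1 against a reference network.

The package also provides

* **semi-supervised refinement**: separate penalties λ_edge / λ_non-edge for
  pairs inside and outside a prior network, yielding *novel* (non-prior but
  supported by the data) and *anomalous* (prior but unsupported) edges;
* **baselines**: pairwise Granger causality (F-tests with BH correction) and
  Lasso-Granger (the same fit without the order constraint);
* **simulators**: the three-gene repressilator ODE and sparse vector
  autoregressions with known ground truth, plus a (T, Δt, l_max) AUC sweep.

Intended users: computational biologists benchmarking network-inference
methods on time-series data, and anyone needing an order-constrained lasso
path with a clean Python API.

## Worked example

```python
import numpy as np
import lagnet as ln

# simulate a densely sampled repressilator (alpha=4, n=3)
data, truth = ln.simulate_repressilator(
    ln.RepressilatorParams(T=6 * np.pi, dt=6 * np.pi / 256)
)

# rank all 6 off-diagonal gene pairs by their entry value on the lambda path
path = ln.edge_entry_path(data, l_max=1)
for (j, i), lam in sorted(path.entry_value.items(),
                          key=lambda kv: -(kv[1] or 0)):
    star = "*" if (j, i) in truth.edges else " "
    print(f"  {data.gene_names[j]} -> {data.gene_names[i]}  "
          f"entry lambda = {lam:9.4f}  {star}")

roc = ln.auc_from_entries(path, truth)
print("merged-path ROC AUC:", roc.auc)
```

prints

```
  z -> x  entry lambda =   11.1536  *
  x -> y  entry lambda =   11.1536  *
  y -> z  entry lambda =   11.1536  *
  z -> y  entry lambda =    0.0219
  x -> z  entry lambda =    0.0199
  y -> x  entry lambda =    0.0151
merged-path ROC AUC: 1.0
```

The three true repression edges (starred) enter the model at a penalty
almost three orders of magnitude larger than any false pair, so the ranking
separates them perfectly (AUC = 1): the entry value is a usable measure of
edge confidence.  Thresholding the path anywhere between those levels
recovers exactly the true network (precision = recall = F1 = 1).

The same pipeline is available from the shell:

```sh
lagnet simulate-repressilator --outdir sim/
lagnet fit-denovo --series sim/expression.tsv --l-max 1 --outdir fit/
lagnet evaluate --entry-path fit/entry_path.tsv --truth sim/truth_edges.tsv \
                --genes sim/expression.tsv --outdir eval/
```

Expression files are genes-as-rows TSV (first column = gene id, one column
per time point, one file per replicate series); edge lists are headerless
`source<TAB>target` TSV.  Every command writes a `run_log.json` with its
parameters and wall time.

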