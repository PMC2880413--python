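# pmdlnet

Reverse engineering of gene regulatory networks from time-series expression
data, using information theory end to end: time-lagged mutual information to
score candidate regulator→target edges, a predictive minimum-description-length
(MDL) criterion to pick the MI cutoff without a hand-tuned parameter, and
time-lagged conditional mutual information (CMI) to prune edges that a third
gene explains away. A probabilistic network simulator and a precision/recall
benchmarking harness are included, so the method can be evaluated entirely on
synthetic ground truth.

The package is aimed at systems-biology practitioners working with short,
discretized microarray-style time courses (tens of genes, tens of time
points), and at anyone studying information-theoretic network inference.

## The method

Genes take discrete expression levels in the alphabet `A_q = {0, …, q−1}`
(binarized data, `q = 2`, is the common case). A network is a directed graph
in which each gene `x_i` has a conditional probability table (CPT)
`p(x_{i,t+1} | P_t(x_i))` over the states of its regulator set `P(x_i)`; the
network induces a factorized Markov chain on expression states,

```
p(X_{t+1} | X_t) = ∏_i p(x_{i,t+1} | P_t(x_i)).
```

Inference proceeds in three stages:

1. **MI matrix.** Every ordered pair is scored by the plug-in lagged MI
   `M[i,j] = I(x_i(t); x_j(t+1)) = H(X_t) + H(Y_{t+1}) − H(X_t, Y_{t+1})`
   (bits); the unit lag gives edges a direction.
2. **Predictive-MDL cutoff selection.** Every distinct off-diagonal value of
   `M` is tried as a cutoff `δ`; each induces the candidate network with edge
   set `{(i,j) : M[i,j] ≥ δ}`, whose CPTs are fitted by maximum likelihood
   and whose description length `L = Σ_t −log₂ p(X_{t+1}|X_t)` (the
   accumulated code length of the observed transitions; the initial-state
   term is the same for all candidates and dropped) is computed. The shortest
   `L` wins; ties go to the largest `δ`, i.e. the sparsest of the equally
   short models.
3. **CMI pruning.** For each surviving edge `x → y` and every other gene
   `z`, the lagged CMI `I(x_t; y_{t+1} | z_t)` is evaluated; if the minimum
   over `z` falls below the single user threshold `Th`, the edge is deemed
   indirect and deleted. `Th ≈ 0.1` bits is the useful operating point for
   binary data.

Evaluation uses directed-edge precision `P = Ce/(Ce+Fe)` and recall
`R = Ce/(Ce+Me)` against the simulator's ground truth (`Ce` correct, `Fe`
false, `Me` missed edges).

## Worked example

Simulate a 5-gene, 30-point dataset, then infer the network back:

```
$ pmdlnet simulate --n 5 --m 30 --seed 7 --out-prefix demo
5-gene network with 11 edges -> demo.truth.sif, demo.data.tsv

$ pmdlnet infer --input demo.data.tsv --quantized --cmi-threshold 0.1 \
      --output demo.edges.sif --tsv demo.edges.tsv --report demo.report.json
selected MI cutoff 0.0000; 20 edges before pruning, 4 after -> demo.edges.sif

$ cat demo.edges.tsv
source  target  mi        min_cmi
g1      g3      0.133491  0.112300
g2      g5      0.146021  0.122322
g3      g5      0.449735  0.432490
g4      g1      0.133028  0.110224
```

The MDL scan keeps a permissive cutoff (20 candidate edges); the CMI stage
then removes every edge whose dependence some third gene explains away,
leaving four edges, all of which are in the simulated ground truth
(precision 1.0, recall 4/11 ≈ 0.36 on this run — the short series leaves
many weak edges undetected). `mi` is the lagged mutual information that
admitted the edge and `min_cmi` the smallest conditional MI over all
conditioning genes; both are in bits.

The same pipeline is available as a library:

```python
from pmdlnet import SimConfig, generate_network, simulate_timeseries
from pmdlnet import InferenceConfig, infer_network, score

net = generate_network(SimConfig(n=20, m=50, seed=1))
data = simulate_timeseries(net, 50, seed=2)
conn, report = infer_network(data, InferenceConfig(cmi_threshold=0.1))
print(score(net, conn))
```

Real expression matrices (tab-delimited, genes in rows, `NA` for missing
values) go through `pmdlnet quantize` (neighbour-mean filling, outlier-robust
median binarization) before inference, or `pmdlnet infer --input expr.tsv`
runs both steps.

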