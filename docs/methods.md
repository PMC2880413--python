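# Methods

## Model

A gene regulatory network over `n` genes is a directed graph together with
one conditional probability table (CPT) per gene: with expression quantized
to the alphabet `A_q = {0, …, q−1}`, a gene with `k` regulators has a
`q^k × q` table giving `p(x_{t+1} = v | parent state s)`. Row indices encode
the parent-state tuple with the first (lowest-index) parent most
significant. The network induces a time-homogeneous Markov chain on
expression states whose transition probability factorizes over genes. The
model is assumed first-order (only the previous time point matters),
time-invariant, and synchronous: every regulation acts once per sampling
step, which is why a unit time lag carries the direction information.

CPTs are estimated by maximum likelihood from the `m−1` observed
transitions, with no smoothing. Parent states that never occur in the data
get no fabricated probabilities: dense tables mark them NaN, and tables
whose `q^k` exceeds 4096 rows switch to a sparse representation that stores
only the observed parent states (at most `m−1` of them). The two forms are
semantically identical on observed states, and the description length never
queries an unobserved state because it only scores transitions that were
themselves counted.

## Description-length model selection

The predictive description length of the data under a candidate network is
the accumulated code length of the observed transitions,
`L = Σ_{t=1}^{m−1} −log₂ p(X_{t+1} | X_t)`, in bits. The cost of the
initial state is common to all candidates and omitted; no model-coding term
is added — candidates are compared by data length alone. Candidate networks
are generated by thresholding the lagged-MI matrix at every one of its
distinct off-diagonal values (`≤ n(n−1)` candidates); the inclusive rule
`M[i,j] ≥ δ` means the largest candidate still induces a non-empty model.

Two numerical facts shape the scan's behaviour, and the implementation is
explicit about both:

* Adding a parent can never increase the empirical conditional entropy of a
  gene, so `L(δ)` is non-increasing as `δ` falls and its minimum always
  includes the densest candidate. On structured data `L` reaches its
  minimum (typically exactly zero, once every observed parent state
  determines its child value) well before the densest candidate, producing
  a plateau of equally short models.
* The tie-break therefore does the real model selection: among candidates
  within 1e−9 bits of the minimum, the largest `δ` — the sparsest of the
  equally short models — is returned. On pure-noise data there is no
  plateau and the scan returns a dense model; the CMI stage is then what
  empties it.

Because candidate edge sets are nested along the sorted cutoffs, each
gene's parent set along the scan is a prefix of its potential parents
ordered by decreasing MI. The scan computes each gene's description length
once per distinct prefix (at most `n` per gene) from transition counts
keyed by observed parent states, giving an `O(n² · m)`-ish scan in practice
and never materializing a dense CPT. Optional `max_parents` /
`max_table_cells` caps skip candidates whose tables would exceed a budget
(with a logged warning); both default to off.

## CMI pruning

For every edge `x → y` of the selected model, the plug-in lagged CMI
`I(x_t; y_{t+1} | z_t)` is computed for every conditioning gene
`z ∉ {x, y}`, and the edge is deleted when the minimum over `z` falls below
the user threshold `Th` (default 0.1 bits). Edges with no eligible `z`
(2-gene networks) are kept. All deletions are evaluated against the
pre-pruning connectivity in one pass, so the result does not depend on edge
order, and pruning never adds edges — raising `Th` can only shrink the
network, which is the mechanism behind the precision-up / recall-down trend
the benchmark reproduces. A config option (`prune_conditioning="parents"`)
restricts `z` to the other inferred regulators of `y`; with the dense
models the scan typically selects, the two conditioning modes give
indistinguishable benchmark results, so the default conditions on all
genes.

All information quantities use base-2 logarithms throughout; a fixed base
choice only rescales thresholds and description lengths uniformly.
Plug-in estimates are clamped to zero when floating-point cancellation
leaves a residue smaller than 1e−12 in magnitude.

## Preprocessing

Missing values are filled per gene: interior gaps by linear interpolation
between the nearest observed neighbours (for a single gap this is exactly
the mean of the two neighbours), leading/trailing gaps by the nearest
observed value. Binarization is per gene and outlier-robust: the smallest
and largest of the gene's sorted values are excluded (exactly one each;
they are still quantized), the median of the rest is the split point, and
values strictly above it map to 1. Ties at the split map to 0, which makes
constant genes all-zero and the procedure deterministic. The general
`q`-level routine uses equal-frequency binning against the gene's own
empirical quantiles; `q = 2` with outlier dropping reproduces the binary
recipe.

## The simulator and what the benchmarks mean

The synthetic generator draws, per gene, a parent count uniform in
`{1, …, 3}` and that many distinct parents uniformly at random (no
self-loops), then fills each CPT row by placing probability 0.85
(`determinism`) on one uniformly chosen level and splitting the remainder
evenly. Trajectories start from a uniform random state and follow the
induced Markov chain; one trajectory per dataset, matching single-series
microarray experiments. Benchmark defaults are 50 time points and 10
replicates per condition, with per-replicate seeds derived from a single
base seed via `SeedSequence` so every experiment is reproducible
bit-for-bit.

`determinism` is the signal-to-noise dial: 1.0 gives a deterministic
Boolean network, `1/q` pure noise. Uniformly random dominant levels mean a
multi-parent gene's regulation is frequently non-monotone (XOR-like), in
which case a single parent's *marginal* lagged MI with the child can be
near zero even though the joint regulation is strong — such edges are
invisible to any pairwise-MI first stage. The generator's dense feedback
structure also duplicates information across genes, and the min-over-`z`
pruning rule deletes a true edge whenever any other gene carries
approximately the same signal as its regulator. Both effects depress recall
(measured here: ~28% mean recall at `Th = 0.1`, with precision 80–90%,
rising above 95% at `Th ∈ {0.15, 0.2}`) relative to what a generator with
monotone, less redundant regulation would show. Passing benchmarks
therefore demonstrate correct mechanics and the expected precision/recall
threshold trade-off, not field performance on real expression data, where
regulation is typically monotone but where measurement noise,
non-stationarity and unmeasured regulators add their own difficulties.

The data-size sweep uses one 20-gene network (the experiment's network size
is a free choice; 20 is the smallest benchmark size) with one 75-point
trajectory, running inference on the first 15, 20, …, 75 points — 13 runs —
and reporting precision, recall and their ratio per prefix length.

## Known limitations

* Plug-in MI/CMI on ~50 transitions carries a positive bias of roughly
  `0.02–0.05` bits; the CMI threshold `Th` implicitly absorbs it. No bias
  correction or significance testing is attempted.
* The minimum-over-`z` pruning is aggressive in redundant networks (see
  above); recall is the casualty.
* Single lag only; slower regulation spread over several sampling steps is
  out of scope, as are continuous-valued models and multi-condition or
  replicate designs.
* Degenerate precision/recall denominators (empty inferred or true edge
  sets) are reported as missing and excluded from averages, with a logged
  count.
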