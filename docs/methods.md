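# Methods

## Model

The classifier performs transductive binary node classification on a
gene–gene network: given features `X ∈ R^{N×F}`, a symmetric binary
adjacency `A` with zero diagonal, and labels `y ∈ {0, 1, NA}^N`, it
scores every gene's likelihood of being a cancer driver.

The encoder interprets message passing as a discrete diffusion process.
In one update step a gene's state is a convex combination of all genes'
states, with per-pair diffusivities realized as a learned attention
matrix: `R_ij = σ(q_i · k_j)` over *all* ordered pairs (diagonal
included — a gene attends to itself), row-normalized so each row of the
diffusivity matrix sums to one.  The sigmoid kernel keeps every entry
strictly positive, so the attention output always lies in the convex hull
of the value rows.  A parallel branch propagates the same value matrix
over the observed topology with the symmetrically normalized adjacency
`D^{-1/2} A D^{-1/2}` — deliberately without self-loop augmentation, so
isolated genes receive the zero vector (`0^{-1/2} ≡ 0` convention) and
the branch carries purely relational information.  The two branch outputs
are concatenated, linearly fused (`W_d ∈ R^{2d×d}`), mixed with the
previous layer's embedding as `β·fused + (1−β)·Z_prev`, and row-wise
layer-normalized.  The residual share `(1−β)` corresponds to the
self-retention term of the diffusion update and is the main guard against
over-smoothing.

The readout spans all `T+1` layer states (layer 0 = the ReLU feature
projection): `M = Σ_t α_t Z^t W_Z^t` with free scalar layer weights
`α_t`.  The α are *not* softmax-normalized by default — they are plain
learnable scalars initialized at 0.5; an optional flag enables softmax
normalization for experimentation.  `M` is reported as the gene score
(logit); `σ(M)` enters the loss.  The loss is the mean binary
cross-entropy over the labeled genes selected by the training mask, with
probabilities clamped to `[1e-7, 1−1e-7]`; unlabeled genes receive
predictions but never contribute to the loss, and no class reweighting is
applied.

### Orientation and conventions

Embeddings are row vectors; every linear map is a right multiplication
`Z @ W`.  Node order is lexicographic by gene identifier, fixed at load
time; all matrices share it.  Ranks in prediction files are 1-based by
descending probability with ties broken by ascending gene id.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `hidden_dim` (d) | 100 | embedding width of every layer |
| `n_layers` (T) | 4 | fused encoder layers; readout uses T+1 states |
| `beta` | 0.5 | share of fresh propagated information in the residual mix (dimensionless, in [0,1]) |
| `learning_rate` | 0.001 | Adam step size |
| `epochs` | 100 | full-graph training rounds |
| `use_*` flags | on | disable one architecture component each (ablations) |
| `gcn_input` | `value` | graph branch propagates the value matrix; `embedding` propagates Z directly |
| `omega` | 0.1 | weight of the pairwise term in the diagnostic energy |
| `kappa` | log(1+s) | concave pairwise penalty, κ(0)=0 |

With a single branch disabled, the fusion matrix shrinks to `d×d` and the
remaining branch feeds it alone.  Disabling the residual fixes the mix at
`β = 1` while keeping the LayerNorm.  Disabling the multi-layer readout
scores from the final layer only.

### Initialization and numerics

All transform matrices use Glorot-style uniform initialization
(`±sqrt(6/(fan_in+fan_out))`), seed-driven; biases and LayerNorm shifts
start at zero, gains at one, layer weights α at 0.5.  The per-layer
readout projections `W_Z` start at **zero**, so the model begins at
probability 0.5 for every gene (loss ln 2): the first optimization steps
are then small and the early loss trajectory is stable rather than
oscillatory.  All computation is float64.  LayerNorm adds 1e-5 to the
per-row variance before the square root.  The sigmoid is evaluated in its
numerically stable split form.  Gradients come from a minimal in-package
reverse-mode engine (`ecdcdgi.autodiff`) whose every primitive is checked
against central finite differences in the tests.

The energy functional `E(Z, Z_ref) = ‖Z − Z_ref‖_F² + ω Σ_{ij}
κ(‖z_i − z_j‖²)` is purely diagnostic: it is computed on layer outputs
when requested (`--log-energy`, `diagnose`) and never enforced as a
constraint.  κ is configurable but validated numerically to be
increasing, concave, and zero at zero; concavity softens the penalty on
already-distant pairs so representation diversity is not punished.
Whether the learned model drives this energy down layer-to-layer is an
empirical question the trajectory lets the user inspect; nothing in
training forces it.

## Synthetic benchmarks

The generator emulates the statistical shape of real CDG benchmarks, not
their biology:

* **Topology** — Barabási–Albert preferential attachment (`attach_m`
  edges per new node), giving the hub-dominated, heavy-tailed degree
  structure of biomolecular networks.  Edge count is exactly
  `attach_m · (n − attach_m)`.
* **Features** — i.i.d. Gaussian noise (`noise_sd`, default 1) in
  `n_features` dimensions (default 58, matching common multi-omic
  feature panels), with a mean shift `effect_size` added on the first
  `n_informative` dimensions (documented, deterministic choice) of
  positive genes.
* **Labels** — a `labeled_fraction` of genes is labeled, a
  `pos_fraction` of those positive, the rest NA.  `homophily` controls
  how strongly positives cluster on the graph; the topology-signal
  variant grows positives as connected clusters and keeps only a weak
  feature shift, which is the fixture on which the graph-convolution
  branch earns its keep.

One global seed spawns three independent sub-streams (topology, features,
labels), so changing one knob never perturbs the others.  The default
condition used throughout the tests is n=600, attach_m=3, 58 features
with 8 informative at effect size 1.0, 300 labeled genes at 40%
positives.  Under that condition the Bayes-optimal feature-only AUC is
about `Φ(√8/√2) = 0.98`, so cross-validated AUC well above 0.85 indicates
the model actually learns the planted signal, and AUPR is judged against
the 0.4 prevalence baseline.

What the generator does **not** model: feature correlations and mixed
scales of real omics data, assortativity beyond preferential attachment,
label noise, and any mechanistic meaning of individual dimensions.
Passing tests therefore demonstrate that the implementation is correct
and can extract planted signal of both feature and topological kind — not
that it matches any particular performance level on real networks.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default ten repeats of five
folds) over the labeled genes.  Stratification keeps the class ratio per
fold stable under imbalance.  The graph and features stay visible to
every fold's model — only the loss mask changes — which is the standard
transductive protocol.  Metrics (AUC in the Mann–Whitney tie-aware form,
AUPR as the descending-sweep step sum / average precision) are computed
on held-out genes only, i.e. from out-of-fold scores, and the report
exposes per-fold values, per-repeat means, and the joint mean.

Rank aggregation across networks uses mean-rank (Borda) scoring with
missing genes assigned one rank past the list end and lexicographic
tie-breaks; it is isolated behind one function so alternative consensus
schemes can be swapped in.  Score skewness uses the adjusted
Fisher–Pearson form.  The connectivity diagnostic counts, for each
candidate gene (scored genes outside the known-driver set), its direct
known-driver neighbors, and reports the Spearman correlation of those
counts with the scores (average-rank ties, large-sample t p-value; exact
permutation p available for ≤10 candidates).

## Problem sizes in tests and the acceptance script

The planted-signal check runs the full default condition (n=600, 5-fold).
The ablation and null checks run on 300-node graphs with 3-fold CV over
5 and 10 seeds respectively — sizes chosen so that each check is a
seed-averaged directional comparison completing in minutes on one CPU
while remaining comfortably powered for the effect sizes involved.  The
acceptance script derives every fixture seed, fold shuffle and weight
initialization from its single `--seed` argument.

## Known limitations

* Attention is dense: O(N²) time and memory per layer.  Fine at desk
  scale (≲ a few thousand genes); real 11k-gene networks are feasible but
  slow on one CPU.  No sparse or linear-time attention approximation is
  provided, and no multi-head variant (one similarity matrix per layer).
* Full-batch training only; no mini-batching, dropout, weight decay,
  early stopping, or hyperparameter search.
* The two-branch design shares the value transform: the graph branch
  propagates `V` by default (`gcn_input="value"`), which couples the
  branches' parameterization.
* No identifier mapping between gene-symbol namespaces and no parsers for
  database-native dump formats; inputs are plain delimiter-separated
  files.
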