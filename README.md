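# ecdcdgi

Cancer driver gene (CDG) identification on gene–gene networks with an
energy-constrained diffusion attention model.

## The problem

Known driver genes are a small, partially labeled minority of the genes in
a biomolecular network; the rest are confident non-drivers or unlabeled.
Graph neural networks that only aggregate over direct neighbors are easily
dominated by high-degree hubs and miss dependencies between genes that are
not directly connected.  This package implements a transductive node
classifier that treats message passing as a *diffusion process over all
gene pairs*: the diffusivity between genes *i* and *j* is a learned,
sigmoid-kernel attention weight, so every gene's representation is a
convex combination of every other gene's, while a parallel graph
convolution branch injects the actual network topology.

## The model

Given features `X ∈ R^{N×F}` and symmetric adjacency `A`:

1. `Z⁰ = ReLU(X W_I + b_I)` — projection into a d-dimensional space;
2. per layer *t*: `K = Z W_K`, `Q = Z W_Q`, `V = Z W_V`;
   `R_ij = σ(q_i · k_j)` (all pairs, diagonal included);
   `P = diag(R·1)⁻¹ R · V` — row-normalized diffusion attention;
   `H = D^{-1/2} A D^{-1/2} V` — graph convolution (no self-loops,
   isolated genes get the zero vector);
   `Z^{t+1} = LayerNorm(β · W_d[P‖H] + (1−β) Z^t)` — fusion with a
   residual mix that plays the role of the diffusion self-term;
3. readout over **all** layers: `M = Σ_{t=0}^{T} α_t Z^t W_Z^t` with
   learnable layer weights `α_t`.

`M` is the per-gene *score* (a logit, can be negative); `σ(M)` is the
driver probability used in the masked binary cross-entropy loss over
labeled genes.  Training is full-graph Adam.  A diagnostic energy
functional `E = ‖Z − Z^t‖_F² + ω Σ_{ij} κ(‖z_i − z_j‖²)` can be logged
per layer to monitor the diffusion-toward-equilibrium view of the
encoder.  The four architecture components (diffusion attention, graph
convolution, residual, multi-layer readout) can each be disabled by a
configuration flag for ablation studies.

There is no external autodiff dependency: gradients come from a small
reverse-mode engine in `ecdcdgi.autodiff`, validated against finite
differences in the test suite.

## Worked example

```python
import numpy as np
from ecdcdgi import SyntheticSpec, generate, ModelConfig, cross_validate

# 600 genes on a preferential-attachment graph; 58 features of which 8
# carry a unit mean shift for positives; 300 labeled genes, 40% positive.
graph = generate(SyntheticSpec(seed=7))
report = cross_validate(graph, ModelConfig(), k=5, repeats=1, seed=7)
print(f"AUC  {report.auc_mean:.4f} +/- {report.auc_std:.4f}")
print(f"AUPR {report.aupr_mean:.4f} +/- {report.aupr_std:.4f}")
```

prints

```
AUC  0.9356 +/- 0.0181
AUPR 0.9212 +/- 0.0151
```

i.e. with the default configuration (d=100, 4 layers, 100 Adam epochs at
learning rate 0.001) the model recovers the planted signal almost
perfectly: a random held-out driver outscores a random held-out
non-driver ~94% of the time, and the precision–recall area is far above
the 0.4 positive-prevalence baseline.

The same pipeline is available from the shell:

```sh
ecd-cdgi simulate --out-dir data --seed 7
ecd-cdgi crossval --edges data/edges.tsv --features data/features.tsv \
    --labels data/labels.tsv --out report.json
ecd-cdgi train   --edges data/edges.tsv --features data/features.tsv \
    --labels data/labels.tsv --out model.npz --log train.jsonl --log-energy
ecd-cdgi predict --model model.npz --edges data/edges.tsv \
    --features data/features.tsv --out predictions.tsv
```

`predictions.tsv` ranks every gene (labeled and unlabeled) by driver
probability; `ecd-cdgi rank-merge` merges rankings from several networks
by mean rank, and `ecd-cdgi diagnose` prints the per-layer energy
trajectory of a forward pass.

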