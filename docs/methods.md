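# Methods

## Model

A cell's measured expression `X ∈ R^m` is modelled through `n < m` latent
gene modules. The modules form a linear-Gaussian structural causal model: a
directed acyclic graph with weight matrix `A` (entry `A[i, j]` is the effect
of module `j` on module `i`, nonzero only on the graph mask), exogenous noise
`Z` with unit scale (the module scale is arbitrary, so `σ_i = 1` by
convention), and — under perturbation `p` — an additive shift `c_p S_p`:

```
U = A U + Z + c_p S_p    ⇔    U = (I − A)^{-1} (Z + c_p S_p).
```

The observational (control) model is the special case `S = 0`. Because the
system is linear, an intervention displaces the latent state by exactly
`c_p (I − A)^{-1} S_p`, independent of `Z`; penetrance scales displacement
linearly. The solver exploits this superposition wherever a displacement is
needed (embeddings, penetrance sweeps), so linearity in `c` holds to the
floating-point bit, not just to tolerance.

Four neural components surround the SCM:

* **expression encoder** `X → q(Z|X)`, a diagonal Gaussian with MLP-computed
  mean and log-variance; prior `p(Z) = N(0, I_n)`;
* **shift encoder** mapping a perturbation label to `S_p ∈ R^n`. The label of
  a perturbation targeting gene `g` is gene `g`'s score vector on the top-k
  principal axes of the (genes × control cells) expression matrix. Labels
  exist for every gene on the panel, which is what allows generalisation to
  unseen targets;
* **decoder** `U → X̂`;
* learnable scalar penetrances `c_p` (initialised at 1) for training
  perturbations.

Graph modes: `learned_full_triangular` (all strictly-upper-triangular weights
trainable; the default), `fixed_adjacency` (user-supplied DAG),
`random_dag` (seeded random DAG; an ablation), and `none_conditional`
(`A ≡ 0`; the conditional-VAE ablation, identical to a causal model with an
empty frozen graph — asserted in tests). Masks are re-projected after every
optimizer step, so off-pattern weights are exactly zero at all times. Cyclic
adjacencies are rejected at the interface.

## Loss

```
L = recon + β · KL(q(Z|X) ‖ N(0, I)) + γ · mean_{p≠control} MMD²(X^p, X̂^p)
```

* `recon`: per-gene mean squared error, averaged over cells, then over
  conditions (control included). Perturb-seq offers no natural pairing
  between a perturbed cell and the control cell whose `Z` seeds its
  prediction, so each perturbed cell is paired with a uniformly resampled
  control cell per batch; the MMD term carries the distribution-level match.
* KL is averaged over control cells only; MMD over non-control conditions
  only (the control likelihood is handled by the variational bound, the
  perturbed distributions by MSE + MMD).
* The MMD penalty is the biased V-statistic of squared MMD with an RBF
  kernel, bandwidth by median heuristic on the pooled batch (treated as a
  constant for gradients).

**Choice of β and γ.** Defaults are `β = 0.01`, `γ = 50`. With a weak MMD
term the unpaired reconstruction term is minimised by predicting each
perturbation's *mean* for every cell, collapsing the predicted response
distribution (we observed predicted-cell standard deviations ~3% of truth).
`γ = 50` puts the distribution-matching term on the same scale as the
per-gene MSE at desk scale and restores calibrated output variance; `β` is
small because the KL is summed over latent dimensions while the
reconstruction is a per-gene mean. Both were fixed from a coarse sweep on the
synthetic scenario before any acceptance experiment was frozen, and both are
ordinary `TrainConfig` fields.

**Label-noise augmentation.** With only tens of training perturbations, an
MLP shift encoder memorises each label and interpolates arbitrarily between
them. During training the gene label is jittered with Gaussian noise (sd
`0.3 ×` the per-dimension label SD across genes, `TrainConfig.label_noise`),
which forces the encoder to be smooth in label space — the property that
makes unseen-gene labels land on sensible shifts. Inference is deterministic;
identical labels always produce identical shifts.

## Training protocol

Adam (lr `1e-3`), seeded end to end; identical config and data reproduce
identical weights bit for bit. Each batch draws control cells plus
`batch_perturbations` sampled conditions with `cells_per_condition` cells
each (default 32–48; kernel two-sample terms degrade below ~16 cells per
condition). The checkpoint with the lowest validation total loss is kept;
early stopping after `patience = 10` non-improving epochs.
`hyperparameter_search` evaluates a config grid by validation loss and never
accepts a test split.

Splits: in-distribution = per-condition 70/10/20 cell split (controls are one
condition). Out-of-distribution = the perturbation set is shuffled once by
the seed and partitioned into `total_splits` groups; group `split_index`
contributes *all* its cells to the test set, every remaining condition —
controls included — splits 85/15 into train/val. Across the rotating indices
every perturbation is tested exactly once. OOD test partitions deliberately
contain no control cells; prediction and baselines for held-out perturbations
encode training controls, which are never "unseen".

Perturbation filtering keeps conditions with at least `min_cells` cells
(default 200) whose cells an L2-regularised logistic regression separates
from an equal-size control subsample with mean stratified 5-fold CV accuracy
above 0.6. Balancing the classes makes 0.5 the chance level; the exact
classifier behind the published screens' filter is not public, so these
details are configurable.

## Penetrance selection for unseen perturbations

Given a pseudo-bulk target for unseen target `q`: encode `B = 64` control
cells, compute the unit latent displacement `(I − A)^{-1} S_q` once, and for
each grid candidate `c` decode `U_0 + c · dU` and score the MSE between the
predicted per-gene mean and the target. The same cells are reused across
candidates, and — by default — cells are generated from posterior means
without reparameterisation noise: only the mean of the predicted population
enters the comparison, and suppressing sampling noise (the same device the
model uses for latent embeddings) keeps the argmin stable on flat MSE
valleys. Ties break toward smaller `|c|` (closer to control). The default
grid spans the learned `c_p` range padded ±20% with 41 points; because
learned penetrances can cluster near their 1.0 initialisation (only the
product `c_p S_p` is identified), recovery experiments use an explicit grid
over `[−1, 3]`, the range swept in the penetrance analyses.

## Synthetic data generator

The generator states a fully identified world for recovery tests. Defaults:
`m = 200` genes, `n_true = 16` modules wired by a strictly upper-triangular
`A_true` with edge probability 0.3 and weights in `[−0.8, 0.8]`; 20
perturbations; 300 cells per condition; observation noise sd 0.1; true
penetrances cycling through `{0.5, 1, 2}`.

Read-out design (the part the stated world leaves open): every gene loads
~1.0 on one *dominant* module plus small dense background loadings (sd 0.1)
— genes belong to co-expression modules, as in real screens. A perturbation
of gene `g` shifts `g`'s dominant module negatively (knock-down semantics),
with a half-weight second module for every other perturbation (1- or
2-sparse shifts). The 20 target genes cover 10 modules, two genes per
module, so a held-out perturbation always has an in-training functional
neighbour. This is what makes out-of-distribution generalisation from PCA
gene labels possible *at all*: if unseen targets shared no regulatory
structure with seen ones, no method could extrapolate.

What a green synthetic test does **not** establish: the generator is
linear-Gaussian at the module level with additive Gaussian observation noise.
Real Perturb-seq data are counts with zero inflation, batch structure,
off-target effects and non-additive regulation; performance there is an
empirical question the synthetic suite cannot answer.

## Metrics

Per perturbation, on all genes and on its top-50 highly variable genes
(variance ranked on the perturbation's ground-truth cells; ties to lower
index): pseudo-bulk MSE and Pearson r between per-gene mean vectors; MMD
(square root of the biased RBF V-statistic, median-heuristic bandwidth —
reported on the metric scale, while the training penalty uses the squared
statistic); energy distance (V-statistic, Euclidean); fractions of genes
moved from control in the same/opposite direction as truth, with genes whose
predicted or true displacement is within `1e-6` counted in neither fraction.
Aggregation is mean ± population SD across perturbations. Both two-sample
estimators are validated against O(N²) double-loop references.

## Numerical choices

* Everything runs in float64 on a small in-repo reverse-mode autodiff engine
  (no deep-learning framework dependency); gradients, including the custom
  SCM-solve adjoint, are verified against central finite differences.
* The SCM solve materialises `(I − A)^{-1}` once per batch (n ≤ a few
  hundred) rather than iterating; the Neumann series and topological forward
  substitution serve as independent oracles in tests only.
* Degenerate kernels (all pooled points identical) fall back to bandwidth
  1.0 with a warning; zero-variance mean vectors make Pearson r undefined
  (reported as NaN).
* `A` initialises at `N(0, 0.01²)` on the free pattern — training starts
  near the conditional model and lets regulation emerge.

## Known limitations

* Gaussian output likelihood (MSE); no count / zero-inflated negative
  binomial head.
* Single-gene perturbations only; no combinatorial labels.
* Acyclic graphs only; feedback loops are rejected.
* No causal-structure discovery: pre-specified graphs are consumed as input.
* Learned penetrances are identifiable only up to the `c_p S_p` product;
  comparisons of `c` values are meaningful within one trained model.
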