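# Methods

## Problem and model

PIWI-clade Argonaute proteins (mouse MILI and MIWI, among others) cleave RNA
targets under the guidance of a bound piRNA. High-throughput in vitro assays
(Cleave-'N-Seq style) measure, for one guide-loaded complex, the
pre-steady-state cleavage rate `k` of thousands of target variants that differ
from the perfect complement by defined mismatches, deletions and insertions.
`piwislice` learns the regression `f(guide, duplex geometry) -> k̂` from such
tables and exposes per-position attributions of the learned rule.

The predictor operates on an interaction-centric encoding of the guide-target
duplex. For a guide of length L (default 26), each position i carries an
11-dimensional feature vector `X_i = [G_i, m_i, e_i, d_i]`:

* `G_i ∈ {0,1}^4` — guide nucleotide one-hot (channel order A, C, G, U);
* `m_i ∈ {0,1}^2` — canonical match mode, separating A-U (two hydrogen
  bonds) from C-G (three);
* `e_i ∈ {0,1}^4` — the identity of the target nucleotide at a mismatch,
  which is what lets the model distinguish a near-neutral G-U wobble from a
  destabilizing purine-purine clash;
* `d_i ∈ {0,1}` — deletion flag (guide position with no paired target base).

A separate binary vector `I ∈ {0,1}^{L+1}` flags insertion boundaries (slot 0
is 5' of g1; slot j is immediately 3' of guide position j; multiple inserted
bases at one boundary collapse to a single flag — inserted-base identity is
not encoded). At every position exactly one of match/mismatch/deletion is
active; a G-U wobble is always a mismatch, never a match.

The network is

    h_i   = W_G X_i + b_G              per-position projection to R^d, d = 16
    h_i  += p_i                        learnable positional embedding
    H     = ReLU(Conv1d(H, d filters, kernel 3))   length-preserving, zero-padded
    H     = AttentionStack(H)          3 post-norm blocks, 4 heads,
                                       feed-forward width 4d, dropout 0.1
    z     = W_I I + b_I                insertion embedding, d' = 8
    k̂    = W_2 ReLU(W_1 [Flatten(H) ‖ z] + b_1) + b_2    hidden width 64

The convolution captures local motifs (contiguous pairing around the
catalytic core g9-g11); the attention stack propagates distal perturbations
(a bulge at g15 affecting the core); the insertion branch keeps bulge
information from being washed out of the positional features. Predictions
live in z-score-normalized rate space; the training layer owns the moments
and denormalizes before reporting raw-rate errors.

Four ablation variants share the machinery: `no_position` (no positional
table), `pure_cnn` (no attention stack; the convolution output is flattened
directly), `simple_pairing` (m/e collapsed to one binary match flag;
per-position width 6), `no_insert` (insertion branch removed).

### Autodiff engine

No autodiff framework is assumed: `piwislice.autodiff` is a compact tape-based
reverse-mode engine over numpy arrays providing exactly the operations the
network needs (broadcast arithmetic, batched matmul, reductions, shape ops,
ReLU/abs, fused softmax, layer norm, 1D convolution, dropout). It yields exact
gradients with respect to both parameters (training) and inputs (saliency);
its tests check every operation against central finite differences. Default
dtype is float32; `use_dtype(np.float64)` exists for tight numeric checks.
Because small-matrix BLAS kernels are not bit-stable across row positions,
"same seed, same result" holds bit-exactly for repeated identical runs, and to
float round-off across batch compositions.

## Training

The loss is `α·MAE + (1−α)·(1−PCC)` with α = 0.8: MAE anchors quantitative
accuracy, the Pearson term preserves the ranking of variants. Inside the loss,
means/SDs are population moments with a 1e-8 guard on each SD, so a
constant-prediction batch is maximally penalized instead of NaN; reported
metrics use the sample Pearson correlation. Optimization is AdamW (lr 1e-4,
weight decay 0.1), batch size 128 (last incomplete batch kept, a singleton
merged into the previous batch so the Pearson term stays defined), with the
learning rate halved after 5 epochs without validation-loss improvement and
early stop below lr 1e-6. `max_epochs` defaults to 200; the convergence of
interest on the synthetic benchmarks happens well before that, and the timed
tests and the acceptance script use 50 epochs as their problem size.

Rates are z-score normalized with moments fitted on training records only
(population SD); evaluation MAE is computed on denormalized predictions (PCC
is affine-invariant, so normalization affects MAE only).

**Protocols.** Leave-one-guide-out (LOGO) cross-validation holds out one guide
with all its variants per fold, testing generalization to unseen guides. Per
fold, a random 10% of the fold's training records forms an inner validation
set; the best epoch minimizes validation MAE there, and the final model is
retrained on the fold's full training set for that many epochs, replaying the
recorded learning-rate trajectory. A pooled "mixed" protocol (random 75/25
record split) complements it. Repeated-seed score pairs are compared with
two-sided paired t-tests (all-zero differences report p = 1; zero-variance
nonzero differences report a divergent t and p = 0, stated explicitly).

**Baselines.** Classic regressors (kNN, ridge, random forest, extra trees,
bagging, AdaBoost, gradient boosting, XGBoost, and two MLP variants — one
hidden layer of 100, and 64×64) from scikit-learn/xgboost run on four
encodings: the flattened interaction features (length 11L + L + 1), the
binary-match simplification (6L + L + 1), concatenated guide/target one-hots,
and k-mer counts (k = 3 by default; deletions contribute no base to the
implied target and insertions are unknown by construction). A fifth encoding
(`cnn_embed`) feeds the regressor the global-max-pooled activations of a
small convolutional extractor (16 filters, width 3) trained end-to-end as a
tiny rate regressor on the stacked guide/target one-hot.

## Interpretability

* Saliency: `S_i = E_batch[Σ_c |∂k̂/∂G_ic|]` — plain absolute gradients with
  respect to the four guide one-hot channels, no gradient-times-input or
  smoothing, computed in normalized-rate space on the evaluation set by
  default (a flag selects another set).
* Counterfactual impact: over records with a mismatch at i, `Δ_i` is the mean
  prediction change when the mismatch is replaced by the perfect Watson-Crick
  match (E row zeroed; M channel chosen from the guide base, since the
  perfect-complement target base is determined by the guide). Positive `Δ_i`
  means the mismatch was deleterious. Deletions are a distinct intervention
  and get a separate optional profile (`deletion_profile`), never pooled into
  `Δ_i`. Positions with no supporting records are missing (NA), never 0.
* Profiles across repeated-seed models aggregate as mean ± SD. Reports label
  guide regions: g1 (5' anchor buried in the MID domain), g2-g8 (seed,
  relaxed for PIWI), g9-g11 (catalytic core), g12-g15 (central), g16+ (3').

## Synthetic benchmark generator

The generator emulates the shape of a CNS-seq variant library: per guide, the
perfect complement, all three single mismatches at every scan position
(g2-g20 by default), all 3×3 consecutive double mismatches, single deletions,
single insertions, and replicate perfect-match records — about 250 records
per guide, about 1,000 for the default 4-guide benchmark. Rates follow a
multiplicative law on k (additive on log k):

    log k = β₀ − Σ_mismatch w_i·mtype[g_i, t_i] − Σ_deletion w_i·δ − n_ins·ι + ε

with ε ~ N(0, σ). Defaults: β₀ = 0; position weights `w` follow the known
positional hierarchy (low g1, intermediate seed, maximal g9-g11, decay to
near-zero from g16), amplitude 1.5 with a ±3% seeded jitter; mismatch-type
multipliers drawn in [0.7, 1.4] with G-U/U-G wobbles fixed at 0.3 (the
`wobble_sensitive` profile widens this to [0.9, 1.8] vs 0.05, and `flat`
makes `w` constant as a negative control); deletion multiplier 1.5, insertion
penalty 0.8 per flagged boundary, σ = 0.2 — large enough to make the task
nontrivial, small enough that the positional signal is recoverable at the
default library size. A multiplicative law was chosen because rates are
positive and mismatch effects present as rate reductions; no claim is made
that it is the true biochemical law. An optional per-guide relative
perturbation of `w` emulates guide-specific deviations.

Because the law is linear in the flattened interaction features (per guide),
ordinary least squares on noiseless data recovers every penalty product
exactly — the brute-force oracle that grounds the network's recovery tests
independently of the network.

### Validation experiments and their problem sizes

Two experiments anchor the heavy end of the test suite and the acceptance
script, with sizes chosen to run in minutes on one CPU:

* **Positional recovery** — LOGO-CV of the full model on the default 4-guide
  benchmark (~1,000 records), 3 seeds, 50 epochs, best-epoch selection on the
  inner validation split (without the final full-train refit, which the
  library implements and defaults to but which roughly doubles runtime for a
  marginal change on this benchmark). Checked: held-out-guide PCC, and the
  Spearman rank correlation between the aggregated counterfactual profile and
  the generator's true position weights.
* **Ablation ordering** — the `wobble_sensitive` rule on the pooled 75/25
  protocol (4 guides, default library with 20 insertion variants per guide),
  3 seeds, 60 epochs: full encoding vs the binary `simple_pairing`
  simplification, and vs `no_insert`. The pooled protocol is used here
  deliberately: distinguishing mismatch *types* requires either many guides
  or within-guide evidence. With only a handful of guides, a model trained
  under LOGO can fit per-position type shortcuts that match the training
  guides exactly, and the inner validation (drawn from the same guides)
  cannot penalize them — so on an unseen guide the identity-aware encoding
  carries extra variance without payoff, and the comparison is
  uninformative. On pooled held-out records the ordering is clean and
  consistent across seeds. Resolving the same ordering under LOGO would need
  guide diversity well beyond desk scale.

What the generator does not emulate: the kinetic time-course fitting that
produces `k` upstream (and its heteroscedastic errors), sequence-context
effects beyond per-position additivity, inserted-base identity, and the
dynamic-range structure of real assays. Passing recovery tests therefore
demonstrates that the pipeline can learn and attribute a position- and
type-dependent rule of realistic shape from realistic library sizes — not
that it reproduces any particular measured dataset.

## Numerical choices and edge cases

* Convolution uses zero padding of width (kernel−1)/2, preserving length L.
* Initialization: uniform ±1/√fan_in for linear/conv weights, zeros for
  biases, N(0, 0.02) for the positional table; all draws from one seeded
  generator, so a (config, seed) pair rebuilds bit-identical parameters.
* Attention blocks are post-norm with residual connections; head width d/4.
* Guides with fewer than 2 records yield an undefined (NaN) fold PCC,
  reported as missing rather than fabricated; zero-variance prediction
  vectors likewise give NaN PCC in reports (but a guarded, finite loss).
* Checkpoints serialize config + parameters + normalization moments to one
  `.npz` and round-trip exactly.
* Human-facing positions are 1-based g-notation; internal indices 0-based;
  insertion slots 0-based 0..L everywhere.

## Known limitations

* The engine is CPU-only numpy; fine for the ~39k-parameter default model,
  not for large-scale retraining.
* The pairing-text dialect describes one guide-coordinate duplex per record;
  it cannot express multi-nucleotide insertion identity (deliberately, since
  the encoding does not either).
* With very few guides, LOGO generalization depends on the shared rule
  assumption of the generator; real guide-specific idiosyncrasies are only
  emulated through the optional per-guide weight perturbation.
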