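# piwislice

Predicting PIWI-mediated RNA cleavage rates from guide-target duplex geometry.

PIWI-clade Argonaute proteins (e.g. mouse MILI and MIWI), guided by a bound
piRNA, cleave complementary RNA targets with striking tolerance for imperfect
pairing: mismatches are forgiven almost anywhere as long as the catalytic core
(guide positions g9-g11) pairs, while the 5'-anchored g1 and the 3' tail
contribute little. High-throughput in vitro assays measure the pre-steady-state
cleavage rate `k` of thousands of target variants of a single guide — perfect
complements, systematic single and double mismatches, deletions, insertions —
but each new guide-protein pair costs a full wet-lab campaign.

`piwislice` is for computational biologists who have such cleavage tables (or
want to simulate them) and need a quantitative, interpretable model of the
cleavage rule. It learns a regression

    k̂ = f(guide sequence, duplex pairing geometry)

with an interaction-centric encoding — per guide position: the guide base
(one-hot), the canonical match mode (A-U vs C-G), the identity of a mismatched
target base (so a mild G-U wobble is distinguishable from an A-A clash), a
deletion flag, plus insertion-boundary flags — fed through a position-aware
hybrid network: learnable positional embeddings, a 1D convolution for local
motifs, a multi-head attention stack for distal effects, and a dense head.
Training minimizes `0.8·MAE + 0.2·(1 − PCC)` on z-score-normalized rates, and
evaluation follows leave-one-guide-out cross-validation (every fold holds out
one guide with all of its variants). Two attribution tools read the learned
rule back out: gradient saliency `S_i` per guide position, and the
counterfactual mismatch impact `Δ_i` (mean predicted-rate change when a
mismatch at i is repaired to the perfect match).

A synthetic benchmark generator emulates the variant-library shape of the real
assays with a known parametric ground-truth law, so the whole pipeline —
encoding, training, cross-validation, ablations, attribution — is testable by
parameter recovery without any external download. See `docs/methods.md` for
the model, the generator law, and all numerical conventions.

## Worked example

```python
import numpy as np
from piwislice import CleavageRateModel, TrainConfig, simulate

# four synthetic guides, ~250 target variants each, known ground-truth rule
data, rule = simulate.generate_benchmark(n_guides=4, seed=1)

results = CleavageRateModel(data, train_config=TrainConfig(max_epochs=50)).fit(seed=0)
print(results.summary())
```

```
Cleavage-rate regression results
================================================
records (train/val):    904/100
guides:                 4
guide length L:         26
architecture:           d=16, conv 16x3, 3 attention layers x 4 heads
ablation:               none
parameters:             38721
seed:                   0
epochs run/best:        50/46
rate normalization:     mean=0.4064, sd=0.2757
------------------------------------------------
validation PCC:         0.7673
validation MAE (raw k): 0.1107
```

A validation PCC of about 0.77 means the model ranks unseen variants' cleavage
rates well despite the generator's log-normal noise; the MAE is in the raw
units of `k`. Generalization to unseen *guides* — the harder, scientifically
relevant test — uses the leave-one-guide-out protocol:

```python
logo = CleavageRateModel(data, train_config=TrainConfig(max_epochs=50)).fit_logo(seeds=[0])
print(logo.to_frame().round(3))          # one row per held-out guide
delta = logo.counterfactual()            # per-position mismatch impact, mean ± SD
```

On this benchmark each held-out guide reaches PCC ≈ 0.7, and the counterfactual
profile `Δ_i` rises from a negligible g1, through an intermediate seed, peaks
at the catalytic core g9-g11 and decays toward the 3' end — recovering the
position weights the generator planted (Spearman rank correlation ≥ 0.8).

The same workflows are scriptable from a shell:

```
piwislice simulate --n-guides 4 --seed 1 --out-dir sim/
piwislice crossval --data sim/dataset.tsv --mode logo --seeds 0,1,2 --out-dir cv/
piwislice train    --data sim/dataset.tsv --seed 0 --out-dir run/
piwislice explain  --data sim/dataset.tsv --checkpoint run/checkpoint.npz \
                   --kind counterfactual --out-dir profiles/
piwislice benchmark --data sim/dataset.tsv --out-dir grid/   # classic-regressor grid
```

Input tables are TSV with columns `guide_id`, `guide_seq`, `pairing`, `k`,
where `pairing` uses a run-length dialect (`M*9,X:U,M*16` = mismatch with
target U at g10; `D` = deletion; `|ins:20` flags an insertion boundary).

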