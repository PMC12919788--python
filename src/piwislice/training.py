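"""Training objective, optimization loop, cross-validation and baselines.

The objective is a composite of mean absolute error and a Pearson-correlation
term, ``alpha * MAE + (1 - alpha) * (1 - PCC)`` with ``alpha = 0.8`` by
default: MAE anchors quantitative rate accuracy, the Pearson term preserves
rank consistency across variants. Rates are z-score normalized with moments
fitted on training records only; reported MAE is always on denormalized
(raw-rate) predictions, and PCC is affine-invariant so normalization does not
affect it.

Evaluation follows leave-one-guide-out cross-validation (LOGO-CV): every fold
holds out one guide RNA with all of its target variants, testing
generalization to unseen guides. A pooled "mixed" protocol (random 75/25
record split) is also provided. Optimization uses AdamW with a
reduce-on-plateau learning-rate schedule; repeated runs over seeds are
compared with paired t-tests.

Conventions: the Pearson term inside the loss uses population standard
deviations with a 1e-8 guard (a constant prediction batch is maximally
penalized rather than NaN); reported metrics use the sample Pearson
correlation. Mini-batches keep the last incomplete batch, merging a would-be
singleton into the previous batch so the Pearson term stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .autodiff import Tensor, zero_grads
from .data import CleavageDataset
from .encoding import (
    GuideSequence,
    PairingSpec,
    StateKind,
    COMPLEMENT,
    encode_kmer,
    flatten_interaction,
    one_hot,
)
from .network import InteractionRegressor, ModelConfig, build_model

EPS_SD = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    alpha: float = 0.8
    lr: float = 1e-4
    weight_decay: float = 0.1
    batch_size: int = 128
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    max_epochs: int = 200
    min_lr: float = 1e-6
    n_seeds: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (Pearson term needs >= 2 points)")


# ---------------------------------------------------------------------------
# loss and normalization
# ---------------------------------------------------------------------------

def composite_loss(k: np.ndarray, khat: np.ndarray, alpha: float = 0.8) -> float:
    """alpha * MAE + (1 - alpha) * (1 - PCC), population moments, eps-guarded."""
    k = np.asarray(k, dtype=float)
    khat = np.asarray(khat, dtype=float)
    if k.shape != khat.shape:
        raise ValueError(f"length mismatch: {k.shape} vs {khat.shape}")
    if k.size < 2:
        raise ValueError("composite loss needs at least 2 points")
    mae = np.mean(np.abs(k - khat))
    cov = np.mean((k - k.mean()) * (khat - khat.mean()))
    pcc = cov / ((k.std() + EPS_SD) * (khat.std() + EPS_SD))
    return float(alpha * mae + (1.0 - alpha) * (1.0 - pcc))


def composite_loss_t(k: Tensor, khat: Tensor, alpha: float = 0.8) -> Tensor:
    """Differentiable composite loss (identical formula to :func:`composite_loss`)."""
    mae = (k - khat).abs().mean()
    kc = k - k.mean()
    pc = khat - khat.mean()
    cov = (kc * pc).mean()
    sd_k = (kc * kc).mean().sqrt() + EPS_SD
    sd_p = (pc * pc).mean().sqrt() + EPS_SD
    pcc = cov / (sd_k * sd_p)
    return alpha * mae + (1.0 - alpha) * (1.0 - pcc)


@dataclass(frozen=True)
class NormalizationParams:
    """z-score moments of k, fitted on training records only (population SD)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise ValueError("normalization needs nonconstant training rates (sd > 0)")

    def apply(self, k: np.ndarray) -> np.ndarray:
        return (np.asarray(k, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def normalize_rates(train_k: Sequence[float]) -> NormalizationParams:
    k = np.asarray(train_k, dtype=float)
    if k.size < 2:
        raise ValueError("need at least 2 training rates")
    return NormalizationParams(mean=float(k.mean()), sd=float(k.std()))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Pearson correlation and raw-rate MAE on one evaluation set."""

    pcc: float  # NaN when undefined (zero variance or n < 2)
    mae: float
    n: int
    per_seed_pcc: list[float] = field(default_factory=list)
    per_seed_mae: list[float] = field(default_factory=list)

    @property
    def pcc_defined(self) -> bool:
        return np.isfinite(self.pcc)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("evaluate needs two equal-length vectors of >= 2 points")
    mae = float(np.mean(np.abs(pred - truth)))
    if pred.std() == 0 or truth.std() == 0:
        return EvalResult(pcc=float("nan"), mae=mae, n=pred.size)
    pcc = float(stats.pearsonr(pred, truth).statistic)
    return EvalResult(pcc=pcc, mae=mae, n=pred.size)


def repeat_and_compare(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test over per-seed score pairs.

    All differences exactly zero -> (0, 1). Constant nonzero differences have
    zero variance; the t statistic diverges and p is reported as 0.0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired comparison needs two equal-length vectors of >= 2 scores")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    if diff.std() == 0:
        return float(np.sign(diff[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# optimizer and loop
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (bias-corrected moments)."""

    def __init__(self, params: Sequence[Tensor], lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float | None = None
    val_mae: float | None = None


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and len(batches[-1]) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _fit_loop(
    model: InteractionRegressor,
    X: np.ndarray,
    I: np.ndarray,
    y_norm: np.ndarray,
    tcfg: TrainConfig,
    seed: int,
    epochs: int,
    lr_schedule: Sequence[float] | None = None,
    val: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    norm: NormalizationParams | None = None,
) -> tuple[list[EpochRecord], dict[str, np.ndarray] | None, int]:
    """Run the optimization loop; returns (history, best state dict, best epoch).

    With ``val`` provided, tracks validation composite loss (scheduler) and
    raw-rate validation MAE (best-epoch selection) each epoch. With
    ``lr_schedule`` provided, the per-epoch learning rate is replayed from it
    instead (used for final retraining on the full fold training set).
    """
    rng = np.random.default_rng(seed)
    params = model.parameters()
    opt = AdamW(params, lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    history: list[EpochRecord] = []
    best_mae = np.inf
    best_state: dict[str, np.ndarray] | None = None
    best_epoch = 0
    best_val_loss = np.inf
    stale = 0
    for epoch in range(1, epochs + 1):
        if lr_schedule is not None:
            opt.lr = lr_schedule[min(epoch - 1, len(lr_schedule) - 1)]
        losses = []
        for idx in _batches(len(y_norm), tcfg.batch_size, rng):
            pred = model.forward(Tensor(X[idx]), Tensor(I[idx]), training=True, rng=rng)
            loss = composite_loss_t(Tensor(y_norm[idx]), pred, alpha=tcfg.alpha)
            zero_grads(params)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        rec = EpochRecord(epoch=epoch, lr=opt.lr, train_loss=float(np.mean(losses)))
        if val is not None:
            Xv, Iv, yv_raw = val
            pred_v = model.forward(Tensor(Xv), Tensor(Iv)).data
            yv_norm = norm.apply(yv_raw)
            rec.val_loss = composite_loss(yv_norm, pred_v, alpha=tcfg.alpha)
            rec.val_mae = float(np.mean(np.abs(norm.invert(pred_v) - yv_raw)))
            if rec.val_mae < best_mae:
                best_mae = rec.val_mae
                best_state = model.state_dict()
                best_epoch = epoch
            # reduce-on-plateau on the validation composite loss
            if rec.val_loss < best_val_loss - 1e-12:
                best_val_loss = rec.val_loss
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.scheduler_patience:
                    opt.lr *= tcfg.scheduler_factor
                    stale = 0
        history.append(rec)
        if opt.lr < tcfg.min_lr:
            break
    return history, best_state, best_epoch


def train_model(
    train: CleavageDataset,
    val: CleavageDataset,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    seed: int,
) -> tuple[InteractionRegressor, NormalizationParams, list[EpochRecord], int]:
    """Train a predictor; returns the best-validation-MAE parameters.

    Normalization moments are fitted on the training records only. Returns
    (model carrying best-epoch parameters, normalization, history, best epoch).
    """
    if len(val) < 2:
        raise ValueError("validation set needs at least 2 records for PCC/MAE")
    norm = normalize_rates(train.rates)
    model = build_model(mcfg, seed=seed)
    X, I = model.batch_inputs(train.encodings())
    Xv, Iv = model.batch_inputs(val.encodings())
    history, best_state, best_epoch = _fit_loop(
        model, X, I, norm.apply(train.rates), tcfg, seed=seed, epochs=tcfg.max_epochs,
        val=(Xv, Iv, val.rates), norm=norm,
    )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, norm, history, best_epoch


def predict_rates(model: InteractionRegressor, data: CleavageDataset, norm: NormalizationParams) -> np.ndarray:
    """Raw-rate predictions for a dataset."""
    return norm.invert(model.predict(data.encodings()))


def split_train_val(
    data: CleavageDataset, val_fraction: float, seed: int
) -> tuple[CleavageDataset, CleavageDataset]:
    """Random record-level split (seeded); validation gets >= 2 records."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_val = max(2, int(round(val_fraction * len(data))))
    return data.subset(order[n_val:]), data.subset(order[:n_val])


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    guide_id: str
    result: EvalResult
    best_epoch: int
    model: InteractionRegressor
    norm: NormalizationParams
    test_indices: list[int]


def leave_one_guide_out(
    data: CleavageDataset,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    seed: int = 0,
    retrain: bool = True,
) -> dict[str, FoldResult]:
    """LOGO-CV: one fold per guide id, the held-out guide absent from training.

    Per fold, a random ``val_fraction`` of the fold's training records serves
    as the inner validation set for best-epoch selection and the plateau
    scheduler; with ``retrain`` the model is then retrained on the fold's full
    training set for the selected number of epochs, replaying the recorded
    learning-rate trajectory. Folds of guides with < 2 records report an
    undefined (NaN) PCC rather than a fabricated one.
    """
    groups = data.guide_groups
    if len(groups) < 2:
        raise ValueError("LOGO-CV needs at least 2 distinct guide ids")
    results: dict[str, FoldResult] = {}
    for gid in sorted(groups):
        test_idx = groups[gid]
        train_idx = [i for i in range(len(data)) if data.records[i].guide.id != gid]
        fold_train = data.subset(train_idx)
        test = data.subset(test_idx)
        inner_train, inner_val = split_train_val(fold_train, tcfg.val_fraction, seed=seed)
        model, norm, history, best_epoch = train_model(inner_train, inner_val, mcfg, tcfg, seed=seed)
        if retrain and best_epoch > 0:
            norm = normalize_rates(fold_train.rates)
            model = build_model(mcfg, seed=seed)
            X, I = model.batch_inputs(fold_train.encodings())
            lr_schedule = [rec.lr for rec in history]
            _fit_loop(
                model, X, I, norm.apply(fold_train.rates), tcfg, seed=seed,
                epochs=best_epoch, lr_schedule=lr_schedule,
            )
        preds = predict_rates(model, test, norm)
        if len(test) >= 2:
            result = evaluate(preds, test.rates)
        else:
            result = EvalResult(pcc=float("nan"), mae=float(np.mean(np.abs(preds - test.rates))), n=len(test))
        results[gid] = FoldResult(
            guide_id=gid, result=result, best_epoch=best_epoch, model=model,
            norm=norm, test_indices=list(test_idx),
        )
    return results


def mixed_split(
    data: CleavageDataset, test_fraction: float = 0.25, seed: int = 0
) -> tuple[CleavageDataset, CleavageDataset]:
    """Pooled protocol: random record split across all guides (default 75/25)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_test = int(round(test_fraction * len(data)))
    return data.subset(order[n_test:]), data.subset(order[:n_test])


# ---------------------------------------------------------------------------
# classic-regressor baselines
# ---------------------------------------------------------------------------

ENCODING_KINDS = ("interaction", "simple_pairing", "concat_onehot", "kmer", "cnn_embed")
MODEL_KINDS = (
    "knn", "ridge", "random_forest", "extra_trees", "bagging",
    "adaboost", "gradient_boosting", "xgboost", "mlp", "ffnn",
)


def implied_target(guide: GuideSequence, spec: PairingSpec) -> str:
    """Reconstruct the target bases paired to the guide (guide coordinates).

    Matches map to the guide complement, mismatches to their recorded target
    identity; deleted positions contribute no base and inserted bases are
    unknown by construction, so both are omitted. Used only by the
    sequence-only baseline encodings.
    """
    out = []
    for g, state in zip(guide.nucleotides, spec.states):
        if state.kind is StateKind.MATCH:
            out.append(COMPLEMENT[g])
        elif state.kind is StateKind.MISMATCH:
            out.append(state.target)
    return "".join(out)


def _stacked_onehot(guide: GuideSequence, spec: PairingSpec) -> np.ndarray:
    """(L, 8) channel-stacked guide/target one-hot; deletions are zero rows."""
    L = len(guide)
    tgt = np.zeros((L, 4))
    nuc = "ACGU"
    for i, (g, state) in enumerate(zip(guide.nucleotides, spec.states)):
        if state.kind is StateKind.MATCH:
            tgt[i, nuc.index(COMPLEMENT[g])] = 1.0
        elif state.kind is StateKind.MISMATCH:
            tgt[i, nuc.index(state.target)] = 1.0
    return np.concatenate([one_hot(guide.nucleotides), tgt], axis=1)


def _cnn_embed_features(
    train: CleavageDataset, test: CleavageDataset, seed: int,
    n_filters: int = 16, width: int = 3, epochs: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Features from a small end-to-end-trained convolutional extractor.

    One conv layer (``n_filters`` filters, width ``width``) + ReLU + global
    max-pool over positions on the stacked guide/target one-hot, trained as a
    tiny regressor on the training rates; the pooled activations are then the
    features handed to the downstream classic regressor.
    """
    from .autodiff import conv1d, parameter

    Xtr = np.stack([_stacked_onehot(r.guide, r.spec) for r in train.records])
    Xte = np.stack([_stacked_onehot(r.guide, r.spec) for r in test.records])
    norm = normalize_rates(train.rates)
    y = norm.apply(train.rates)
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(8 * width)
    w = parameter(rng.uniform(-bound, bound, size=(n_filters, 8, width)))
    b = parameter(np.zeros(n_filters))
    w_out = parameter(rng.uniform(-0.1, 0.1, size=(n_filters, 1)))
    b_out = parameter(np.zeros(1))
    params = [w, b, w_out, b_out]
    opt = AdamW(params, lr=1e-2, weight_decay=0.0)

    def pooled(x: np.ndarray) -> Tensor:
        h = conv1d(Tensor(x), w, b).relu()
        # global max-pool over positions, differentiable via one-hot of argmax
        m = h.data.max(axis=1, keepdims=True)
        mask = Tensor((h.data == m) & (np.cumsum(h.data == m, axis=1) == 1))
        return (h * mask).sum(axis=1)

    for _ in range(epochs):
        for idx in _batches(len(y), 64, rng):
            feats = pooled(Xtr[idx])
            pred = (feats @ w_out + b_out).reshape(len(idx))
            loss = ((pred - Tensor(y[idx])) ** 2).mean()
            zero_grads(params)
            loss.backward()
            opt.step()
    return pooled(Xtr).data.copy(), pooled(Xte).data.copy()


def _baseline_features(
    kind: str, train: CleavageDataset, test: CleavageDataset, seed: int, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    if kind == "interaction":
        f = lambda r: flatten_interaction(r.encode())
    elif kind == "simple_pairing":
        f = lambda r: flatten_interaction(r.encode(), simple_pairing=True)
    elif kind == "concat_onehot":
        f = lambda r: _stacked_onehot(r.guide, r.spec).T.reshape(-1)
    elif kind == "kmer":
        f = lambda r: encode_kmer(r.guide, implied_target(r.guide, r.spec), k=k)
    elif kind == "cnn_embed":
        return _cnn_embed_features(train, test, seed=seed)
    else:
        raise ValueError(f"unknown encoding kind {kind!r}; choose from {ENCODING_KINDS}")
    return (
        np.stack([f(r) for r in train.records]),
        np.stack([f(r) for r in test.records]),
    )


def _make_regressor(kind: str, seed: int):
    from sklearn.ensemble import (
        AdaBoostRegressor, BaggingRegressor, ExtraTreesRegressor,
        GradientBoostingRegressor, RandomForestRegressor,
    )
    from sklearn.linear_model import Ridge
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.neural_network import MLPRegressor

    if kind == "knn":
        return KNeighborsRegressor(n_neighbors=5)
    if kind == "ridge":
        return Ridge(alpha=1.0, random_state=seed)
    if kind == "random_forest":
        return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "extra_trees":
        return ExtraTreesRegressor(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "bagging":
        return BaggingRegressor(n_estimators=50, random_state=seed, n_jobs=1)
    if kind == "adaboost":
        return AdaBoostRegressor(n_estimators=100, random_state=seed)
    if kind == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed)
    if kind == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(n_estimators=200, max_depth=4, random_state=seed, n_jobs=1, verbosity=0)
    if kind == "mlp":
        return MLPRegressor(hidden_layer_sizes=(100,), max_iter=500, random_state=seed)
    if kind == "ffnn":
        return MLPRegressor(hidden_layer_sizes=(64, 64), max_iter=500, random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def fit_baseline(
    encoding_kind: str,
    model_kind: str,
    train: CleavageDataset,
    test: CleavageDataset,
    seed: int = 0,
    k: int = 3,
    knn_k: int | None = None,
) -> EvalResult:
    """Fit a classic off-the-shelf regressor on a flattened encoding."""
    Xtr, Xte = _baseline_features(encoding_kind, train, test, seed=seed, k=k)
    norm = normalize_rates(train.rates)
    reg = _make_regressor(model_kind, seed=seed)
    if model_kind == "knn" and knn_k is not None:
        reg.set_params(n_neighbors=knn_k)
    reg.fit(Xtr, norm.apply(train.rates))
    preds = norm.invert(reg.predict(Xte))
    return evaluate(preds, test.rates)
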