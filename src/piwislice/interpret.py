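"""Position-wise interpretability: gradient saliency and counterfactual impact.

Two complementary probes of a trained predictor:

* **Gradient saliency** ``S_i``: the batch-averaged absolute gradient of the
  predicted (normalized) rate with respect to the four guide one-hot channels
  at position i, summed over channels. High S_i marks positions where small
  perturbations move the prediction most -- for PIWI, the catalytic core
  g9-g11.
* **Counterfactual mismatch impact** ``Delta_i``: over the records that carry
  a mismatch at position i, the mean change in predicted rate when that
  mismatch is replaced by the perfect Watson-Crick match (E row zeroed, the M
  channel set from the guide base), everything else held fixed. Positive
  Delta_i means the mismatch at i was deleterious. Deletions are a distinct
  intervention and are deliberately not pooled into Delta_i.

Both are plain gradients / plain prediction differences -- no gradient-times-
input, smoothing, or integration. Profiles from repeated-seed models are
aggregated as mean +/- SD. Positions with no supporting records are reported
as missing (NaN), never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data import CleavageDataset
from .encoding import InteractionEncoding, StateKind
from .network import InteractionRegressor


@dataclass
class PositionProfile:
    """Per-guide-position scores with optional dispersion and support counts."""

    scores: np.ndarray  # (L,); NaN = missing
    kind: str  # "saliency" or "counterfactual"
    dispersion: np.ndarray | None = None  # per-position SD across seeds/models
    support: np.ndarray | None = None  # per-position record count (|M_i|)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.kind == "saliency" and np.nanmin(self.scores) < 0:
            raise ValueError("saliency scores are absolute gradients and must be >= 0")

    @property
    def L(self) -> int:
        return len(self.scores)


def saliency_scores(
    model: InteractionRegressor, encodings: Sequence[InteractionEncoding]
) -> PositionProfile:
    """S_i = E_batch[ sum_d |d khat / d G_id| ] in normalized-rate space."""
    if not len(encodings):
        raise ValueError("saliency needs a nonempty batch")
    X_np, I_np = model.batch_inputs(encodings)
    X = Tensor(X_np, requires_grad=True)
    pred = model.forward(X, Tensor(I_np))
    # records are independent, so the gradient of the sum w.r.t. each record's
    # input equals that record's own prediction gradient
    pred.sum().backward()
    grad_G = X.grad[:, :, :4]  # guide one-hot channels lead the feature layout
    scores = np.abs(grad_G).sum(axis=2).mean(axis=0)
    return PositionProfile(scores=scores, kind="saliency")


def _match_substituted(enc: InteractionEncoding, i: int) -> InteractionEncoding:
    """Replace the pairing state at position i by the perfect Watson-Crick match."""
    M = enc.M.copy()
    E = enc.E.copy()
    guide_is_au = enc.G[i, 0] == 1 or enc.G[i, 3] == 1  # channels A, U
    E[i, :] = 0.0
    M[i, :] = 0.0
    M[i, 0 if guide_is_au else 1] = 1.0
    return InteractionEncoding(G=enc.G, M=M, E=E, D=enc.D, I=enc.I)


def counterfactual_profile(
    model: InteractionRegressor, data: CleavageDataset
) -> PositionProfile:
    """Delta_i = mean over mismatch-at-i records of (matched - original) prediction."""
    if model.config.ablation == "simple_pairing":
        raise ValueError(
            "counterfactual mismatch impact needs the full pairing encoding, "
            "not the binary simple_pairing ablation"
        )
    if len(data) == 0:
        raise ValueError("counterfactual analysis needs a nonempty dataset")
    L = model.config.L
    encodings = data.encodings()
    base_preds = model.predict(encodings)
    scores = np.full(L, np.nan)
    support = np.zeros(L, dtype=int)
    for i in range(L):
        members = [j for j, rec in enumerate(data.records) if rec.spec.states[i].kind is StateKind.MISMATCH]
        if not members:
            continue
        matched = [_match_substituted(encodings[j], i) for j in members]
        deltas = model.predict(matched) - base_preds[members]
        scores[i] = float(deltas.mean())
        support[i] = len(members)
    return PositionProfile(scores=scores, kind="counterfactual", support=support)


def deletion_profile(model: InteractionRegressor, data: CleavageDataset) -> PositionProfile:
    """Optional companion analysis: impact of replacing a deletion by a match."""
    if len(data) == 0:
        raise ValueError("deletion analysis needs a nonempty dataset")
    L = model.config.L
    encodings = data.encodings()
    base_preds = model.predict(encodings)
    scores = np.full(L, np.nan)
    support = np.zeros(L, dtype=int)
    for i in range(L):
        members = [j for j, rec in enumerate(data.records) if rec.spec.states[i].kind is StateKind.DELETION]
        if not members:
            continue
        matched = []
        for j in members:
            enc = encodings[j]
            M = enc.M.copy()
            D = enc.D.copy()
            guide_is_au = enc.G[i, 0] == 1 or enc.G[i, 3] == 1
            D[i] = 0.0
            M[i, 0 if guide_is_au else 1] = 1.0
            matched.append(InteractionEncoding(G=enc.G, M=M, E=enc.E, D=D, I=enc.I))
        deltas = model.predict(matched) - base_preds[members]
        scores[i] = float(deltas.mean())
        support[i] = len(members)
    return PositionProfile(scores=scores, kind="counterfactual_deletion", support=support)


def aggregate_profiles(profiles: Sequence[PositionProfile]) -> PositionProfile:
    """Mean +/- SD across repeated-seed models (NaN-aware; support summed)."""
    if not profiles:
        raise ValueError("nothing to aggregate")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise ValueError(f"cannot aggregate mixed profile kinds {kinds}")
    stack = np.stack([p.scores for p in profiles])
    support = None
    if all(p.support is not None for p in profiles):
        support = np.stack([p.support for p in profiles]).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        # all-NaN positions (no support anywhere) stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    return PositionProfile(scores=mean, kind=profiles[0].kind, dispersion=sd, support=support)


def region_label(position_1based: int, L: int = 26) -> str:
    """Functional region of a guide position (g-notation, 1-based)."""
    if position_1based == 1:
        return "5prime_anchor"
    if position_1based <= 8:
        return "seed"
    if position_1based <= 11:
        return "catalytic_core"
    if position_1based <= 15:
        return "central"
    return "3prime"


def profile_report(profile: PositionProfile) -> pd.DataFrame:
    """Plot-ready table: one row per guide position with region annotation."""
    L = profile.L
    return pd.DataFrame(
        {
            "position": [f"g{i + 1}" for i in range(L)],
            "score": profile.scores,
            "sd": profile.dispersion if profile.dispersion is not None else [np.nan] * L,
            "support": profile.support if profile.support is not None else [np.nan] * L,
            "region": [region_label(i + 1, L) for i in range(L)],
        }
    )


def write_profile_tsv(profile: PositionProfile, path: str | Path) -> None:
    """Serialize a profile report; missing positions become NA, never 0."""
    df = profile_report(profile)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def plot_profile(profile: PositionProfile, path: str | Path, title: str = "") -> None:
    """Simple per-position bar plot with region shading for human inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile_report(profile)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    colors = {
        "5prime_anchor": "#4878d0",
        "seed": "#6acc64",
        "catalytic_core": "#ee854a",
        "central": "#956cb4",
        "3prime": "#d65f5f",
    }
    x = np.arange(profile.L)
    ax.bar(x, np.nan_to_num(profile.scores), color=[colors[r] for r in df["region"]],
           yerr=None if profile.dispersion is None else np.nan_to_num(profile.dispersion))
    ax.set_xticks(x[::2])
    ax.set_xticklabels(df["position"][::2], fontsize=7)
    ax.set_ylabel("Delta" if profile.kind.startswith("counterfactual") else "saliency")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
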