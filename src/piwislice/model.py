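"""High-level modelling interface: build a model from data, fit, inspect.

`CleavageRateModel` is constructed from a :class:`~piwislice.data.CleavageDataset`
(or a DataFrame / TSV in the standard cleavage-table layout) together with the
architecture and training configurations. ``fit`` trains one predictor on a
random train/validation split and returns a :class:`CleavageRateResults`
carrying the fitted parameters, the training history, diagnostics, prediction
and interpretability methods, and a ``summary()`` table. ``fit_logo`` runs the
leave-one-guide-out protocol across seeds and returns a :class:`LogoResults`
with per-fold metrics and aggregated position profiles.

Example
-------
>>> from piwislice import simulate, CleavageRateModel
>>> data, rule = simulate.generate_benchmark(n_guides=4, seed=7)
>>> res = CleavageRateModel(data).fit(seed=0)
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CleavageDataset, CleavageRecord, read_cleavage_table
from .encoding import GuideSequence, parse_pairing_string
from .interpret import (
    PositionProfile,
    aggregate_profiles,
    counterfactual_profile,
    saliency_scores,
)
from .network import InteractionRegressor, ModelConfig
from .training import (
    EvalResult,
    FoldResult,
    NormalizationParams,
    TrainConfig,
    evaluate,
    leave_one_guide_out,
    predict_rates,
    split_train_val,
    train_model,
)


def _dataset_from_frame(df: pd.DataFrame) -> CleavageDataset:
    guides: dict[str, GuideSequence] = {}
    records = []
    for _, row in df.iterrows():
        gid = str(row["guide_id"])
        guide = guides.setdefault(gid, GuideSequence(id=gid, nucleotides=str(row["guide_seq"])))
        spec = parse_pairing_string(str(row["pairing"]), L=len(guide))
        records.append(CleavageRecord(guide=guide, spec=spec, k=float(row["k"])))
    return CleavageDataset(records=records)


class CleavageRateModel:
    """A cleavage-rate regression model bound to a dataset."""

    def __init__(
        self,
        data: CleavageDataset,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if len(data) < 4:
            raise ValueError("need at least 4 records to fit")
        L = len(data.records[0].guide)
        self.data = data
        self.model_config = model_config or ModelConfig(L=L)
        self.train_config = train_config or TrainConfig()
        if self.model_config.L != L:
            raise ValueError(f"model L={self.model_config.L} but data has L={L}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "CleavageRateModel":
        return cls(_dataset_from_frame(df), model_config, train_config)

    @classmethod
    def from_tsv(
        cls, path: str | Path, model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "CleavageRateModel":
        return cls(read_cleavage_table(path), model_config, train_config)

    def fit(self, seed: int = 0, val: CleavageDataset | None = None) -> "CleavageRateResults":
        """Train on a random train/validation split (or an explicit ``val`` set)."""
        if val is None:
            train, val = split_train_val(self.data, self.train_config.val_fraction, seed=seed)
        else:
            train = self.data
        net, norm, history, best_epoch = train_model(
            train, val, self.model_config, self.train_config, seed=seed
        )
        return CleavageRateResults(
            model=self, network=net, normalization=norm, history=history,
            best_epoch=best_epoch, seed=seed, train=train, val=val,
        )

    def fit_logo(self, seeds: Sequence[int] = (0,), retrain: bool = True) -> "LogoResults":
        """Leave-one-guide-out cross-validation, repeated over seeds."""
        folds = {
            seed: leave_one_guide_out(
                self.data, self.model_config, self.train_config, seed=seed, retrain=retrain
            )
            for seed in seeds
        }
        return LogoResults(model=self, folds=folds)


@dataclass
class CleavageRateResults:
    """A fitted predictor with its normalization, history and diagnostics."""

    model: CleavageRateModel
    network: InteractionRegressor
    normalization: NormalizationParams
    history: list
    best_epoch: int
    seed: int
    train: CleavageDataset
    val: CleavageDataset

    def predict(self, data: CleavageDataset | None = None) -> np.ndarray:
        """Raw-rate predictions (inverse-time units of the input rates)."""
        return predict_rates(self.network, data if data is not None else self.model.data,
                             self.normalization)

    def evaluate(self, data: CleavageDataset) -> EvalResult:
        return evaluate(self.predict(data), data.rates)

    def saliency(self, data: CleavageDataset | None = None) -> PositionProfile:
        target = data if data is not None else self.val
        return saliency_scores(self.network, target.encodings())

    def counterfactual(self, data: CleavageDataset | None = None) -> PositionProfile:
        target = data if data is not None else self.model.data
        return counterfactual_profile(self.network, target)

    def save(self, path: str | Path) -> None:
        self.network.save(path, normalization=(self.normalization.mean, self.normalization.sd))

    def summary(self) -> str:
        val_res = self.evaluate(self.val)
        cfg = self.network.config
        lines = [
            "Cleavage-rate regression results",
            "=" * 48,
            f"records (train/val):    {len(self.train)}/{len(self.val)}",
            f"guides:                 {len(self.model.data.guide_groups)}",
            f"guide length L:         {cfg.L}",
            f"architecture:           d={cfg.d}, conv {cfg.conv_filters}x{cfg.kernel}, "
            f"{cfg.n_layers} attention layers x {cfg.n_heads} heads",
            f"ablation:               {cfg.ablation}",
            f"parameters:             {self.network.count_parameters()}",
            f"seed:                   {self.seed}",
            f"epochs run/best:        {len(self.history)}/{self.best_epoch}",
            f"rate normalization:     mean={self.normalization.mean:.4g}, sd={self.normalization.sd:.4g}",
            "-" * 48,
            f"validation PCC:         {val_res.pcc:.4f}",
            f"validation MAE (raw k): {val_res.mae:.4f}",
        ]
        return "\n".join(lines)


@dataclass
class LogoResults:
    """Leave-one-guide-out results over one or more seeds."""

    model: CleavageRateModel
    folds: dict[int, dict[str, FoldResult]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seed, by_guide in self.folds.items():
            for fold_no, (gid, fr) in enumerate(sorted(by_guide.items()), start=1):
                rows.append(
                    {"fold": fold_no, "guide_id": gid, "seed": seed,
                     "pcc": fr.result.pcc, "mae": fr.result.mae, "n": fr.result.n}
                )
        return pd.DataFrame(rows)

    def mean_pcc(self) -> float:
        return float(np.nanmean(self.to_frame()["pcc"]))

    def per_seed_pcc(self) -> dict[int, float]:
        df = self.to_frame()
        return {int(s): float(np.nanmean(g["pcc"])) for s, g in df.groupby("seed")}

    def counterfactual(self, heldout_only: bool = True) -> PositionProfile:
        """Counterfactual profile aggregated over seeds and folds.

        With ``heldout_only`` each fold's model is probed on its own held-out
        guide's records (the unseen-guide analysis); otherwise on all records.
        """
        profiles = []
        for by_guide in self.folds.values():
            for fr in by_guide.values():
                data = (
                    self.model.data.subset(fr.test_indices) if heldout_only else self.model.data
                )
                profiles.append(counterfactual_profile(fr.model, data))
        return aggregate_profiles(profiles)

    def saliency(self, heldout_only: bool = True) -> PositionProfile:
        profiles = []
        for by_guide in self.folds.values():
            for fr in by_guide.values():
                data = (
                    self.model.data.subset(fr.test_indices) if heldout_only else self.model.data
                )
                profiles.append(saliency_scores(fr.model, data.encodings()))
        return aggregate_profiles(profiles)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Leave-one-guide-out cross-validation",
            "=" * 48,
            f"guides/folds: {df['guide_id'].nunique()}   seeds: {df['seed'].nunique()}",
            "-" * 48,
            df.groupby("guide_id")[["pcc", "mae"]].agg(["mean", "std"]).round(4).to_string(),
            "-" * 48,
            f"overall mean PCC: {self.mean_pcc():.4f}",
        ]
        return "\n".join(lines)
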