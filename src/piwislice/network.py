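"""The position-aware hybrid CNN-attention cleavage-rate predictor.

The model maps the interaction encoding of a guide-target duplex to a
predicted cleavage rate (in z-score-normalized rate space; the training
module owns denormalization). Its stages, per duplex:

1. per-position projection of the 11-dim feature vector ``X_i = [G_i, M_i,
   E_i, D_i]`` into a d-dim embedding, ``h_i = W_G X_i + b_G``;
2. addition of a learnable position-specific embedding ``p_i`` (the model's
   handle on the spatial hierarchy of the guide: catalytic core g9-g11,
   relaxed seed, dispensable 3' tail);
3. a length-preserving 1D convolution + ReLU over positions, detecting local
   motifs such as contiguous Watson-Crick pairs near the catalytic core;
4. a stack of multi-head self-attention blocks contextualizing every
   position against the whole duplex (distal bulges perturbing the core);
5. a separate linear embedding of the insertion boundary vector ``I``;
6. a dense head on [flattened attention output || insertion embedding].

Four ablation variants reuse the same machinery: ``no_position`` drops stage
2, ``pure_cnn`` drops stage 4 and flattens the convolution output directly,
``simple_pairing`` collapses the M/E channels to one binary match flag
(per-position width 6), and ``no_insert`` drops stages 5 and the ``z`` input
to the head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, conv1d, dropout, layer_norm, parameter, softmax
from .encoding import InteractionEncoding

ABLATIONS = ("none", "no_position", "pure_cnn", "simple_pairing", "no_insert")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setting)."""

    L: int = 26
    d: int = 16
    d_ins: int = 8
    conv_filters: int = 16
    kernel: int = 3
    n_layers: int = 3
    n_heads: int = 4
    head_hidden: int = 64
    dropout: float = 0.1
    ablation: str = "none"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.conv_filters % self.n_heads != 0:
            raise ValueError("conv_filters must be divisible by n_heads")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if self.head_hidden < 1:
            raise ValueError("head_hidden must be >= 1")

    @property
    def input_width(self) -> int:
        return 6 if self.ablation == "simple_pairing" else 11

    @property
    def head_input_width(self) -> int:
        width = self.L * self.conv_filters
        if self.ablation != "no_insert":
            width += self.d_ins
        return width


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        bound = 1.0 / np.sqrt(n_in)
        self.W = parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class AttentionBlock:
    """Post-norm multi-head self-attention block with a ReLU feed-forward."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int, p_drop: float):
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.p_drop = p_drop
        self.q = Linear(rng, d, d)
        self.k = Linear(rng, d, d)
        self.v = Linear(rng, d, d)
        self.o = Linear(rng, d, d)
        self.ff1 = Linear(rng, d, 4 * d)
        self.ff2 = Linear(rng, 4 * d, d)
        self.ln1_g = parameter(np.ones(d))
        self.ln1_b = parameter(np.zeros(d))
        self.ln2_g = parameter(np.ones(d))
        self.ln2_b = parameter(np.zeros(d))

    def _split_heads(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, h: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        B, L, _ = h.shape
        q = self._split_heads(self.q(h), B, L)
        k = self._split_heads(self.k(h), B, L)
        v = self._split_heads(self.v(h), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attended = softmax(scores, axis=-1) @ v
        merged = attended.transpose(0, 2, 1, 3).reshape(B, L, self.d)
        out = self.o(merged)
        if training and rng is not None:
            out = dropout(out, self.p_drop, rng, training)
        h = layer_norm(h + out, self.ln1_g, self.ln1_b)
        ff = self.ff2(self.ff1(h).relu())
        if training and rng is not None:
            ff = dropout(ff, self.p_drop, rng, training)
        return layer_norm(h + ff, self.ln2_g, self.ln2_b)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for lin in (self.q, self.k, self.v, self.o, self.ff1, self.ff2):
            out.extend(lin.parameters())
        out.extend([self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b])
        return out


class InteractionRegressor:
    """The differentiable predictor; built deterministically from a seed."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.proj = Linear(rng, c.input_width, c.d)
        self.pos: Tensor | None = (
            None if c.ablation == "no_position" else parameter(rng.normal(0.0, 0.02, size=(c.L, c.d)))
        )
        bound = 1.0 / np.sqrt(c.d * c.kernel)
        self.conv_w = parameter(rng.uniform(-bound, bound, size=(c.conv_filters, c.d, c.kernel)))
        self.conv_b = parameter(np.zeros(c.conv_filters))
        self.blocks: list[AttentionBlock] = (
            []
            if c.ablation == "pure_cnn"
            else [AttentionBlock(rng, c.conv_filters, c.n_heads, c.dropout) for _ in range(c.n_layers)]
        )
        self.ins: Linear | None = None if c.ablation == "no_insert" else Linear(rng, c.L + 1, c.d_ins)
        self.head1 = Linear(rng, c.head_input_width, c.head_hidden)
        self.head2 = Linear(rng, c.head_hidden, 1)

    # -- parameters -----------------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = [("proj.W", self.proj.W), ("proj.b", self.proj.b)]
        if self.pos is not None:
            out.append(("pos", self.pos))
        out.extend([("conv.W", self.conv_w), ("conv.b", self.conv_b)])
        for i, blk in enumerate(self.blocks):
            names = (
                "q.W q.b k.W k.b v.W v.b o.W o.b ff1.W ff1.b ff2.W ff2.b "
                "ln1.g ln1.b ln2.g ln2.b"
            ).split()
            for name, p in zip(names, blk.parameters()):
                out.append((f"block{i}.{name}", p))
        if self.ins is not None:
            out.extend([("ins.W", self.ins.W), ("ins.b", self.ins.b)])
        out.extend(
            [("head1.W", self.head1.W), ("head1.b", self.head1.b),
             ("head2.W", self.head2.W), ("head2.b", self.head2.b)]
        )
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward --------------------------------------------------------
    def batch_inputs(self, encodings: Sequence[InteractionEncoding]) -> tuple[np.ndarray, np.ndarray]:
        """Stack encodings into (X, I) arrays of shape (B, L, w) and (B, L+1)."""
        simple = self.config.ablation == "simple_pairing"
        X = np.stack([e.position_features(simple_pairing=simple) for e in encodings])
        I = np.stack([e.I for e in encodings])
        if X.shape[1] != self.config.L:
            raise ValueError(f"encoding length {X.shape[1]} != model L {self.config.L}")
        return X, I

    def forward(
        self,
        X: Tensor,
        I: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predict normalized rates for a batch; returns a (B,) tensor."""
        B = X.shape[0]
        c = self.config
        h = self.proj(X)
        if self.pos is not None:
            h = h + self.pos
        h = conv1d(h, self.conv_w, self.conv_b).relu()
        for blk in self.blocks:
            h = blk(h, training, rng)
        flat = h.reshape(B, c.L * c.conv_filters)
        if self.ins is not None:
            flat = concat([flat, self.ins(I)], axis=1)
        out = self.head2(self.head1(flat).relu())
        return out.reshape(B)

    def predict(self, encodings: Sequence[InteractionEncoding]) -> np.ndarray:
        """Normalized-rate predictions as a plain array (no dropout)."""
        if not len(encodings):
            raise ValueError("empty batch")
        X, I = self.batch_inputs(encodings)
        return self.forward(Tensor(X), Tensor(I)).data.copy()

    # -- serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=ad.DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {name}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def save(self, path: str | Path, normalization: tuple[float, float] | None = None) -> None:
        """Write config + parameters (+ rate normalization) to one .npz file."""
        payload = {f"param/{k}": v for k, v in self.state_dict().items()}
        payload["config_json"] = np.array(json.dumps(asdict(self.config)))
        if normalization is not None:
            payload["normalization"] = np.array(normalization, dtype=np.float64)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> tuple["InteractionRegressor", tuple[float, float] | None]:
        with np.load(path, allow_pickle=False) as blob:
            config = ModelConfig(**json.loads(str(blob["config_json"])))
            model = cls(config, seed=0)
            model.load_state_dict(
                {k[len("param/"):]: blob[k] for k in blob.files if k.startswith("param/")}
            )
            norm = tuple(blob["normalization"]) if "normalization" in blob.files else None
        return model, norm


def build_model(config: ModelConfig, seed: int) -> InteractionRegressor:
    """Deterministically initialize a predictor (same config+seed => same bits)."""
    return InteractionRegressor(config, seed=seed)
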