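"""The trainable molecule-attention classifier.

Architecture: a linear embedding of per-atom features into d_model, N encoder
blocks (multi-head structure-augmented self-attention -> residual + layer
norm -> position-wise feed-forward -> residual + layer norm), masked mean (or
sum) pooling over atoms, and a logistic classification head producing
P(active).

Each attention head mixes the learned softmax attention with fixed structure
matrices:  λ_a·softmax(QKᵀ/√d_k) + λ_d·g(D) + λ_g·A + λ_h·H_bond, applied to
V. The mixing scalars are configuration, not learned parameters; λ_h = 0
together with a zero H-bond matrix turns the model into the plain
distance/adjacency variant (the ablation baseline), from the same code path.

Molecules of different sizes are batched by padding to the largest atom count
with an atom mask; masked positions are excluded from every softmax
normalization and from pooling, so padding never changes a molecule's output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .attention import normalize_distance
from .errors import ShapeError
from .featurizer import NUM_NODE_FEATURES, DescriptorSet, FeaturizerConfig

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults follow the full-scale training recipe: d_model 1024, 8 encoder
    blocks, 16 heads, batch 64, 100 epochs, Adam at 1e-4.
    :meth:`scaled_down` returns the reduced profile used for CPU-scale tests
    and examples (2 blocks, 4 heads, d_model 64, 10 epochs, Adam at 3e-3 —
    the short schedule needs the larger step size).
    """

    d_model: int = 1024
    n_blocks: int = 8
    heads: int = 16
    d_ff: Optional[int] = None
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    dropout: float = 0.0
    pooling: str = "mean"
    classification_threshold: float = 0.5
    lambda_a: float = 1.0 / 3.0
    lambda_d: float = 1.0 / 3.0
    lambda_g: float = 1.0 / 3.0
    lambda_h: float = 1.0
    distance_normalizer: str = "softmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model
        if min(self.lambda_a, self.lambda_d, self.lambda_g) < 0:
            raise ValueError("mixing scalars must be non-negative")
        if self.pooling not in ("mean", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    @property
    def dk(self) -> int:
        return self.d_model // self.heads

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        base = dict(
            d_model=64, n_blocks=2, heads=4, batch_size=32, epochs=10,
            learning_rate=3e-3,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = list(d["betas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["betas"] = tuple(d["betas"])
        return cls(**d)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return np.clip(rng.normal(0.0, std, shape), -2 * std, 2 * std)


def pad_batch(
    descriptors: Sequence[DescriptorSet], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of molecules to a common atom count.

    Returns (X, C, mask_bias, mask): node features (B,N,F), the fixed
    structure mix λ_d·g(D) + λ_g·A + λ_h·H_bond (B,N,N) with zero columns at
    padding, the additive attention bias (B,1,N) excluding padded keys, and
    the {0,1} atom mask (B,N). g(D) is computed on each molecule's own
    submatrix so padding cannot leak probability mass.
    """
    nmax = max(d.n_atoms for d in descriptors)
    b = len(descriptors)
    x = np.zeros((b, nmax, descriptors[0].node_features.shape[1]))
    c = np.zeros((b, nmax, nmax))
    mask = np.zeros((b, nmax))
    for i, d in enumerate(descriptors):
        n = d.n_atoms
        x[i, :n] = d.node_features
        g_d = normalize_distance(d.distance, config.distance_normalizer)
        c[i, :n, :n] = (
            config.lambda_d * g_d
            + config.lambda_g * d.adjacency
            + config.lambda_h * d.hbond_bool
        )
        mask[i, :n] = 1.0
    mask_bias = np.where(mask[:, None, :] > 0, 0.0, NEG_INF)
    return x, c, mask_bias, mask


class MathModel:
    """Structure-augmented attention classifier over descriptor bundles."""

    def __init__(
        self,
        config: ModelConfig,
        n_features: int = NUM_NODE_FEATURES,
        featurizer_config: Optional[FeaturizerConfig] = None,
    ):
        self.config = config
        self.n_features = n_features
        self.featurizer_config = featurizer_config or FeaturizerConfig()
        self.params: dict[str, ad.Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        p = self.params
        p["embed_w"] = ad.parameter(_trunc_normal(rng, (self.n_features, cfg.d_model)))
        p["embed_b"] = ad.parameter(np.zeros(cfg.d_model))
        for b in range(cfg.n_blocks):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"blk{b}.{name}"] = ad.parameter(
                    _trunc_normal(rng, (cfg.d_model, cfg.d_model))
                )
            p[f"blk{b}.bo"] = ad.parameter(np.zeros(cfg.d_model))
            p[f"blk{b}.ln1_g"] = ad.parameter(np.ones(cfg.d_model))
            p[f"blk{b}.ln1_b"] = ad.parameter(np.zeros(cfg.d_model))
            p[f"blk{b}.ff_w1"] = ad.parameter(_trunc_normal(rng, (cfg.d_model, cfg.d_ff)))
            p[f"blk{b}.ff_b1"] = ad.parameter(np.zeros(cfg.d_ff))
            p[f"blk{b}.ff_w2"] = ad.parameter(_trunc_normal(rng, (cfg.d_ff, cfg.d_model)))
            p[f"blk{b}.ff_b2"] = ad.parameter(np.zeros(cfg.d_model))
            p[f"blk{b}.ln2_g"] = ad.parameter(np.ones(cfg.d_model))
            p[f"blk{b}.ln2_b"] = ad.parameter(np.zeros(cfg.d_model))
        p["clf_w"] = ad.parameter(_trunc_normal(rng, (cfg.d_model, 1)))
        p["clf_b"] = ad.parameter(np.zeros(1))

    # ---- forward ----------------------------------------------------------

    def _attention(
        self, h: ad.Tensor, c: np.ndarray, mask_bias: np.ndarray, block: int
    ) -> ad.Tensor:
        """Multi-head mixed attention on a padded batch; h is (B,N,d_model)."""
        cfg = self.config
        p = self.params
        b, n, _ = h.shape
        hd, dk = cfg.heads, cfg.dk

        def split(t: ad.Tensor) -> ad.Tensor:
            return t.reshape(b, n, hd, dk).transpose(0, 2, 1, 3)  # (B,h,N,dk)

        q = split(h @ p[f"blk{block}.wq"])
        k = split(h @ p[f"blk{block}.wk"])
        v = split(h @ p[f"blk{block}.wv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        attn = ad.softmax(scores, bias=mask_bias[:, None, :, :])
        mix = cfg.lambda_a * attn + ad.constant(c[:, None, :, :])
        out = mix @ v  # (B,h,N,dk)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, cfg.d_model)
        return out @ p[f"blk{block}.wo"] + p[f"blk{block}.bo"]

    def _block(
        self, h: ad.Tensor, c: np.ndarray, mask_bias: np.ndarray, block: int,
        drop_rng: Optional[np.random.Generator] = None,
    ) -> ad.Tensor:
        p = self.params
        att = self._attention(h, c, mask_bias, block)
        att = self._dropout(att, drop_rng)
        h = ad.layer_norm(h + att, p[f"blk{block}.ln1_g"], p[f"blk{block}.ln1_b"])
        ff = (h @ p[f"blk{block}.ff_w1"] + p[f"blk{block}.ff_b1"]).relu()
        ff = ff @ p[f"blk{block}.ff_w2"] + p[f"blk{block}.ff_b2"]
        ff = self._dropout(ff, drop_rng)
        return ad.layer_norm(h + ff, p[f"blk{block}.ln2_g"], p[f"blk{block}.ln2_b"])

    def _dropout(self, t: ad.Tensor, rng: Optional[np.random.Generator]) -> ad.Tensor:
        if rng is None or self.config.dropout <= 0:
            return t
        keep = 1.0 - self.config.dropout
        mask = (rng.random(t.shape) < keep) / keep
        return t * ad.constant(mask)

    def forward_batch(
        self,
        descriptors: Sequence[DescriptorSet],
        drop_rng: Optional[np.random.Generator] = None,
    ) -> ad.Tensor:
        """Logits (B,) for a list of molecules, on the autodiff tape."""
        cfg = self.config
        x, c, mask_bias, mask = pad_batch(descriptors, cfg)
        b, n, _ = x.shape
        h = ad.constant(x) @ self.params["embed_w"] + self.params["embed_b"]
        for blk in range(cfg.n_blocks):
            h = self._block(h, c, mask_bias, blk, drop_rng)
        m = ad.constant(mask[:, :, None])
        pooled = (h * m).sum(axis=1)
        if cfg.pooling == "mean":
            pooled = pooled * ad.constant(1.0 / mask.sum(axis=1)[:, None])
        logits = pooled @ self.params["clf_w"] + self.params["clf_b"]
        return logits.reshape(b)

    def encoder_block(self, hidden: np.ndarray, descriptors: DescriptorSet,
                      block: int = 0) -> np.ndarray:
        """Apply one encoder block to a single molecule's hidden states."""
        n = descriptors.n_atoms
        if hidden.shape != (n, self.config.d_model):
            raise ShapeError(
                f"hidden {hidden.shape} incompatible with {(n, self.config.d_model)}"
            )
        _, c, mask_bias, _ = pad_batch([descriptors], self.config)
        out = self._block(ad.constant(hidden[None]), c, mask_bias, block)
        return out.data[0]

    def forward(self, molecule: DescriptorSet) -> float:
        """P(active) for one molecule."""
        return float(self.predict_proba([molecule])[0])

    def predict_proba(self, descriptors: Sequence[DescriptorSet]) -> np.ndarray:
        """P(active) for a list of molecules (batched, no gradient bookkeeping)."""
        probs = np.empty(len(descriptors))
        bs = self.config.batch_size
        for start in range(0, len(descriptors), bs):
            chunk = descriptors[start:start + bs]
            logits = self.forward_batch(chunk).data
            probs[start:start + len(chunk)] = 1.0 / (1.0 + np.exp(-logits))
        return probs

    def predict(self, descriptors: Sequence[DescriptorSet]) -> np.ndarray:
        return (self.predict_proba(descriptors) >= self.config.classification_threshold).astype(int)

    # ---- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint: weights + model config + featurizer config."""
        meta = json.dumps(
            {
                "model_config": self.config.to_dict(),
                "featurizer_config": dataclasses.asdict(self.featurizer_config),
                "n_features": self.n_features,
            }
        )
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez_compressed(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "MathModel":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        model = cls(
            ModelConfig.from_dict(meta["model_config"]),
            n_features=meta["n_features"],
            featurizer_config=FeaturizerConfig(**meta["featurizer_config"]),
        )
        for k in model.params:
            model.params[k].data = archive[k]
        return model
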