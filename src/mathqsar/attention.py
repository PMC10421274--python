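"""Molecule self-attention: scaled dot-product attention augmented with
adjacency, inter-atomic distance and intramolecular hydrogen-bond structure.

For one head with projections W^Q, W^K, W^V and key dimension d_k, standard
attention over hidden states H is

    A = softmax(Q K^T / sqrt(d_k)) V,   Q = H W^Q, K = H W^K, V = H W^V.

The molecule variant mixes the attention weights with structure matrices
before applying them to V:

    A = (λ_a softmax(Q K^T / sqrt(d_k)) + λ_d g(D) + λ_g A_adj + λ_h H_bond) V

where A_adj is the covalent adjacency matrix, D the heavy-atom distance
matrix, H_bond the {0,1} hydrogen-bond contact matrix, λ_* non-negative
mixing scalars, and g a normalizer mapping distances to non-negative row
weights. Setting (λ_a, λ_d, λ_g, λ_h) = (1, 0, 0, 0) recovers standard
attention; setting λ_h = 0 (or a zero H_bond) recovers the distance/adjacency
variant without hydrogen-bond information, which serves as the ablation
baseline.

These are single-molecule reference implementations in plain NumPy; the
trainable model in :mod:`mathqsar.model` evaluates the same formulas on the
autodiff tape, and the test suite checks the two against each other and
against scalar-loop oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ShapeError

DISTANCE_NORMALIZERS = ("softmax", "exp")


@dataclass
class AttentionParams:
    """Per-head projections plus the structure-mixing scalars."""

    wq: Sequence[np.ndarray]  # heads × (d_model, d_k)
    wk: Sequence[np.ndarray]
    wv: Sequence[np.ndarray]
    dk: int
    heads: int
    lambda_a: float = 1.0 / 3.0
    lambda_d: float = 1.0 / 3.0
    lambda_g: float = 1.0 / 3.0
    lambda_h: float = 1.0
    distance_normalizer: str = "softmax"

    def __post_init__(self) -> None:
        if self.dk <= 0 or self.heads < 1:
            raise ValueError("dk must be positive and heads >= 1")
        for lam, name in ((self.lambda_a, "lambda_a"), (self.lambda_d, "lambda_d"),
                          (self.lambda_g, "lambda_g")):
            if lam < 0:
                raise ValueError(f"{name} must be non-negative, got {lam}")
        if self.distance_normalizer not in DISTANCE_NORMALIZERS:
            raise ValueError(f"unknown distance normalizer {self.distance_normalizer!r}")


def row_softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def normalize_distance(distance: np.ndarray, kind: str = "softmax") -> np.ndarray:
    """g(D): map a distance matrix to non-negative attention weights.

    ``"softmax"`` (default) is a row softmax of the negated distances, so each
    row sums to 1 and nearer atoms receive larger weight. ``"exp"`` is the
    unnormalized elementwise exp(−D).
    """
    if kind == "softmax":
        return row_softmax(-distance)
    if kind == "exp":
        return np.exp(-distance)
    raise ValueError(f"unknown distance normalizer {kind!r}")


def _check_head(params: AttentionParams, head: int) -> None:
    if not 0 <= head < params.heads:
        raise ShapeError(f"head {head} out of range for {params.heads} heads")


def standard_attention(hidden: np.ndarray, params: AttentionParams, head: int) -> np.ndarray:
    """softmax(Q Kᵀ / √d_k) V for one head; each softmax row sums to 1."""
    _check_head(params, head)
    wq, wk, wv = params.wq[head], params.wk[head], params.wv[head]
    if hidden.ndim != 2 or hidden.shape[1] != wq.shape[0]:
        raise ShapeError(
            f"hidden {hidden.shape} not conformable with projections {wq.shape}"
        )
    q, k, v = hidden @ wq, hidden @ wk, hidden @ wv
    scores = q @ k.T / np.sqrt(params.dk)
    return row_softmax(scores) @ v


def molecule_self_attention(
    hidden: np.ndarray,
    adjacency: np.ndarray,
    distance: np.ndarray,
    hbond: np.ndarray,
    params: AttentionParams,
    head: int,
) -> np.ndarray:
    """Structure-augmented attention for one head (see module docstring)."""
    _check_head(params, head)
    n = hidden.shape[0]
    for name, mat in (("adjacency", adjacency), ("distance", distance), ("hbond", hbond)):
        if mat.shape != (n, n):
            raise ShapeError(f"{name} has shape {mat.shape}, expected {(n, n)}")
    wq, wk, wv = params.wq[head], params.wk[head], params.wv[head]
    if hidden.shape[1] != wq.shape[0]:
        raise ShapeError(
            f"hidden {hidden.shape} not conformable with projections {wq.shape}"
        )
    q, k, v = hidden @ wq, hidden @ wk, hidden @ wv
    attn = row_softmax(q @ k.T / np.sqrt(params.dk))
    g_d = normalize_distance(distance, params.distance_normalizer)
    mix = (
        params.lambda_a * attn
        + params.lambda_d * g_d
        + params.lambda_g * adjacency
        + params.lambda_h * hbond
    )
    return mix @ v


def random_params(
    d_model: int,
    heads: int,
    rng: np.random.Generator,
    scale: float = 0.1,
    **lambdas,
) -> AttentionParams:
    """Convenience constructor with Gaussian projections (testing / examples)."""
    if d_model % heads:
        raise ValueError("d_model must be divisible by heads")
    dk = d_model // heads
    mk = lambda: [rng.normal(0, scale, (d_model, dk)) for _ in range(heads)]
    return AttentionParams(wq=mk(), wk=mk(), wv=mk(), dk=dk, heads=heads, **lambdas)
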