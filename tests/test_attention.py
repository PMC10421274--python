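"""Attention operations against scalar-loop oracles.

The oracles below evaluate the attention formulas element by element with
plain Python loops and math.exp — written independently of the vectorized
implementations they check.
"""

import math

import numpy as np
import pytest

from mathqsar.attention import (
    AttentionParams,
    molecule_self_attention,
    normalize_distance,
    random_params,
    standard_attention,
)
from mathqsar.errors import ShapeError


# ---- scalar oracles ---------------------------------------------------------


def oracle_standard(h, wq, wk, wv, dk):
    n, d = len(h), len(h[0])
    dv = len(wv[0])
    q = [[sum(h[i][a] * wq[a][b] for a in range(d)) for b in range(dk)] for i in range(n)]
    k = [[sum(h[i][a] * wk[a][b] for a in range(d)) for b in range(dk)] for i in range(n)]
    v = [[sum(h[i][a] * wv[a][b] for a in range(d)) for b in range(dv)] for i in range(n)]
    out = [[0.0] * dv for _ in range(n)]
    for i in range(n):
        scores = [sum(q[i][b] * k[j][b] for b in range(dk)) / math.sqrt(dk) for j in range(n)]
        mx = max(scores)
        ex = [math.exp(s - mx) for s in scores]
        z = sum(ex)
        for j in range(n):
            w = ex[j] / z
            for b in range(dv):
                out[i][b] += w * v[j][b]
    return np.array(out)


def oracle_molecule(h, adj, dist, hbond, wq, wk, wv, dk, la, ld, lg, lh):
    n = len(h)
    dv = len(wv[0])
    d = len(h[0])
    q = [[sum(h[i][a] * wq[a][b] for a in range(d)) for b in range(dk)] for i in range(n)]
    k = [[sum(h[i][a] * wk[a][b] for a in range(d)) for b in range(dk)] for i in range(n)]
    v = [[sum(h[i][a] * wv[a][b] for a in range(d)) for b in range(dv)] for i in range(n)]
    out = [[0.0] * dv for _ in range(n)]
    for i in range(n):
        scores = [sum(q[i][b] * k[j][b] for b in range(dk)) / math.sqrt(dk) for j in range(n)]
        mx = max(scores)
        ex = [math.exp(s - mx) for s in scores]
        zs = sum(ex)
        negd = [-dist[i][j] for j in range(n)]
        mg = max(negd)
        eg = [math.exp(x - mg) for x in negd]
        zg = sum(eg)
        for j in range(n):
            w = la * ex[j] / zs + ld * eg[j] / zg + lg * adj[i][j] + lh * hbond[i][j]
            for b in range(dv):
                out[i][b] += w * v[j][b]
    return np.array(out)


def random_instance(rng, lambdas=None):
    n = int(rng.integers(2, 6))
    d_model, heads = 8, 2
    p = random_params(d_model, heads, rng, **(lambdas or {}))
    h = rng.normal(size=(n, d_model))
    adj = (rng.random((n, n)) < 0.4).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    dist = np.abs(rng.normal(1.5, 1.0, size=(n, n)))
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    hb = (rng.random((n, n)) < 0.2).astype(float)
    hb = np.triu(hb, 1)
    hb = hb + hb.T
    return h, adj, dist, hb, p


def test_standard_attention_matches_scalar_oracle_on_100_instances():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        h, _, _, _, p = random_instance(rng)
        for head in range(p.heads):
            got = standard_attention(h, p, head)
            exp = oracle_standard(
                h.tolist(), p.wq[head].tolist(), p.wk[head].tolist(),
                p.wv[head].tolist(), p.dk,
            )
            np.testing.assert_allclose(got, exp, atol=1e-5)


def test_molecule_attention_matches_scalar_oracle_on_100_instances():
    rng = np.random.default_rng(99)
    for _ in range(100):
        h, adj, dist, hb, p = random_instance(
            rng, dict(lambda_a=1 / 3, lambda_d=1 / 3, lambda_g=1 / 3, lambda_h=1.0)
        )
        head = int(rng.integers(p.heads))
        got = molecule_self_attention(h, adj, dist, hb, p, head)
        exp = oracle_molecule(
            h.tolist(), adj.tolist(), dist.tolist(), hb.tolist(),
            p.wq[head].tolist(), p.wk[head].tolist(), p.wv[head].tolist(),
            p.dk, p.lambda_a, p.lambda_d, p.lambda_g, p.lambda_h,
        )
        np.testing.assert_allclose(got, exp, atol=1e-5)


# ---- structural properties --------------------------------------------------


def test_reduction_to_standard_attention():
    rng = np.random.default_rng(7)
    for _ in range(20):
        h, adj, dist, _, p = random_instance(
            rng, dict(lambda_a=1.0, lambda_d=0.0, lambda_g=0.0, lambda_h=5.0)
        )
        zero_hb = np.zeros_like(adj)
        got = molecule_self_attention(h, adj, dist, zero_hb, p, 0)
        np.testing.assert_allclose(got, standard_attention(h, p, 0), atol=1e-6)


def test_single_atom_output_equals_value_row():
    rng = np.random.default_rng(3)
    p = random_params(8, 2, rng)
    h = rng.normal(size=(1, 8))
    np.testing.assert_allclose(standard_attention(h, p, 0), h @ p.wv[0], atol=1e-12)


def test_identical_rows_give_identical_outputs():
    rng = np.random.default_rng(4)
    p = random_params(8, 2, rng)
    h = np.tile(rng.normal(size=(1, 8)), (4, 1))
    out = standard_attention(h, p, 1)
    np.testing.assert_allclose(out, np.tile(out[:1], (4, 1)), atol=1e-12)


def test_pure_adjacency_routing_swaps_value_rows():
    rng = np.random.default_rng(5)
    p = random_params(8, 1, rng, lambda_a=0.0, lambda_d=0.0, lambda_g=1.0, lambda_h=0.0)
    h = rng.normal(size=(2, 8))
    adj = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = molecule_self_attention(h, adj, np.zeros((2, 2)), np.zeros((2, 2)), p, 0)
    v = h @ p.wv[0]
    np.testing.assert_allclose(out, v[::-1], atol=1e-12)


def test_softmax_normalizer_rows_sum_to_one():
    rng = np.random.default_rng(6)
    d = np.abs(rng.normal(2, 1, size=(5, 5)))
    g = normalize_distance(d, "softmax")
    assert np.all(g >= 0)
    np.testing.assert_allclose(g.sum(axis=1), np.ones(5), atol=1e-12)
    assert np.all(normalize_distance(d, "exp") >= 0)


def test_nearer_atoms_get_larger_weight():
    d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
    g = normalize_distance(d)
    assert g[0, 1] > g[0, 2]


def test_shape_and_lambda_validation():
    rng = np.random.default_rng(8)
    p = random_params(8, 2, rng)
    h = rng.normal(size=(3, 8))
    with pytest.raises(ShapeError):
        standard_attention(rng.normal(size=(3, 5)), p, 0)
    with pytest.raises(ShapeError):
        standard_attention(h, p, 5)
    with pytest.raises(ShapeError):
        molecule_self_attention(h, np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((3, 3)), p, 0)
    with pytest.raises(ValueError):
        AttentionParams(wq=p.wq, wk=p.wk, wv=p.wv, dk=4, heads=2, lambda_a=-0.1)
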