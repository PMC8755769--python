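"""Metric kernels against hand values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracecf import nn
from tracecf.metrics import (confidence, proximity_from_latents, realism,
                             sparsity, validity)

# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------


def test_validity_categorical_counts():
    assert validity([1, 1, 0], [1, 1, 0], "categorical") == 1.0
    preds = [1] * 7 + [0] * 3
    assert validity(preds, [1] * 10, "categorical") == pytest.approx(0.7)


def test_validity_continuous_is_mape():
    assert validity(np.full(5, 25.0), np.full(5, 20.0), "continuous") == \
        pytest.approx(0.25)
    with pytest.raises(ValueError):
        validity([1.0], [0.0], "continuous")
    with pytest.raises(ValueError):
        validity([1], [1], "fuzzy")


# ---------------------------------------------------------------------------
# confidence
# ---------------------------------------------------------------------------


def _fixed_classifier(logits):
    from tracecf.counterfactual import ClassifierConfig, SoftmaxClassifier
    rng = np.random.default_rng(0)
    net = nn.Sequential([nn.Dense(3, len(logits), rng)])
    net.layers[0].W.value[...] = 0.0
    net.layers[0].b.value[...] = logits
    return SoftmaxClassifier(net=net, n_classes=len(logits), latent_dim=3,
                             config=ClassifierConfig())


def test_confidence_softmax_values():
    z = np.zeros(3)
    clf = _fixed_classifier([0.0, 0.0])
    assert confidence(clf, z, 0) == pytest.approx(0.5)
    assert confidence(clf, z, 0) + confidence(clf, z, 1) == pytest.approx(1.0)
    steep = _fixed_classifier([10.0, -10.0])
    assert confidence(steep, z, 0) == pytest.approx(1.0, abs=1e-4)
    with pytest.raises(ValueError):
        confidence(clf, z, 5)


# ---------------------------------------------------------------------------
# sparsity
# ---------------------------------------------------------------------------


def test_sparsity_hand_cases():
    x = np.zeros((10, 10))
    assert sparsity(x, x) == 0.0
    one = x.copy()
    one[3, 4] = 0.5
    assert sparsity(x, one) == pytest.approx(0.01)
    assert sparsity(x, np.ones((10, 10))) == 1.0
    with pytest.raises(ValueError):
        sparsity(x, np.zeros((9, 10)))


def test_sparsity_threshold_is_one_quantization_step():
    x = np.zeros((4, 4))
    y = np.full((4, 4), 0.5 / 255.0)  # below one 8-bit step: not "altered"
    assert sparsity(x, y) == 0.0
    assert sparsity(x, np.full((4, 4), 2.0 / 255.0)) == 1.0


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------


def test_proximity_hand_cases():
    train = np.array([[1.0], [2.0], [5.0]])
    assert proximity_from_latents(np.array([0.0]), train, K=2) == pytest.approx(1.5)
    assert proximity_from_latents(train[0], train, K=1) == 0.0
    with pytest.raises(ValueError):
        proximity_from_latents(np.array([0.0]), train, K=4)


# ---------------------------------------------------------------------------
# realism
# ---------------------------------------------------------------------------


def test_realism_hand_evaluation():
    real = np.array([[0.0], [1.0]])
    # each point's 1st neighbor (excluding itself) is at distance 1
    assert realism(np.array([0.5]), real, K=1) == pytest.approx(2.0)
    assert realism(np.array([10.0]), real, K=1) == pytest.approx(1.0 / 9.0)
    # off-manifold scores below the midpoint score
    assert realism(np.array([10.0]), real, K=1) < realism(np.array([0.5]), real, K=1)


def test_realism_sentinel_and_minimum_set_size():
    real = np.array([[0.0], [1.0], [2.0]])
    assert realism(np.array([1.0]), real, K=1) == 1e6
    with pytest.raises(ValueError):
        realism(np.array([0.5]), real, K=3)


def test_realism_invariant_under_rigid_rotation():
    rng = np.random.default_rng(0)
    real = rng.standard_normal((20, 3))
    g = rng.standard_normal(3)
    # a random rotation (QR of a Gaussian matrix)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    assert realism(g @ q.T, real @ q.T, K=3) == \
        pytest.approx(realism(g, real, K=3), rel=1e-9)


# ---------------------------------------------------------------------------
# property: kernels match brute force on random instances
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**32 - 1))
def test_kernels_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    # sparsity
    x = rng.random((6, 6))
    y = rng.random((6, 6))
    eps = 1.0 / 255.0
    brute = sum(abs(x[i, j] - y[i, j]) > eps for i in range(6) for j in range(6)) / 36
    assert sparsity(x, y, eps) == pytest.approx(brute, abs=1e-12)
    # proximity
    train = rng.standard_normal((15, 4))
    zb = rng.standard_normal(4)
    K = int(rng.integers(1, 6))
    dists = sorted(np.sqrt(((train - zb) ** 2).sum(axis=1)))
    assert proximity_from_latents(zb, train, K) == \
        pytest.approx(float(np.mean(dists[:K])), abs=1e-10)
    # realism
    feats = rng.standard_normal((10, 3))
    g = rng.standard_normal(3)
    Kr = int(rng.integers(1, 4))
    best = -np.inf
    for j in range(10):
        others = sorted(np.linalg.norm(feats[k] - feats[j])
                        for k in range(10) if k != j)
        best = max(best, others[Kr - 1] / np.linalg.norm(feats[j] - g))
    assert realism(g, feats, Kr) == pytest.approx(best, rel=1e-10)


# ---------------------------------------------------------------------------
# batch evaluation (on the shared pipeline)
# ---------------------------------------------------------------------------


def test_evaluate_batch_single_row_and_permutation(bench):
    from tracecf.counterfactual import CFConfig, generate_trace
    from tracecf.metrics import evaluate_batch

    idx = np.flatnonzero(bench.dataset.labels == 0)[:6]
    cfs = [generate_trace(bench.latents[i], 1, bench.lbc, bench.wae, CFConfig())
           for i in idx]
    queries = bench.dataset.images[idx]
    targets = np.ones(len(idx), dtype=int)

    one = evaluate_batch(cfs[:1], queries[:1], targets[:1], bench.lbc,
                         bench.wae, bench.dataset.images)
    assert one.n == 1
    assert one.aggregates.loc["std"].eq(0.0).all()
    np.testing.assert_allclose(one.aggregates.loc["mean"].to_numpy(),
                               one.rows.iloc[0].to_numpy())

    full = evaluate_batch(cfs, queries, targets, bench.lbc, bench.wae,
                          bench.dataset.images)
    perm = np.array([3, 1, 5, 0, 4, 2])
    shuffled = evaluate_batch([cfs[i] for i in perm], queries[perm],
                              targets[perm], bench.lbc, bench.wae,
                              bench.dataset.images)
    np.testing.assert_allclose(full.aggregates.to_numpy(),
                               shuffled.aggregates.to_numpy(), atol=1e-12)

    # aggregates equal an independent recomputation from the rows
    for col in full.rows.columns:
        assert full.aggregates.loc["mean", col] == \
            pytest.approx(float(np.mean(full.rows[col])))
        assert full.aggregates.loc["std", col] == \
            pytest.approx(float(np.std(full.rows[col])))

    with pytest.raises(ValueError):
        evaluate_batch(cfs, queries[:2], targets, bench.lbc, bench.wae,
                       bench.dataset.images)
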