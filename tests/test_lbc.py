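"""Calibration kernels and the alternating LbC trainer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracecf.lbc import (LbcConfig, class_probabilities, coverage,
                         hinge_interval_loss, interval_calibration_error,
                         labels_to_logits, load_lbc, predict, save_lbc,
                         train_lbc)
from tracecf.synthetic import heteroscedastic_regression

# ---------------------------------------------------------------------------
# label -> logit encoding
# ---------------------------------------------------------------------------


def test_binary_logit_encoding_matches_log_odds():
    v = labels_to_logits(0, K=2, eps_negative=0.01)
    np.testing.assert_allclose(v, [np.log(99.0), np.log(1 / 99.0)], atol=1e-12)
    assert v[0] == pytest.approx(4.5951, abs=1e-4)


def test_three_class_encoding_values():
    v = labels_to_logits(1, K=3, eps_negative=0.01)
    assert v[1] == pytest.approx(np.log(0.98 / 0.02), abs=1e-12)
    assert v[1] == pytest.approx(3.8918, abs=1e-4)
    assert v[0] == v[2] == pytest.approx(np.log(0.01 / 0.99), abs=1e-12)


@pytest.mark.parametrize("K", [2, 3, 5])
def test_encoded_probabilities_sum_to_one(K):
    v = labels_to_logits(0, K=K, eps_negative=0.01)
    p = 1.0 / (1.0 + np.exp(-v))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_invalid_encoding_parameters_raise():
    with pytest.raises(ValueError):
        labels_to_logits(0, K=1)
    with pytest.raises(ValueError):
        labels_to_logits(0, K=2, eps_negative=0.6)
    with pytest.raises(ValueError):
        labels_to_logits(5, K=2)


# ---------------------------------------------------------------------------
# calibration error and hinge kernels
# ---------------------------------------------------------------------------


def test_calibration_error_full_and_zero_coverage():
    y_hat = np.zeros((10, 1))
    y = np.linspace(-1, 1, 10)[:, None]
    huge = np.full((10, 1), 1e6)
    assert interval_calibration_error(y_hat, huge, y, 0.9) == pytest.approx(0.1)
    zero = np.zeros((10, 1))
    assert interval_calibration_error(y_hat, zero, y, 0.9) == pytest.approx(0.9)


def test_calibration_error_exact_coverage_count():
    # 9 of 10 targets inside the interval -> coverage 0.9 -> error 0
    y_hat = np.zeros((10, 1))
    delta = np.ones((10, 1))
    y = np.r_[np.linspace(-0.9, 0.9, 9), 5.0][:, None]
    assert interval_calibration_error(y_hat, delta, y, 0.9) == pytest.approx(0.0)


def test_hinge_hand_values():
    assert hinge_interval_loss([[1.0]], [[0.5]], [[1.2]], 0.05) == 0.0
    assert hinge_interval_loss([[0.0]], [[0.1]], [[1.0]], 0.05) == \
        pytest.approx(0.95, abs=1e-12)
    assert hinge_interval_loss([[3.0]], [[0.7]], [[3.0]], 0.0) == 0.0


def test_hinge_zero_iff_target_inside_margin_shrunk_interval():
    tau = 0.05
    y_hat, delta = np.array([[0.0]]), np.array([[0.5]])
    inside = np.array([[0.44]])
    boundary_out = np.array([[0.46]])
    assert hinge_interval_loss(y_hat, delta, inside, tau) == 0.0
    assert hinge_interval_loss(y_hat, delta, boundary_out, tau) > 0.0


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**32 - 1))
def test_kernels_match_bruteforce_loops(seed):
    rng = np.random.default_rng(seed)
    n, k = rng.integers(2, 12), rng.integers(1, 4)
    y_hat = rng.standard_normal((n, k))
    delta = rng.random((n, k))
    y = rng.standard_normal((n, k))
    alpha, tau = rng.random(), 0.05

    ice = 0.0
    for kk in range(k):
        cov = sum(y_hat[i, kk] - delta[i, kk] <= y[i, kk] <= y_hat[i, kk] + delta[i, kk]
                  for i in range(n)) / n
        ice += abs(alpha - cov)
    assert interval_calibration_error(y_hat, delta, y, alpha) == \
        pytest.approx(ice, abs=1e-12)

    hinge = 0.0
    for kk in range(k):
        for i in range(n):
            hinge += max(0.0, (y_hat[i, kk] - delta[i, kk]) - y[i, kk] + tau) / n
            hinge += max(0.0, y[i, kk] - (y_hat[i, kk] + delta[i, kk]) + tau) / n
    assert hinge_interval_loss(y_hat, delta, y, tau) == pytest.approx(hinge, abs=1e-10)

    # hinge == 0 with tau > 0 implies full hard coverage
    big = np.abs(y - y_hat) + tau + 0.01
    assert hinge_interval_loss(y_hat, big, y, tau) == 0.0
    assert coverage(y_hat, big, y).min() == 1.0


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        hinge_interval_loss(np.zeros((3, 1)), np.zeros((3, 1)), np.zeros((4, 1)), 0.0)


# ---------------------------------------------------------------------------
# training behaviour
# ---------------------------------------------------------------------------

_FAST = LbcConfig(f_hidden=(64, 64), g_hidden=(64, 64), epochs=120)


@pytest.fixture(scope="module")
def regression_fit():
    zt, yt = heteroscedastic_regression(2000, seed=100)
    zv, yv = heteroscedastic_regression(1000, seed=101)
    model = train_lbc(zt, yt, "regression", _FAST, seed=0)
    return model, zv, yv


def test_regression_coverage_near_alpha(regression_fit):
    model, zv, yv = regression_fit
    p = predict(model, zv)
    cov = coverage(p.y_hat, p.delta, yv[:, None])[0]
    assert 0.85 <= cov <= 0.95


def test_predict_path_agrees_with_calibration_error_count(regression_fit):
    model, zv, yv = regression_fit
    p = predict(model, zv)
    cov = coverage(p.y_hat, p.delta, yv[:, None])[0]
    err = interval_calibration_error(p.y_hat, p.delta, yv[:, None], 0.9)
    assert err == pytest.approx(abs(0.9 - cov), abs=1e-12)


def test_deltas_nonnegative_and_destandardized(regression_fit):
    model, zv, _ = regression_fit
    p = predict(model, zv)
    assert (p.delta >= 0).all()
    single = predict(model, zv[0])
    np.testing.assert_allclose(single.y_hat, p.y_hat[0], atol=1e-9)


def test_lower_alpha_gives_lower_coverage_and_narrower_intervals():
    zt, yt = heteroscedastic_regression(1500, seed=200)
    zv, yv = heteroscedastic_regression(800, seed=201)
    covs, widths = {}, {}
    for alpha in (0.5, 0.9):
        cfg = LbcConfig(alpha=alpha, f_hidden=(64, 64), g_hidden=(64, 64),
                        epochs=120)
        deltas, cs = [], []
        for seed in range(3):
            m = train_lbc(zt, yt, "regression", cfg, seed=seed)
            p = predict(m, zv)
            cs.append(coverage(p.y_hat, p.delta, yv[:, None])[0])
            deltas.append(p.delta.mean())
        covs[alpha], widths[alpha] = np.mean(cs), np.mean(deltas)
    assert covs[0.5] < covs[0.9]
    assert widths[0.5] < widths[0.9]


def test_classification_accuracy_on_separable_latents():
    rng = np.random.default_rng(0)
    z = np.vstack([rng.standard_normal((300, 8)) + np.r_[2.5, np.zeros(7)],
                   rng.standard_normal((300, 8)) - np.r_[2.5, np.zeros(7)]])
    labels = np.r_[np.zeros(300, int), np.ones(300, int)]
    m = train_lbc(z, labels, "classification",
                  LbcConfig(f_hidden=(32, 32), g_hidden=(32, 32), epochs=60),
                  seed=1)
    p = class_probabilities(m, z)
    assert (p.argmax(axis=1) == labels).mean() > 0.9
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_degenerate_targets_and_bad_task_raise():
    z = np.random.default_rng(0).standard_normal((20, 4))
    with pytest.raises(ValueError):
        train_lbc(z, np.zeros(20), "regression", _FAST)
    with pytest.raises(ValueError):
        train_lbc(z, np.arange(20), "ranking", _FAST)


def test_checkpoint_roundtrip(regression_fit, tmp_path):
    model, zv, _ = regression_fit
    save_lbc(model, tmp_path / "m.h5")
    back = load_lbc(tmp_path / "m.h5")
    np.testing.assert_allclose(predict(back, zv[:5]).y_hat,
                               predict(model, zv[:5]).y_hat, atol=1e-10)
    assert back.task == "regression"
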