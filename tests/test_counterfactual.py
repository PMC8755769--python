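"""Counterfactual objectives, generators and baseline classifier trainers."""

import numpy as np
import pytest

from tracecf import nn
from tracecf.counterfactual import (CFConfig, ClassifierConfig, DropoutProvider,
                                    EnsembleProvider, bhattacharyya_coefficient,
                                    generate_gaussian_calibrated,
                                    generate_trace, generate_vanilla,
                                    trace_cf_objective, train_ensemble,
                                    train_mixup_classifier,
                                    train_softmax_classifier,
                                    train_uwcc_classifier, progressive_sweep)
from tracecf.lbc import CalibratedPredictor, LbcConfig


def _constant_model(y_hat, delta, d=4):
    """A calibrated predictor whose F and G output fixed constants."""
    rng = np.random.default_rng(0)
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    F = nn.Sequential([nn.Dense(d, len(y_hat), rng)])
    G = nn.Sequential([nn.Dense(d, len(delta), rng)])
    F.layers[0].W.value[...] = 0.0
    F.layers[0].b.value[...] = y_hat
    G.layers[0].W.value[...] = 0.0
    G.layers[0].b.value[...] = delta
    return CalibratedPredictor(F=F, G=G, task="regression", config=LbcConfig(),
                               n_outputs=len(y_hat), latent_dim=d)


def _latent_problem(seed=0, n=400, d=8, gap=1.5):
    rng = np.random.default_rng(seed)
    z = np.vstack([rng.standard_normal((n // 2, d)) + np.r_[gap, np.zeros(d - 1)],
                   rng.standard_normal((n // 2, d)) - np.r_[gap, np.zeros(d - 1)]])
    labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return z, labels


# ---------------------------------------------------------------------------
# the TraCE objective
# ---------------------------------------------------------------------------


def test_objective_term_by_term_hand_value():
    # y_hat=0, delta=0.1, y_bar=1, tau=0.05, etas=(1,1,1), ||z - z_hat||^2=0.25
    model = _constant_model(0.0, 0.1)
    cfg = CFConfig(eta1=1.0, eta2=1.0, eta3=1.0, tau=0.05)
    z = np.zeros(4)
    z_hat = np.r_[0.5, np.zeros(3)]
    assert trace_cf_objective(z_hat, z, model, 1.0, cfg) == \
        pytest.approx(0.25 + 0.95 + 0.1, abs=1e-12)


def test_objective_reduces_to_interval_penalty_when_satisfied():
    model = _constant_model(1.0, 0.5)
    cfg = CFConfig(eta1=0.7, eta2=0.9, eta3=0.3, tau=0.05)
    z = np.ones(4)
    # y_bar inside [y_hat - delta + tau, y_hat + delta - tau] and z_hat = z
    assert trace_cf_objective(z, z, model, 1.2, cfg) == pytest.approx(0.3 * 0.5)


def test_objective_zero_when_all_weights_zero():
    model = _constant_model(3.0, 0.2)
    cfg = CFConfig(eta1=0.0, eta2=0.0, eta3=0.0)
    rng = np.random.default_rng(1)
    assert trace_cf_objective(rng.standard_normal(4), rng.standard_normal(4),
                              model, -5.0, cfg) == 0.0


def test_objective_matches_bruteforce_on_random_networks():
    rng = np.random.default_rng(7)
    d, K = 6, 3
    F = nn.mlp([d, 10, K], rng, activation="elu")
    G = nn.mlp([d, 10, K], rng, activation="relu", out_layer=nn.Softplus())
    model = CalibratedPredictor(F=F, G=G, task="classification",
                                config=LbcConfig(), n_outputs=K, latent_dim=d)
    cfg = CFConfig(eta1=0.5, eta2=0.5, eta3=0.2, tau=0.05)
    from tracecf.lbc import labels_to_logits
    for _ in range(20):
        z = rng.standard_normal(d)
        z_hat = rng.standard_normal(d)
        yb = labels_to_logits(int(rng.integers(0, K)), K, 0.01)
        y_hat = F.forward(z_hat[None])[0]
        delta = G.forward(z_hat[None])[0]
        expected = cfg.eta1 * np.sum((z - z_hat) ** 2) + cfg.eta3 * delta.sum()
        for k in range(K):
            expected += cfg.eta2 * max(0.0, (y_hat[k] - delta[k]) - yb[k] + cfg.tau)
            expected += cfg.eta2 * max(0.0, yb[k] - (y_hat[k] + delta[k]) + cfg.tau)
        got = trace_cf_objective(z_hat, z, model, yb, cfg)
        assert got == pytest.approx(expected, abs=1e-9)


def test_trace_optimizer_descends_its_own_objective():
    """The optimizer's trajectory starts at the query's objective value and
    the returned iterate strictly improves it when the hypothesis is not
    yet satisfied."""
    rng = np.random.default_rng(3)
    d = 5
    F = nn.mlp([d, 8, 1], rng, activation="elu")
    G = nn.mlp([d, 8, 1], rng, activation="relu", out_layer=nn.Softplus())
    model = CalibratedPredictor(F=F, G=G, task="regression", config=LbcConfig(),
                                n_outputs=1, latent_dim=d)
    cfg = CFConfig(eta1=0.4, eta2=0.8, eta3=0.3, tau=0.05, steps=60)
    z = rng.standard_normal(d)
    base_obj = trace_cf_objective(z, z, model, 5.0, cfg)
    r = generate_trace(z.copy(), 5.0, model, None, cfg)
    assert r.trajectory[0]["objective"] == pytest.approx(base_obj, abs=1e-12)
    final = trace_cf_objective(r.z_bar, z, model, 5.0, cfg)
    assert final < base_obj


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def clf_setup():
    z, labels = _latent_problem(seed=0)
    from tracecf.lbc import train_lbc
    lbc = train_lbc(z, labels, "classification",
                    LbcConfig(f_hidden=(32, 32), g_hidden=(32, 32), epochs=60),
                    seed=0)
    clf = train_softmax_classifier(z, labels, seed=0)
    return z, labels, lbc, clf


def test_trace_descends_toward_the_hypothesis(clf_setup):
    z, labels, lbc, _ = clf_setup
    for i in np.flatnonzero(labels == 0)[:10]:
        r = generate_trace(z[i], 1, lbc, None, CFConfig())
        traj = [t["objective"] for t in r.trajectory]
        assert min(traj) <= traj[0] + 1e-9
        # best-iterate contract: returned latent attains the trajectory minimum
        from tracecf.counterfactual import trace_cf_objective
        assert trace_cf_objective(r.z_bar, z[i], lbc, 1, CFConfig()) == \
            pytest.approx(min(traj), abs=1e-9)


def test_trace_deterministic(clf_setup):
    z, labels, lbc, _ = clf_setup
    i = int(np.flatnonzero(labels == 0)[0])
    a = generate_trace(z[i], 1, lbc, None, CFConfig())
    b = generate_trace(z[i], 1, lbc, None, CFConfig())
    np.testing.assert_array_equal(a.z_bar, b.z_bar)


def test_huge_proximity_weight_pins_the_latent(clf_setup):
    z, labels, lbc, clf = clf_setup
    i = int(np.flatnonzero(labels == 0)[0])
    r = generate_trace(z[i], 1, lbc, None, CFConfig(eta1=1e6, steps=100))
    assert r.displacement < 0.05
    rv = generate_vanilla(z[i], 1, clf, None, CFConfig(eta1=1e6, steps=100))
    assert rv.displacement < 0.05


def test_vanilla_descends(clf_setup):
    z, labels, _, clf = clf_setup
    i = int(np.flatnonzero(labels == 0)[1])
    r = generate_vanilla(z[i], 1, clf, None, CFConfig())
    assert r.trajectory[-1]["objective"] <= r.trajectory[0]["objective"] + 1e-9


def test_singleton_sweep_equals_generate_trace(clf_setup):
    z, labels, lbc, _ = clf_setup
    i = int(np.flatnonzero(labels == 0)[2])
    single = progressive_sweep(z[i], 1, lbc, None, [0.5])
    direct = generate_trace(z[i], 1, lbc, None, CFConfig(eta1=0.5))
    np.testing.assert_array_equal(single[0].z_bar, direct.z_bar)
    with pytest.raises(ValueError):
        progressive_sweep(z[i], 1, lbc, None, [])
    with pytest.raises(ValueError):
        progressive_sweep(z[i], 1, lbc, None, [0.1, 0.5])


# ---------------------------------------------------------------------------
# Gaussian-calibrated generators and providers
# ---------------------------------------------------------------------------


def test_single_member_ensemble_is_deterministic(clf_setup):
    z, labels, _, _ = clf_setup
    members = train_ensemble(z, labels, M=1, seed=0)
    prov = EnsembleProvider(members)
    i = int(np.flatnonzero(labels == 0)[0])
    a = generate_gaussian_calibrated(z[i], 1, prov, None, CFConfig(steps=80))
    b = generate_gaussian_calibrated(z[i], 1, prov, None, CFConfig(steps=80))
    np.testing.assert_array_equal(a.z_bar, b.z_bar)
    mu, var = prov.mean_var(z[i])
    assert np.all(var == 0.0)  # M=1: degenerate ensemble, floored in the objective


def test_constant_variance_reduces_to_squared_error(clf_setup):
    """With sigma^2 constant, the Gaussian objective's minimizer coincides
    with a plain squared-error objective's on the same problem."""
    z, labels, _, _ = clf_setup

    class ConstVar:
        def __init__(self, members, var):
            self.inner = EnsembleProvider(members)
            self.var = var

        def mean_var(self, z_hat):
            mu, _ = self.inner.mean_var(z_hat)
            return mu, np.full_like(mu, self.var)

        def backprop(self, z_hat, d_mu, d_var):
            return self.inner.backprop(z_hat, d_mu, np.zeros_like(d_var))

    members = train_ensemble(z, labels, M=1, seed=0)
    i = int(np.flatnonzero(labels == 0)[0])
    cfg = CFConfig(steps=120)
    a = generate_gaussian_calibrated(z[i], 1, ConstVar(members, 0.5), None, cfg)

    # Gaussian NLL with sigma^2 = 0.5 equals the plain squared-error data term
    # (y_bar - mu)^2 up to an additive constant, so an explicit squared-error
    # descent with the same optimizer must land on the same iterate.
    from tracecf.counterfactual import _optimize_latent
    from tracecf.lbc import labels_to_logits
    prov = ConstVar(members, 0.5)
    yb = labels_to_logits(1, 2)
    z0 = z[i]

    def se_step(z_hat):
        mu, _ = prov.mean_var(z_hat)
        obj = cfg.eta1 * np.sum((z0 - z_hat) ** 2) + cfg.eta2 * np.sum((yb - mu) ** 2)
        d_mu = cfg.eta2 * 2.0 * (mu - yb)
        g = prov.backprop(z_hat, d_mu, np.zeros_like(mu)) \
            + 2.0 * cfg.eta1 * (z_hat - z0)
        return obj, g, {}

    z_se, _ = _optimize_latent(z0, se_step, cfg)
    np.testing.assert_allclose(a.z_bar, z_se, atol=1e-8)


def test_dropout_provider_variance_and_fixed_masks(clf_setup):
    z, labels, _, _ = clf_setup
    clf = train_softmax_classifier(z, labels,
                                   ClassifierConfig(dropout=0.3, epochs=30),
                                   seed=1)
    prov = DropoutProvider(clf, T=5, seed=0)
    mu1, var1 = prov.mean_var(z[0])
    mu2, var2 = prov.mean_var(z[0])
    np.testing.assert_array_equal(mu1, mu2)  # masks are frozen
    assert var1.max() > 0.0  # distinct masks disagree

    # provider gradient vs finite differences of the Gaussian data term
    yb = np.array([1.0, -1.0])
    cfg = CFConfig(eta1=0.0, eta2=1.0, steps=1)

    def data_term(zz):
        mu, var = prov.mean_var(zz)
        var = np.maximum(var, cfg.var_floor)
        return float(np.sum((yb - mu) ** 2 / (2 * var) + 0.5 * np.log(var)))

    mu, raw = prov.mean_var(z[0])
    var = np.maximum(raw, cfg.var_floor)
    d_mu = (mu - yb) / var
    d_var = -(yb - mu) ** 2 / (2 * var ** 2) + 0.5 / var
    g = prov.backprop(z[0], d_mu, d_var)
    eps = 1e-6
    for i in range(3):
        zp, zm = z[0].copy(), z[0].copy()
        zp[i] += eps
        zm[i] -= eps
        num = (data_term(zp) - data_term(zm)) / (2 * eps)
        assert num == pytest.approx(g[i], rel=1e-4, abs=1e-6)


def test_dropout_provider_requires_dropout_net(clf_setup):
    z, labels, _, clf = clf_setup
    with pytest.raises(ValueError):
        DropoutProvider(clf, T=5)


# ---------------------------------------------------------------------------
# baseline trainers
# ---------------------------------------------------------------------------


def test_mixup_label_arithmetic():
    a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    assert np.allclose(0.5 * a + 0.5 * b, [0.5, 0.5])
    assert np.allclose(1.0 * a + 0.0 * b, a)


def test_mixup_tempers_confidence(clf_setup):
    z, labels, _, _ = clf_setup
    held_z, held_y = _latent_problem(seed=5)
    plain = train_softmax_classifier(z, labels, seed=2)
    mixed = train_mixup_classifier(z, labels, beta_param=0.2, seed=2)
    p_plain = plain.probabilities(held_z).max(axis=1).mean()
    p_mixed = mixed.probabilities(held_z).max(axis=1).mean()
    assert p_mixed <= p_plain
    with pytest.raises(ValueError):
        train_mixup_classifier(z, labels, beta_param=0.0)


def test_bhattacharyya_identical_distributions():
    p = np.array([0.2, 0.3, 0.5])
    assert bhattacharyya_coefficient(p, p) == pytest.approx(1.0, abs=1e-12)
    q = np.array([0.5, 0.3, 0.2])
    assert bhattacharyya_coefficient(p, q) < 1.0
    # identical passes -> alpha = 1 - mean BC = 0 -> pure cross entropy
    assert 1.0 - bhattacharyya_coefficient(p, p) == pytest.approx(0.0, abs=1e-12)


def test_kl_from_uniform_zero_iff_uniform():
    K = 4
    u = np.full(K, 1.0 / K)

    def kl_u(p):
        return float(np.sum(u * np.log(u / p)))

    assert kl_u(u) == pytest.approx(0.0, abs=1e-12)
    assert kl_u(np.array([0.7, 0.1, 0.1, 0.1])) > 0.0


def test_uwcc_trains_and_validates(clf_setup):
    z, labels, _, _ = clf_setup
    m = train_uwcc_classifier(z, labels, T=3,
                              config=ClassifierConfig(dropout=0.2, epochs=20),
                              seed=0)
    acc = (m.probabilities(z).argmax(axis=1) == labels).mean()
    assert acc > 0.9
    with pytest.raises(ValueError):
        train_uwcc_classifier(z, labels, T=1)


def test_invalid_cf_config():
    with pytest.raises(ValueError):
        CFConfig(eta1=-0.1)
    with pytest.raises(ValueError):
        CFConfig(steps=0)
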