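"""Latent-space counterfactual generation: the calibration-driven (TraCE)
objective and the uncertainty-aware baseline objectives.

All generators share the same skeleton: starting from the query's latent
code z, gradient-descend (Adam) an objective over a free latent z_hat, then
decode the best iterate.  They differ only in the data term:

* TraCE: eta1 ||z - z_hat||^2 + eta2 * hinge(y_hat, delta, y_bar) + eta3 * delta,
  with y_hat = F(z_hat), delta = G(z_hat) from a calibrated (LbC) predictor.
  The hinge vanishes once the hypothesis y_bar lies inside the margin-shrunk
  prediction interval, and the eta3 term penalizes arbitrarily wide intervals.
* Vanilla (also used for mixup- and UWCC-trained classifiers):
  eta1 ||z - z_hat||^2 + eta2 * CrossEntropy(softmax(F(z_hat)), y_bar).
* Gaussian-calibrated (MC dropout / deep ensembles):
  eta1 ||z - z_hat||^2 + eta2 * [ (y_bar - mu)^2 / (2 sigma^2) + 0.5 log sigma^2 ],
  where (mu, sigma^2) come from T stochastic forward passes or M ensemble
  members aggregating logits.

Classification hypotheses are encoded as logit targets (the same encoding
LbC trains on), with hinge and interval terms summed over the K outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .lbc import CalibratedPredictor, labels_to_logits
from .wae import WAEModel, decode

__all__ = [
    "CFConfig", "CounterfactualResult", "SoftmaxClassifier", "ClassifierConfig",
    "trace_cf_objective", "generate_trace", "progressive_sweep",
    "generate_vanilla", "generate_gaussian_calibrated",
    "train_softmax_classifier", "train_mixup_classifier", "train_uwcc_classifier",
    "train_ensemble", "DropoutProvider", "EnsembleProvider",
]


@dataclass(frozen=True)
class CFConfig:
    """Weights and optimizer settings for counterfactual optimization."""

    eta1: float = 0.5
    eta2: float = 0.5
    eta3: float = 0.2
    tau: float = 0.05
    steps: int = 300
    lr: float = 0.05
    early_stop: bool = True  # stop once the hinge is 0 and delta has plateaued
    plateau_tol: float = 1e-4
    plateau_window: int = 10
    var_floor: float = 1e-6  # sigma^2 floor for the Gaussian objectives

    def __post_init__(self):
        if min(self.eta1, self.eta2, self.eta3) < 0:
            raise ValueError("eta weights must be nonnegative")
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")


@dataclass
class CounterfactualResult:
    z: np.ndarray                 # query latent
    z_bar: np.ndarray             # optimized latent (best iterate)
    x_bar: np.ndarray | None      # decoded image (None if no decoder given)
    trajectory: list = field(repr=False)  # per-step {step, objective, ...}
    y_hat: np.ndarray | None = None       # achieved prediction at z_bar
    delta: np.ndarray | None = None       # achieved interval at z_bar (TraCE)

    @property
    def displacement(self) -> float:
        return float(np.linalg.norm(self.z_bar - self.z))


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def _encode_target(model: CalibratedPredictor, y_bar) -> np.ndarray:
    """Map a hypothesis to the model's internal output scale."""
    if model.task == "classification":
        y = np.asarray(y_bar, dtype=np.float64)
        if y.ndim == 0:  # class index -> logit encoding
            y = labels_to_logits(int(y), model.n_outputs, model.config.eps_negative)
        if y.shape != (model.n_outputs,):
            raise ValueError(f"target shape {y.shape} does not match K={model.n_outputs}")
        return y
    y = float(np.asarray(y_bar))
    return np.array([(y - model.target_mean) / model.target_std])


def _hinge_terms(y_hat, delta, y_bar, tau):
    lower = np.maximum(0.0, (y_hat - delta) - y_bar + tau)
    upper = np.maximum(0.0, y_bar - (y_hat + delta) + tau)
    return lower, upper


def trace_cf_objective(z_hat: np.ndarray, z: np.ndarray, model: CalibratedPredictor,
                       y_bar, config: CFConfig | None = None) -> float:
    """Calibration-driven counterfactual objective at a candidate latent.

    eta1 ||z - z_hat||_2^2 + eta2 * sum_k hinge_k + eta3 * sum_k delta_k,
    with y_hat = F(z_hat) and delta = G(z_hat).
    """
    cfg = config or CFConfig()
    z_hat = np.asarray(z_hat, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    yb = _encode_target(model, y_bar)
    y_hat = model.F.forward(z_hat[None, :])[0]
    delta = model.G.forward(z_hat[None, :])[0]
    lower, upper = _hinge_terms(y_hat, delta, yb, cfg.tau)
    return float(cfg.eta1 * np.sum((z - z_hat) ** 2)
                 + cfg.eta2 * np.sum(lower + upper)
                 + cfg.eta3 * np.sum(delta))


# ---------------------------------------------------------------------------
# shared Adam-on-latent loop
# ---------------------------------------------------------------------------


def _optimize_latent(z0: np.ndarray, step_fn, cfg: CFConfig,
                     stop_fn=None) -> tuple[np.ndarray, list]:
    """Adam-descend an objective over the latent; return best iterate + path.

    ``step_fn(z_hat)`` returns (objective, gradient, info-dict); the best
    iterate is the *earliest* step attaining the minimum objective.
    """
    z_hat = z0.astype(np.float64).copy()
    m = np.zeros_like(z_hat)
    v = np.zeros_like(z_hat)
    best_obj, best_z = np.inf, z_hat.copy()
    trajectory: list[dict] = []
    plateau: list[float] = []
    for step in range(cfg.steps):
        obj, grad, info = step_fn(z_hat)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"counterfactual objective became non-finite at step {step}")
        trajectory.append({"step": step, "objective": float(obj), **info})
        if obj < best_obj - 1e-12:
            best_obj, best_z = obj, z_hat.copy()
        if stop_fn is not None and stop_fn(info, plateau):
            break
        m = 0.9 * m + 0.1 * grad
        v = 0.999 * v + 0.001 * grad ** 2
        t = step + 1
        z_hat = z_hat - cfg.lr * (m / (1 - 0.9 ** t)) / (
            np.sqrt(v / (1 - 0.999 ** t)) + 1e-8)
    return best_z, trajectory


def generate_trace(z: np.ndarray, y_bar, model: CalibratedPredictor,
                   wae: WAEModel | None = None,
                   config: CFConfig | None = None) -> CounterfactualResult:
    """Generate a counterfactual under the calibration-driven objective."""
    cfg = config or CFConfig()
    z = np.asarray(z, dtype=np.float64)
    yb = _encode_target(model, y_bar)

    def step_fn(z_hat):
        y_hat = model.F.forward(z_hat[None, :])[0]
        delta = model.G.forward(z_hat[None, :])[0]
        lower, upper = _hinge_terms(y_hat, delta, yb, cfg.tau)
        hinge = float(np.sum(lower + upper))
        obj = (cfg.eta1 * np.sum((z - z_hat) ** 2) + cfg.eta2 * hinge
               + cfg.eta3 * np.sum(delta))
        d_yhat = cfg.eta2 * ((lower > 0).astype(float) - (upper > 0).astype(float))
        d_delta = cfg.eta2 * (-(lower > 0).astype(float) - (upper > 0).astype(float)) \
            + cfg.eta3
        gz = model.F.backward(d_yhat[None, :])[0] + model.G.backward(d_delta[None, :])[0]
        gz = gz + 2.0 * cfg.eta1 * (z_hat - z)
        return obj, gz, {"hinge": hinge, "delta_sum": float(np.sum(delta)),
                         "y_hat": y_hat.tolist()}

    def stop_fn(info, plateau):
        if not cfg.early_stop:
            return False
        plateau.append(info["delta_sum"])
        if info["hinge"] > 0:
            plateau.clear()
            return False
        if len(plateau) < cfg.plateau_window:
            return False
        return max(plateau[-cfg.plateau_window:]) - \
            min(plateau[-cfg.plateau_window:]) < cfg.plateau_tol

    z_bar, traj = _optimize_latent(z, step_fn, cfg, stop_fn)
    y_hat = model.F.forward(z_bar[None, :])[0]
    delta = model.G.forward(z_bar[None, :])[0]
    x_bar = decode(wae, z_bar) if wae is not None else None
    return CounterfactualResult(z=z, z_bar=z_bar, x_bar=x_bar, trajectory=traj,
                                y_hat=y_hat, delta=delta)


def progressive_sweep(z: np.ndarray, y_bar, model: CalibratedPredictor,
                      wae: WAEModel | None, eta1_grid,
                      config: CFConfig | None = None) -> list[CounterfactualResult]:
    """One counterfactual per eta1, relaxing the proximity weight.

    A strictly decreasing eta1 grid progressively frees the optimizer to move
    further from the query, tracing the transition toward the hypothesis class.
    """
    grid = list(eta1_grid)
    if len(grid) == 0:
        raise ValueError("eta1_grid must be non-empty")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("eta1_grid must be strictly decreasing")
    cfg = config or CFConfig()
    return [generate_trace(z, y_bar, model, wae, replace(cfg, eta1=float(e)))
            for e in grid]


# ---------------------------------------------------------------------------
# plain softmax classifiers (vanilla / mixup / UWCC / ensembles)
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    hidden: tuple = (64, 64)
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.0


@dataclass
class SoftmaxClassifier:
    net: nn.Sequential
    n_classes: int
    latent_dim: int
    config: ClassifierConfig

    def logits(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        return self.net.forward(z)

    def probabilities(self, z: np.ndarray) -> np.ndarray:
        p = nn.softmax(self.logits(z), axis=1)
        return p[0] if np.asarray(z).ndim == 1 else p


def _build_classifier(d: int, K: int, cfg: ClassifierConfig,
                      rng: np.random.Generator) -> nn.Sequential:
    return nn.mlp([d, *cfg.hidden, K], rng, activation="relu", dropout=cfg.dropout)


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((len(labels), K))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_softmax_classifier(latents: np.ndarray, labels: np.ndarray,
                             config: ClassifierConfig | None = None,
                             seed: int = 0,
                             sample_idx: np.ndarray | None = None) -> SoftmaxClassifier:
    """Cross-entropy training with no calibration (the Vanilla baseline).

    ``sample_idx`` restricts training to a subset/bootstrap of the data
    (used by the deep-ensemble trainer).
    """
    cfg = config or ClassifierConfig()
    z = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1
    if sample_idx is not None:
        z, labels = z[sample_idx], labels[sample_idx]
    rng = np.random.default_rng(seed)
    net = _build_classifier(z.shape[1], K, cfg, rng)
    net.set_dropout_rng(rng)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    onehot = _one_hot(labels, K)
    n = len(z)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            logits = net.forward(z[idx], train=True)
            p = nn.softmax(logits, axis=1)
            opt.zero_grad()
            net.backward((p - onehot[idx]) / len(idx))
            opt.step()
    return SoftmaxClassifier(net=net, n_classes=K, latent_dim=z.shape[1], config=cfg)


def train_mixup_classifier(latents: np.ndarray, labels: np.ndarray,
                           beta_param: float = 0.2,
                           config: ClassifierConfig | None = None,
                           seed: int = 0) -> SoftmaxClassifier:
    """Mixup training: each batch is replaced by convex combinations of random
    pairs of (latent, one-hot label), with weights from a symmetric Beta."""
    if beta_param <= 0:
        raise ValueError(f"beta_param must be > 0, got {beta_param}")
    cfg = config or ClassifierConfig()
    z = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    net = _build_classifier(z.shape[1], K, cfg, rng)
    net.set_dropout_rng(rng)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    onehot = _one_hot(labels, K)
    n = len(z)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            jdx = rng.permutation(idx)
            lam = rng.beta(beta_param, beta_param, size=(len(idx), 1))
            zb = lam * z[idx] + (1 - lam) * z[jdx]
            yb = lam * onehot[idx] + (1 - lam) * onehot[jdx]
            logits = net.forward(zb, train=True)
            p = nn.softmax(logits, axis=1)
            opt.zero_grad()
            net.backward((p - yb) / len(idx))
            opt.step()
    return SoftmaxClassifier(net=net, n_classes=K, latent_dim=z.shape[1], config=cfg)


def bhattacharyya_coefficient(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """BC(p, q) = sum_k sqrt(p_k q_k) over the last axis; 1 iff p = q."""
    return np.sqrt(np.asarray(p) * np.asarray(q)).sum(axis=-1)


def train_uwcc_classifier(latents: np.ndarray, labels: np.ndarray, T: int = 5,
                          config: ClassifierConfig | None = None,
                          seed: int = 0) -> SoftmaxClassifier:
    """Uncertainty-weighted confidence calibration.

    Per sample the loss is (1 - a_i) * CE + a_i * KL(U || p_i), where p_i is
    the mean softmax over T dropout passes and a_i = 1 - mean Bhattacharyya
    coefficient between each pass and the mean (clipped to [0, 1]); identical
    passes give a_i = 0, i.e. plain cross entropy.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    cfg = config or ClassifierConfig()
    if cfg.dropout <= 0.0:
        cfg = replace(cfg, dropout=0.2)
    z = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    K = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    net = _build_classifier(z.shape[1], K, cfg, rng)
    drop_layers = net.dropout_layers()
    opt = nn.Adam(net.params(), lr=cfg.lr)
    onehot = _one_hot(labels, K)
    n = len(z)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            zb, yb = z[idx], onehot[idx]
            # T stochastic passes with recorded masks
            masks, probs = [], []
            for _t in range(T):
                net.set_dropout_rng(rng)
                for l in drop_layers:
                    l.mask_override = None
                logits = net.forward(zb, train=True)
                masks.append([l._mask for l in drop_layers])
                probs.append(nn.softmax(logits, axis=1))
            probs = np.stack(probs)          # (T, n, K)
            p_mean = probs.mean(axis=0)
            bc = bhattacharyya_coefficient(probs, p_mean[None]).mean(axis=0)
            a = np.clip(1.0 - bc, 0.0, 1.0)[:, None]  # treated as constant

            # dL/dp_mean for (1-a)*CE(p_mean, y) + a*KL(U || p_mean)
            d_pmean = -(1.0 - a) * yb / np.maximum(p_mean, 1e-12) \
                - a * (1.0 / K) / np.maximum(p_mean, 1e-12)
            d_pmean /= len(idx)
            opt.zero_grad()
            for t_i in range(T):
                for l, mask in zip(drop_layers, masks[t_i]):
                    l.mask_override = mask
                logits = net.forward(zb, train=True)
                p_t = nn.softmax(logits, axis=1)
                g = d_pmean / T
                d_logits = p_t * (g - (p_t * g).sum(axis=1, keepdims=True))
                net.backward(d_logits)
            for l in drop_layers:
                l.mask_override = None
            opt.step()
    return SoftmaxClassifier(net=net, n_classes=K, latent_dim=z.shape[1], config=cfg)


def train_ensemble(latents: np.ndarray, labels: np.ndarray, M: int = 5,
                   config: ClassifierConfig | None = None,
                   seed: int = 0) -> list[SoftmaxClassifier]:
    """M independently initialized classifiers trained on bootstrap resamples."""
    rng = np.random.default_rng(seed)
    n = len(latents)
    members = []
    for m in range(M):
        idx = rng.integers(0, n, size=n) if M > 1 else np.arange(n)
        members.append(train_softmax_classifier(
            latents, labels, config, seed=int(rng.integers(0, 2**31 - 1)),
            sample_idx=idx))
    return members


# ---------------------------------------------------------------------------
# vanilla / Gaussian-calibrated generators
# ---------------------------------------------------------------------------


def generate_vanilla(z: np.ndarray, y_bar_class: int, classifier: SoftmaxClassifier,
                     wae: WAEModel | None = None,
                     config: CFConfig | None = None) -> CounterfactualResult:
    """Cross-entropy counterfactual for an uncalibrated softmax classifier."""
    cfg = config or CFConfig()
    z = np.asarray(z, dtype=np.float64)
    k = int(y_bar_class)
    if not 0 <= k < classifier.n_classes:
        raise ValueError(f"class index {k} out of range")

    def step_fn(z_hat):
        logits = classifier.net.forward(z_hat[None, :])
        p = nn.softmax(logits, axis=1)
        ce = -float(np.log(max(p[0, k], 1e-12)))
        obj = cfg.eta1 * np.sum((z - z_hat) ** 2) + cfg.eta2 * ce
        d_logits = p.copy()
        d_logits[0, k] -= 1.0
        gz = classifier.net.backward(cfg.eta2 * d_logits)[0]
        gz = gz + 2.0 * cfg.eta1 * (z_hat - z)
        return obj, gz, {"p_target": float(p[0, k])}

    z_bar, traj = _optimize_latent(z, step_fn, cfg)
    y_hat = classifier.logits(z_bar)[0]
    x_bar = decode(wae, z_bar) if wae is not None else None
    return CounterfactualResult(z=z, z_bar=z_bar, x_bar=x_bar, trajectory=traj,
                                y_hat=y_hat)


class DropoutProvider:
    """(mu, sigma^2) of the logits over T fixed-mask dropout passes."""

    def __init__(self, classifier: SoftmaxClassifier, T: int = 5, seed: int = 0):
        if classifier.config.dropout <= 0.0:
            raise ValueError("DropoutProvider needs a dropout-trained classifier")
        self.classifier = classifier
        self.T = T
        self._drop = classifier.net.dropout_layers()
        rng = np.random.default_rng(seed)
        d = classifier.latent_dim
        # Pre-sample one mask per pass per dropout layer on a (1, width) slab.
        widths = []
        h = np.zeros((1, d))
        for layer in classifier.net.layers:
            h = layer.forward(h, train=False)
            if isinstance(layer, nn.Dropout):
                widths.append(h.shape[1])
        self.masks = [[l.sample_mask((1, w), rng)
                       for l, w in zip(self._drop, widths)]
                      for _ in range(self.T)]

    def _pass(self, z_hat: np.ndarray, t: int) -> np.ndarray:
        for l, mask in zip(self._drop, self.masks[t]):
            l.mask_override = mask
        logits = self.classifier.net.forward(z_hat[None, :], train=True)
        return logits[0]

    def mean_var(self, z_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.stack([self._pass(z_hat, t) for t in range(self.T)])
        self._clear()
        return f.mean(axis=0), f.var(axis=0)

    def backprop(self, z_hat: np.ndarray, d_mu: np.ndarray,
                 d_var: np.ndarray) -> np.ndarray:
        f = np.stack([self._pass(z_hat, t) for t in range(self.T)])
        mu = f.mean(axis=0)
        gz = np.zeros_like(z_hat)
        for t in range(self.T):
            g_t = d_mu / self.T + d_var * 2.0 * (f[t] - mu) / self.T
            self._pass(z_hat, t)  # restore caches for this pass
            gz = gz + self.classifier.net.backward(g_t[None, :])[0]
        self._clear()
        return gz

    def _clear(self):
        for l in self._drop:
            l.mask_override = None


class EnsembleProvider:
    """(mu, sigma^2) of the logits across M deterministic ensemble members."""

    def __init__(self, members: list[SoftmaxClassifier]):
        if not members:
            raise ValueError("ensemble must have at least one member")
        self.members = members

    def mean_var(self, z_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.stack([m.net.forward(z_hat[None, :])[0] for m in self.members])
        return f.mean(axis=0), f.var(axis=0)

    def backprop(self, z_hat, d_mu, d_var):
        f = np.stack([m.net.forward(z_hat[None, :])[0] for m in self.members])
        mu = f.mean(axis=0)
        M = len(self.members)
        gz = np.zeros_like(z_hat)
        for t, member in enumerate(self.members):
            member.net.forward(z_hat[None, :])  # refresh caches
            g_t = d_mu / M + d_var * 2.0 * (f[t] - mu) / M
            gz = gz + member.net.backward(g_t[None, :])[0]
        return gz


def generate_gaussian_calibrated(z: np.ndarray, y_bar, provider,
                                 wae: WAEModel | None = None,
                                 config: CFConfig | None = None,
                                 target_encoder=None) -> CounterfactualResult:
    """Heteroscedastic-Gaussian counterfactual for MC-dropout / ensembles.

    ``y_bar`` may be a class index (encoded to logit targets via
    ``target_encoder`` or the default 2-class/eps=0.01 encoding) or an
    explicit per-output target vector.  The data term sums the Gaussian
    negative log-likelihood over outputs; sigma^2 is floored for stability.
    """
    cfg = config or CFConfig()
    z = np.asarray(z, dtype=np.float64)
    mu0, _ = provider.mean_var(z)
    K = len(mu0)
    yb = np.asarray(y_bar, dtype=np.float64)
    if yb.ndim == 0:
        if target_encoder is not None:
            yb = np.asarray(target_encoder(int(yb)), dtype=np.float64)
        else:
            yb = labels_to_logits(int(yb), K) if K >= 2 else np.array([float(yb)])
    if yb.shape != (K,):
        raise ValueError(f"target shape {yb.shape} does not match outputs ({K},)")

    def step_fn(z_hat):
        mu, raw_var = provider.mean_var(z_hat)
        var = np.maximum(raw_var, cfg.var_floor)
        data = float(np.sum((yb - mu) ** 2 / (2.0 * var) + 0.5 * np.log(var)))
        obj = cfg.eta1 * np.sum((z - z_hat) ** 2) + cfg.eta2 * data
        d_mu = cfg.eta2 * (mu - yb) / var
        d_var = np.where(raw_var > cfg.var_floor,
                         cfg.eta2 * (-(yb - mu) ** 2 / (2.0 * var ** 2)
                                     + 0.5 / var),
                         0.0)
        gz = provider.backprop(z_hat, d_mu, d_var) + 2.0 * cfg.eta1 * (z_hat - z)
        return obj, gz, {"mu": mu.tolist()}

    z_bar, traj = _optimize_latent(z, step_fn, cfg)
    y_hat, _ = provider.mean_var(z_bar)
    x_bar = decode(wae, z_bar) if wae is not None else None
    return CounterfactualResult(z=z, z_bar=z_bar, x_bar=x_bar, trajectory=traj,
                                y_hat=y_hat)
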