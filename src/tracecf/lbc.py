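"""Learn-by-Calibrating (LbC): interval-calibrated predictors on latent codes.

The predictor is a pair of networks sharing the same input space: F maps a
latent code to point estimates (logits for classification, a scalar for
regression) and G maps it to nonnegative interval half-widths delta, so the
model's prediction is the interval [y_hat - delta, y_hat + delta].  Training
alternates two objectives:

* G (parameters phi) minimizes the empirical interval calibration error
  sum_k | alpha - coverage_k |, where coverage_k is the fraction of targets
  falling inside their interval for output k and alpha is the requested
  confidence level.  The hard indicator is non-differentiable, so gradient
  steps use a product-of-sigmoids surrogate; all *reported* calibration
  numbers use the hard indicator.
* F (parameters theta) minimizes a hinge loss that is zero exactly when every
  target sits inside its margin-shrunk interval
  [y_hat - delta + tau, y_hat + delta - tau].

Classification is handled by encoding class labels as logits: every negative
class receives a small probability floor (default 0.01), the positive class
the remainder, and each probability p is mapped to log(p / (1 - p)).  The
calibration machinery then treats the K logits as continuous targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import nn

__all__ = [
    "LbcConfig", "IntervalPrediction", "CalibratedPredictor",
    "labels_to_logits", "interval_calibration_error", "hinge_interval_loss",
    "coverage", "train_lbc", "predict", "class_probabilities",
    "save_lbc", "load_lbc",
]


@dataclass
class LbcConfig:
    alpha: float = 0.9
    tau: float = 0.05
    eps_negative: float = 0.01
    f_hidden: tuple = (512, 1024, 256, 128, 64, 16)
    g_hidden: tuple = (512, 1024, 256, 128, 64)
    epochs: int = 150
    lr: float = 1e-3
    batch_size: int = 64
    surrogate_temperature: float = 10.0
    patience: int = 10  # epochs without validation improvement before stopping
    min_epochs: int = 30  # epochs before the patience rule may trigger
    val_fraction: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tau < 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not 0.0 < self.eps_negative < 1.0:
            raise ValueError(f"eps_negative must be in (0, 1), got {self.eps_negative}")


@dataclass
class IntervalPrediction:
    """Point estimate(s) with interval half-width(s): [y_hat - delta, y_hat + delta]."""

    y_hat: np.ndarray
    delta: np.ndarray


@dataclass
class CalibratedPredictor:
    F: nn.Sequential
    G: nn.Sequential
    task: str  # "classification" | "regression"
    config: LbcConfig
    n_outputs: int
    latent_dim: int
    target_mean: float = 0.0  # regression standardization
    target_std: float = 1.0
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def labels_to_logits(label: int | np.ndarray, K: int, eps_negative: float = 0.01) -> np.ndarray:
    """Encode class label(s) as a length-K logit vector.

    Negative classes get probability ``eps_negative``, the positive class
    1 - (K-1) * eps_negative (the probabilities sum to one), and each
    probability p maps elementwise to log(p / (1 - p)).
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not 0.0 < eps_negative < 1.0 / K:
        raise ValueError(f"eps_negative must be in (0, 1/K), got {eps_negative}")
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"label out of range for K={K}")
    p = np.full((len(labels), K), eps_negative)
    p[np.arange(len(labels)), labels] = 1.0 - (K - 1) * eps_negative
    logits = np.log(p / (1.0 - p))
    return logits[0] if np.isscalar(label) or np.asarray(label).ndim == 0 else logits


def _check_shapes(y_hat, delta, y):
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=np.float64))
    delta = np.atleast_2d(np.asarray(delta, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if not (y_hat.shape == delta.shape == y.shape):
        raise ValueError(f"shape mismatch: y_hat {y_hat.shape}, delta {delta.shape}, "
                         f"y {y.shape}")
    return y_hat, delta, y


def coverage(y_hat, delta, y) -> np.ndarray:
    """Hard-indicator per-output coverage: fraction of targets inside the interval."""
    y_hat, delta, y = _check_shapes(y_hat, delta, y)
    inside = (y_hat - delta <= y) & (y <= y_hat + delta)
    return inside.mean(axis=0)


def interval_calibration_error(y_hat, delta, y, alpha: float) -> float:
    """Empirical interval calibration error, summed over outputs (hard indicator)."""
    return float(np.abs(alpha - coverage(y_hat, delta, y)).sum())


def hinge_interval_loss(y_hat, delta, y, tau: float) -> float:
    """Mean-over-samples, summed-over-outputs two-sided hinge on the interval.

    Zero iff every target lies in the margin-shrunk interval
    [y_hat - delta + tau, y_hat + delta - tau].
    """
    y_hat, delta, y = _check_shapes(y_hat, delta, y)
    lower = np.maximum(0.0, (y_hat - delta) - y + tau)
    upper = np.maximum(0.0, y - (y_hat + delta) + tau)
    return float((lower + upper).mean(axis=0).sum())


def _smooth_coverage(y_hat, delta, y, t):
    """Product-of-sigmoids surrogate for the interval indicator, with d/d delta."""
    a = t * (y - (y_hat - delta))
    b = t * ((y_hat + delta) - y)
    sa, sb = nn.sigmoid(a), nn.sigmoid(b)
    c = sa * sb
    dc_ddelta = t * (sa * (1 - sa) * sb + sa * sb * (1 - sb))
    return c, dc_ddelta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_lbc(latents: np.ndarray, targets: np.ndarray, task: str,
              config: LbcConfig | None = None, seed: int = 0) -> CalibratedPredictor:
    """Fit the (F, G) pair by alternating calibration / hinge optimization.

    ``latents`` is (N, d); ``targets`` is class indices (classification) or
    real values (regression).  Regression targets are standardized internally
    and de-standardized at the prediction interface.
    """
    cfg = config or LbcConfig()
    z = np.asarray(latents, dtype=np.float64)
    targets = np.asarray(targets)
    if z.ndim != 2 or len(z) != len(targets):
        raise ValueError("latents must be (N, d) aligned with targets")
    if len(np.unique(targets)) < 2:
        raise ValueError("targets are degenerate: need >= 2 distinct values")
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")

    rng = np.random.default_rng(seed)
    mean, std = 0.0, 1.0
    if task == "classification":
        K = int(targets.max()) + 1
        y = labels_to_logits(targets.astype(int), K, cfg.eps_negative)
    else:
        K = 1
        mean = float(np.mean(targets))
        std = float(np.std(targets)) or 1.0
        y = ((targets.astype(np.float64) - mean) / std)[:, None]

    d = z.shape[1]
    F = nn.mlp([d, *cfg.f_hidden, K], rng, activation="elu")
    G = nn.mlp([d, *cfg.g_hidden, K], rng, activation="relu", out_layer=nn.Softplus())
    opt_f = nn.Adam(F.params(), lr=cfg.lr)
    opt_g = nn.Adam(G.params(), lr=cfg.lr)

    n = len(z)
    n_val = max(2, int(round(cfg.val_fraction * n)))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    zt, yt = z[tr_idx], y[tr_idx]
    zv, yv = z[val_idx], y[val_idx]
    n_tr = len(zt)
    bs = min(cfg.batch_size, n_tr)
    t = cfg.surrogate_temperature

    model = CalibratedPredictor(F=F, G=G, task=task, config=cfg, n_outputs=K,
                                latent_dim=d, target_mean=mean, target_std=std)
    best_val, stale = np.inf, 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_tr)
        # --- phi step: calibrate G against the (frozen) current F ----------
        for start in range(0, n_tr, bs):
            idx = perm[start:start + bs]
            zb, yb = zt[idx], yt[idx]
            y_hat = F.forward(zb)
            delta = G.forward(zb, train=True)
            c, dc_dd = _smooth_coverage(y_hat, delta, yb, t)
            cov_k = c.mean(axis=0)
            d_delta = (-np.sign(cfg.alpha - cov_k)[None, :] / len(idx)) * dc_dd
            opt_g.zero_grad()
            G.backward(d_delta)
            opt_g.step()
        # --- theta step: hinge on F with frozen G --------------------------
        for start in range(0, n_tr, bs):
            idx = perm[start:start + bs]
            zb, yb = zt[idx], yt[idx]
            delta = G.forward(zb)
            y_hat = F.forward(zb, train=True)
            lower_on = (y_hat - delta) - yb + cfg.tau > 0
            upper_on = yb - (y_hat + delta) + cfg.tau > 0
            d_yhat = (lower_on.astype(float) - upper_on.astype(float)) / len(idx)
            opt_f.zero_grad()
            F.backward(d_yhat)
            opt_f.step()

        yv_hat = F.forward(zv)
        dv = G.forward(zv)
        val_hinge = hinge_interval_loss(yv_hat, dv, yv, cfg.tau)
        model.history.append({
            "epoch": epoch,
            "val_hinge": val_hinge,
            "val_coverage": float(coverage(yv_hat, dv, yv).mean()),
            "val_cal_error": interval_calibration_error(yv_hat, dv, yv, cfg.alpha),
            "mean_delta": float(dv.mean()),
        })
        # Convergence monitor: hinge alone rewards arbitrarily wide intervals
        # (it is smallest at initialization, where delta covers everything),
        # so stopping tracks hinge + calibration error, after a minimum
        # number of alternating rounds.
        val_score = val_hinge + model.history[-1]["val_cal_error"]
        if val_score < best_val - 1e-9:
            best_val, stale = val_score, 0
        else:
            stale += 1
            if epoch + 1 >= cfg.min_epochs and stale >= cfg.patience:
                break
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _as_codes(model: CalibratedPredictor, z: np.ndarray) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != model.latent_dim:
        raise ValueError(f"latent dim {z.shape[1]} does not match model "
                         f"({model.latent_dim})")
    return z, single


def predict(model: CalibratedPredictor, z: np.ndarray) -> IntervalPrediction:
    """Interval prediction at latent code(s), on the original target scale."""
    zb, single = _as_codes(model, z)
    y_hat = model.F.forward(zb)
    delta = model.G.forward(zb)
    if model.task == "regression":
        y_hat = y_hat * model.target_std + model.target_mean
        delta = delta * model.target_std
    if single:
        return IntervalPrediction(y_hat=y_hat[0], delta=delta[0])
    return IntervalPrediction(y_hat=y_hat, delta=delta)


def class_probabilities(model: CalibratedPredictor, z: np.ndarray) -> np.ndarray:
    """Softmax of F's logits (classification models only)."""
    if model.task != "classification":
        raise ValueError("class_probabilities requires a classification model")
    zb, single = _as_codes(model, z)
    p = nn.softmax(model.F.forward(zb), axis=1)
    return p[0] if single else p


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_lbc(model: CalibratedPredictor, path) -> None:
    meta = {
        "task": model.task, "n_outputs": model.n_outputs,
        "latent_dim": model.latent_dim, "target_mean": model.target_mean,
        "target_std": model.target_std, "config": asdict(model.config),
    }
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps(meta)
        f.attrs["history"] = json.dumps(model.history)
        for name, seq in (("F", model.F), ("G", model.G)):
            g = f.create_group(name)
            for i, arr in enumerate(seq.state()):
                g.create_dataset(f"p{i:03d}", data=arr)


def load_lbc(path) -> CalibratedPredictor:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        cfgd = meta["config"]
        cfgd["f_hidden"] = tuple(cfgd["f_hidden"])
        cfgd["g_hidden"] = tuple(cfgd["g_hidden"])
        cfg = LbcConfig(**cfgd)
        rng = np.random.default_rng(0)
        F = nn.mlp([meta["latent_dim"], *cfg.f_hidden, meta["n_outputs"]], rng,
                   activation="elu")
        G = nn.mlp([meta["latent_dim"], *cfg.g_hidden, meta["n_outputs"]], rng,
                   activation="relu", out_layer=nn.Softplus())
        F.load_state([f["F"][k][...] for k in sorted(f["F"])])
        G.load_state([f["G"][k][...] for k in sorted(f["G"])])
        history = json.loads(f.attrs["history"])
    model = CalibratedPredictor(F=F, G=G, task=meta["task"], config=cfg,
                                n_outputs=meta["n_outputs"],
                                latent_dim=meta["latent_dim"],
                                target_mean=meta["target_mean"],
                                target_std=meta["target_std"])
    model.history = history
    return model
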