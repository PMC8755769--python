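"""Wasserstein autoencoder (WAE-MMD) over the synthetic radiograph scenes.

The autoencoder builds the low-dimensional continuous latent space that all
predictors and counterfactual optimizers in this package operate in.  The
encoder is a stack of stride-2 3x3 convolutions ([16, 32, 64, 32] filters)
followed by two fully connected layers down to the latent code; the decoder
mirrors it with two fully connected layers and four transposed convolutions,
ending in a sigmoid so every decoded image lies in [0, 1].

Training minimizes

    w1 * MSE(x, D(E(x))) + w2 * MMD^2(E(X), N(0, I)) + w3 * (1 - SSIM)

with the weight schedule (1, 0.5, 0) for an initial warm-up phase and
(1, 0.1, 1) afterwards.  The MMD term uses the unbiased two-sample estimator
with an inverse-multiquadratic kernel of scale 2 * latent_dim, pulling the
encoded distribution toward a standard normal prior so the latent space is
smooth and samplable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import nn
from .ssim import ssim as _ssim_pair, ssim_and_grad
from .synthetic import SyntheticDataset

__all__ = ["WAEConfig", "WAEModel", "mmd_penalty", "ssim", "train_wae",
           "encode", "decode", "encoder_features", "save_wae", "load_wae"]


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity between two images (Gaussian 11-pixel window)."""
    return _ssim_pair(a, b)


@dataclass
class WAEConfig:
    """Architecture and training schedule of the autoencoder.

    The convolution stack and fully connected widths follow the reference
    224x224 architecture; at other image sizes the depth is preserved and the
    decoder's wide fully connected layer is recomputed from the geometry
    (its printed width 6272 = 32 * 14 * 14 is specific to 224x224 inputs).
    """

    latent_dim: int = 100
    image_size: int = 64
    encoder_conv_filters: tuple = (16, 32, 64, 32)
    decoder_deconv_channels: tuple = (64, 32, 16, 1)
    fc_width: int = 512
    kernel: int = 3
    stride: int = 2
    epochs: int = 150
    batch_size: int = 64
    lr: float = 1e-3
    # epoch -> divide the *initial* lr by this factor from that epoch on
    lr_schedule: dict = field(default_factory=lambda: {30: 2.0, 50: 5.0, 100: 10.0})
    warmup_epochs: int = 20  # (mse, mmd, ssim) weights (1, .5, 0) before, (1, .1, 1) after
    weights_warmup: tuple = (1.0, 0.5, 0.0)
    weights_main: tuple = (1.0, 0.1, 1.0)

    def __post_init__(self):
        down = self.stride ** len(self.encoder_conv_filters)
        if self.image_size % down != 0:
            raise ValueError(
                f"image_size {self.image_size} must be divisible by {down} "
                f"(stride {self.stride}, {len(self.encoder_conv_filters)} conv layers)")

    @property
    def bottleneck_hw(self) -> int:
        return self.image_size // self.stride ** len(self.encoder_conv_filters)

    @property
    def bottleneck_size(self) -> int:
        return self.encoder_conv_filters[-1] * self.bottleneck_hw ** 2


@dataclass
class WAEModel:
    encoder: nn.Sequential
    decoder: nn.Sequential
    config: WAEConfig
    training_log: list = field(default_factory=list)


def _build_encoder(cfg: WAEConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in cfg.encoder_conv_filters:
        layers += [nn.Conv2d(c_in, c_out, rng, k=cfg.kernel, stride=cfg.stride, pad=1),
                   nn.ReLU()]
        c_in = c_out
    layers += [nn.Flatten(),
               nn.Dense(cfg.bottleneck_size, cfg.fc_width, rng, scale="he"), nn.ReLU(),
               nn.Dense(cfg.fc_width, cfg.latent_dim, rng)]
    return nn.Sequential(layers)


def _build_decoder(cfg: WAEConfig, rng: np.random.Generator) -> nn.Sequential:
    c0 = cfg.encoder_conv_filters[-1]
    hw = cfg.bottleneck_hw
    layers: list[nn.Layer] = [
        nn.Dense(cfg.latent_dim, cfg.fc_width, rng, scale="he"), nn.ReLU(),
        nn.Dense(cfg.fc_width, c0 * hw * hw, rng, scale="he"), nn.ReLU(),
        nn.Reshape((c0, hw, hw)),
    ]
    chain = (c0, *cfg.decoder_deconv_channels)
    for i in range(len(chain) - 1):
        layers.append(nn.ConvTranspose2d(chain[i], chain[i + 1], rng,
                                         k=cfg.kernel, stride=cfg.stride, pad=1))
        layers.append(nn.ReLU() if i < len(chain) - 2 else nn.Sigmoid())
    return nn.Sequential(layers)


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------


def _imq_kernel(sq_dists: np.ndarray, scale: float) -> np.ndarray:
    return scale / (scale + sq_dists)


def mmd_penalty(codes: np.ndarray, prior_samples: np.ndarray,
                kernel_scale: float | None = None) -> float:
    """Unbiased squared maximum mean discrepancy, inverse-multiquadratic kernel.

    ``kernel_scale`` defaults to 2 * latent_dim, the expected squared distance
    between two standard-normal prior draws.  Symmetric in its arguments; can
    be slightly negative (unbiased estimator).
    """
    x = np.asarray(codes, dtype=np.float64)
    y = np.asarray(prior_samples, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("need at least two samples per set for the unbiased estimator")
    c = 2.0 * x.shape[1] if kernel_scale is None else float(kernel_scale)

    dxx = _sq_dists(x, x)
    dyy = _sq_dists(y, y)
    dxy = _sq_dists(x, y)
    kxx = _imq_kernel(dxx, c)
    kyy = _imq_kernel(dyy, c)
    kxy = _imq_kernel(dxy, c)
    np.fill_diagonal(kxx, 0.0)
    np.fill_diagonal(kyy, 0.0)
    return float(kxx.sum() / (n * (n - 1)) + kyy.sum() / (m * (m - 1))
                 - 2.0 * kxy.mean())


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(1)
    bb = (b * b).sum(1)
    return np.maximum(aa[:, None] + bb[None, :] - 2.0 * a @ b.T, 0.0)


def _mmd_grad_codes(x: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """Gradient of the unbiased MMD^2 estimator w.r.t. the codes ``x``."""
    n, m = len(x), len(y)
    dxx = _sq_dists(x, x)
    dxy = _sq_dists(x, y)
    # d k / d ||d||^2 = -c / (c + d2)^2 ; d ||xi-xj||^2 / d xi = 2 (xi - xj)
    wxx = -c / (c + dxx) ** 2
    np.fill_diagonal(wxx, 0.0)
    wxy = -c / (c + dxy) ** 2
    diff_xx = x[:, None, :] - x[None, :, :]
    diff_xy = x[:, None, :] - y[None, :, :]
    g = (2.0 / (n * (n - 1))) * 2.0 * np.einsum("ij,ijd->id", wxx, diff_xx)
    g += (-2.0 / (n * m)) * 2.0 * np.einsum("ij,ijd->id", wxy, diff_xy)
    return g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_wae(dataset: SyntheticDataset | np.ndarray, config: WAEConfig | None = None,
              seed: int = 0) -> WAEModel:
    """Train the autoencoder on a dataset (or raw (n, H, W) image stack)."""
    images = dataset.images if isinstance(dataset, SyntheticDataset) else np.asarray(dataset)
    if len(images) == 0:
        raise ValueError("cannot train on an empty dataset")
    cfg = config or WAEConfig()
    if images.shape[1] != cfg.image_size:
        raise ValueError(f"images are {images.shape[1:]}, config expects "
                         f"{cfg.image_size}x{cfg.image_size}")
    x_all = images.astype(np.float32)[:, None, :, :]  # NCHW
    n = len(x_all)

    rng = np.random.default_rng(seed)
    enc = _build_encoder(cfg, rng)
    dec = _build_decoder(cfg, rng)
    opt = nn.Adam(enc.params() + dec.params(), lr=cfg.lr)

    model = WAEModel(encoder=enc, decoder=dec, config=cfg)
    bs = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        div = 1.0
        for at, factor in sorted(cfg.lr_schedule.items()):
            if epoch >= at:
                div = factor
        opt.lr = cfg.lr / div
        w1, w2, w3 = (cfg.weights_warmup if epoch < cfg.warmup_epochs
                      else cfg.weights_main)

        order = rng.permutation(n)
        ep = {"mse": 0.0, "mmd": 0.0, "ssim": 0.0, "total": 0.0, "nb": 0}
        for start in range(0, n - 1, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue
            x = x_all[idx]
            z = enc.forward(x, train=True)
            xr = dec.forward(z, train=True)

            npix = x[0].size
            diff = (xr - x).astype(np.float64)
            mse = float((diff ** 2).mean())
            d_xr = (2.0 * diff / (len(idx) * npix))

            prior = rng.standard_normal(z.shape)
            zf = z.astype(np.float64)
            mmd = mmd_penalty(zf, prior)
            dz_mmd = _mmd_grad_codes(zf, prior, 2.0 * cfg.latent_dim)

            ssim_val = 0.0
            d_xr_ssim = np.zeros_like(d_xr)
            if w3 > 0.0:
                for i in range(len(idx)):
                    s, g = ssim_and_grad(xr[i, 0].astype(np.float64),
                                         x[i, 0].astype(np.float64))
                    ssim_val += s / len(idx)
                    d_xr_ssim[i, 0] = -g / len(idx)  # minimize (1 - SSIM)
            total = w1 * mse + w2 * mmd + w3 * (1.0 - ssim_val)

            opt.zero_grad()
            dz = dec.backward((w1 * d_xr + w3 * d_xr_ssim).astype(np.float32))
            enc.backward(dz + (w2 * dz_mmd).astype(np.float32))
            opt.step()

            ep["mse"] += mse
            ep["mmd"] += mmd
            ep["ssim"] += ssim_val
            ep["total"] += total
            ep["nb"] += 1
        nb = max(ep.pop("nb"), 1)
        model.training_log.append(
            {"epoch": epoch, **{k: v / nb for k, v in ep.items()}})
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x)
    if x.ndim == 2:
        return x[None, None, :, :], True
    if x.ndim == 3:
        return x[:, None, :, :], False
    raise ValueError(f"expected (H, W) or (N, H, W) images, got shape {x.shape}")


def encode(model: WAEModel, x: np.ndarray) -> np.ndarray:
    """Map image(s) to latent code(s).  Deterministic; batch-consistent."""
    xb, single = _as_batch(x)
    if xb.shape[-1] != model.config.image_size:
        raise ValueError(f"image size {xb.shape[-1]} does not match config "
                         f"{model.config.image_size}")
    z = model.encoder.forward(xb.astype(np.float32), train=False)
    return z[0] if single else z


def decode(model: WAEModel, z: np.ndarray) -> np.ndarray:
    """Map latent code(s) to image(s) in [0, 1]."""
    z = np.asarray(z, dtype=np.float32)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(f"latent dim {z.shape[1]} does not match config "
                         f"{model.config.latent_dim}")
    x = model.decoder.forward(z, train=False)
    x = np.clip(x[:, 0], 0.0, 1.0)
    return x[0] if single else x


def encoder_features(model: WAEModel, x: np.ndarray) -> np.ndarray:
    """Final hidden activations of the encoder (the default realism features)."""
    xb, single = _as_batch(x)
    h = xb.astype(np.float32)
    for layer in model.encoder.layers[:-1]:  # stop before the latent head
        h = layer.forward(h, train=False)
    return h[0] if single else h


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_wae(model: WAEModel, path) -> None:
    cfg = asdict(model.config)
    cfg["lr_schedule"] = {str(k): v for k, v in cfg["lr_schedule"].items()}
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(cfg)
        f.attrs["log"] = json.dumps(model.training_log)
        for name, seq in (("encoder", model.encoder), ("decoder", model.decoder)):
            g = f.create_group(name)
            for i, arr in enumerate(seq.state()):
                g.create_dataset(f"p{i:03d}", data=arr)


def load_wae(path) -> WAEModel:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        cfg["lr_schedule"] = {int(k): v for k, v in cfg["lr_schedule"].items()}
        cfg["encoder_conv_filters"] = tuple(cfg["encoder_conv_filters"])
        cfg["decoder_deconv_channels"] = tuple(cfg["decoder_deconv_channels"])
        cfg["weights_warmup"] = tuple(cfg["weights_warmup"])
        cfg["weights_main"] = tuple(cfg["weights_main"])
        config = WAEConfig(**cfg)
        rng = np.random.default_rng(0)
        enc = _build_encoder(config, rng)
        dec = _build_decoder(config, rng)
        enc.load_state([f["encoder"][k][...] for k in sorted(f["encoder"])])
        dec.load_state([f["decoder"][k][...] for k in sorted(f["decoder"])])
        log = json.loads(f.attrs["log"])
    return WAEModel(encoder=enc, decoder=dec, config=config, training_log=log)
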