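"""Synthetic chest-radiograph-like scene generator.

Every experiment in this package runs on images from this module, so that the
whole pipeline — autoencoder, calibrated predictors, counterfactual
optimizers, metrics and the bias analyses — is testable end to end with no
external data.  The scenes emulate the statistical structure of a frontal
chest X-ray cohort:

* a torso ellipse on a dark background, whose aspect ratio is driven by a
  binary ``gender_proxy`` factor;
* two fixed elliptical lung fields, darker than the mediastinum, whose
  *opacity* (mean interior brightness) is driven by a continuous ``severity``
  factor in [0, 1] — the stand-in for pneumonia-like consolidation.  Images
  with severity >= 0.5 are labeled "abnormal";
* a rib-like sinusoidal texture on the torso outside the lung fields whose
  spatial frequency and contrast follow an ``age_proxy`` factor (years);
* an optional *nuisance* marker: a bright text-block-like rectangle stamped
  in the top-left corner, used to plant a classification shortcut.

The lung fields are fixed analytic ellipses in normalized coordinates, so
:func:`lung_mask` doubles as an exact oracle for where disease evidence
should appear, and :func:`severity_readout` (mean intensity inside the lung
mask) is a strictly increasing readout of the severity used to generate an
image.  Identical :class:`SceneParams` always produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneParams",
    "SyntheticDataset",
    "lung_mask",
    "corner_mask",
    "generate_image",
    "generate_dataset",
    "severity_readout",
    "save_dataset",
    "load_dataset",
    "export_png",
    "import_png",
]

# Normalized-coordinate geometry (fractions of image side).
_TORSO_CENTER = (0.5, 0.55)  # (x, y)
_TORSO_SEMI_Y = 0.40
_TORSO_SEMI_X = {0: 0.31, 1: 0.37}  # gender_proxy -> half-width
_LUNGS = [  # (cx, cy, rx, ry), fixed for all appearance factors
    (0.35, 0.47, 0.115, 0.20),
    (0.65, 0.47, 0.115, 0.20),
]
_BACKGROUND = 0.05
_TORSO_BASE = 0.45
_LUNG_BASE = 0.15
_SEVERITY_GAIN = 0.55  # peak added opacity at severity = 1


@dataclass(frozen=True)
class SceneParams:
    """Generative factors of one synthetic radiograph."""

    severity: float = 0.0
    age_proxy: float = 50.0
    gender_proxy: int = 0
    nuisance: bool = False
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if not 20.0 <= self.age_proxy <= 90.0:
            raise ValueError(f"age_proxy must be in [20, 90], got {self.age_proxy}")
        if self.gender_proxy not in (0, 1):
            raise ValueError(f"gender_proxy must be 0 or 1, got {self.gender_proxy}")
        if not isinstance(self.nuisance, (bool, np.bool_)):
            raise ValueError(f"nuisance must be boolean, got {self.nuisance!r}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")


@dataclass
class SyntheticDataset:
    """Images with labels and the generative factors that produced them."""

    images: np.ndarray  # (n, H, W) float in [0, 1]
    labels: np.ndarray  # (n,) int, 1 = abnormal
    attributes: pd.DataFrame = field(repr=False)  # severity, age_proxy, gender_proxy, nuisance

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.labels) == n and len(self.attributes) == n):
            raise ValueError("images, labels and attributes must be the same length")

    def __len__(self) -> int:
        return len(self.images)


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(size) + 0.5) / size
    return np.meshgrid(c, c)  # xx, yy with yy varying along rows


def lung_mask(size: int) -> np.ndarray:
    """Boolean mask of the two fixed elliptical lung fields."""
    xx, yy = _grid(size)
    m = np.zeros((size, size), dtype=bool)
    for cx, cy, rx, ry in _LUNGS:
        m |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    return m


def corner_mask(size: int) -> np.ndarray:
    """Boolean mask of the top-left nuisance text-block region.

    The block emulates an overlaid word: short (rows [2, size/8)) but wide
    (cols [2, size/2)), like a corner text banner burned into the image.
    """
    m = np.zeros((size, size), dtype=bool)
    m[2:size // 8, 2:size // 2] = True
    return m


def generate_image(params: SceneParams) -> np.ndarray:
    """Render one deterministic scene in [0, 1] from its generative factors."""
    size = params.image_size
    xx, yy = _grid(size)
    rng = np.random.default_rng(params.seed)

    cx, cy = _TORSO_CENTER
    rx = _TORSO_SEMI_X[int(params.gender_proxy)]
    torso = ((xx - cx) / rx) ** 2 + ((yy - cy) / _TORSO_SEMI_Y) ** 2 <= 1.0
    lungs = lung_mask(size)

    img = np.full((size, size), _BACKGROUND)
    img[torso] = _TORSO_BASE
    img[lungs] = _LUNG_BASE

    # Rib texture: horizontal sinusoid on the torso, outside the lung fields,
    # with frequency and contrast increasing in age_proxy.  Keeping it out of
    # the lung mask makes severity_readout exactly independent of age.
    a = (params.age_proxy - 20.0) / 70.0
    freq = 6.0 + 6.0 * a
    amp = 0.03 + 0.05 * a
    ribs = amp * np.sin(2.0 * np.pi * freq * yy)
    img[torso & ~lungs] += ribs[torso & ~lungs]

    # Opacity clouds: a seed-specific smooth positive field scaled by severity.
    cloud = gaussian_filter(rng.random((size, size)), sigma=size / 16.0)
    lo, hi = cloud.min(), cloud.max()
    cloud = (cloud - lo) / (hi - lo) if hi > lo else np.zeros_like(cloud)
    opacity = params.severity * _SEVERITY_GAIN * (0.6 + 0.4 * cloud)
    img[lungs] += opacity[lungs]

    # Mild smooth acquisition texture everywhere (seeded, severity-independent).
    img += 0.02 * (gaussian_filter(rng.standard_normal((size, size)), sigma=2.0))

    if params.nuisance:
        img[corner_mask(size)] = 0.95

    return np.clip(img, 0.0, 1.0)


def severity_readout(image: np.ndarray) -> float:
    """Mean intensity inside the lung fields — the analytic opacity oracle."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {image.shape}")
    return float(image[lung_mask(image.shape[0])].mean())


def generate_dataset(n: int, class_balance: float = 0.5,
                     nuisance_policy: str = "none", seed: int = 0,
                     image_size: int = 64,
                     age_severity_corr: float = 0.0) -> SyntheticDataset:
    """Sample a labeled cohort of synthetic radiographs.

    Parameters
    ----------
    n : number of images (>= 2).
    class_balance : target fraction of abnormal (severity >= 0.5) images.
    nuisance_policy : "none", or "abnormal_only" to stamp the corner marker on
        exactly the abnormal images (the shortcut-planting design).
    age_severity_corr : in [0, 1]; 0 leaves age independent of severity, 1
        makes age a deterministic function of severity.  Used by the
        attribute-relationship analyses to plant (or withhold) a correlation.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 <= class_balance <= 1.0:
        raise ValueError(f"class_balance must be in [0, 1], got {class_balance}")
    if nuisance_policy not in ("none", "abnormal_only"):
        raise ValueError(f"unknown nuisance_policy {nuisance_policy!r}")
    if not 0.0 <= age_severity_corr <= 1.0:
        raise ValueError(f"age_severity_corr must be in [0, 1], got {age_severity_corr}")

    rng = np.random.default_rng(seed)
    abnormal = rng.random(n) < class_balance
    u = rng.random(n)
    severity = np.where(abnormal, 0.5 + 0.5 * u, 0.4999 * u)
    u_age = (1.0 - age_severity_corr) * rng.random(n) + age_severity_corr * severity
    age = 20.0 + 70.0 * u_age
    gender = rng.integers(0, 2, size=n)
    if nuisance_policy == "abnormal_only":
        nuisance = abnormal.copy()
    else:
        nuisance = np.zeros(n, dtype=bool)
    seeds = rng.integers(0, 2**31 - 1, size=n)

    images = np.empty((n, image_size, image_size))
    for i in range(n):
        images[i] = generate_image(SceneParams(
            severity=float(severity[i]), age_proxy=float(age[i]),
            gender_proxy=int(gender[i]), nuisance=bool(nuisance[i]),
            image_size=image_size, seed=int(seeds[i])))
    labels = (severity >= 0.5).astype(int)
    attrs = pd.DataFrame({
        "severity": severity, "age_proxy": age,
        "gender_proxy": gender, "nuisance": nuisance, "seed": seeds,
    })
    return SyntheticDataset(images=images, labels=labels, attributes=attrs)


def heteroscedastic_regression(n: int, d: int = 10, seed: int = 0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic regression task with input-dependent noise, for calibration
    studies: y = w . z + eps, z ~ N(0, I_d), eps ~ N(0, (0.2 + 0.3 |z_1|)^2),
    with w fixed at linspace(0.5, -0.5, d).  Returns (z, y)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, d))
    w = np.linspace(0.5, -0.5, d)
    sigma = 0.2 + 0.3 * np.abs(z[:, 0])
    y = z @ w + sigma * rng.standard_normal(n)
    return z, y


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_dataset(ds: SyntheticDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images.astype(np.float32))
        f.create_dataset("labels", data=ds.labels)
        g = f.create_group("attributes")
        for col in ds.attributes.columns:
            g.create_dataset(col, data=ds.attributes[col].to_numpy())


def load_dataset(path) -> SyntheticDataset:
    with h5py.File(path, "r") as f:
        images = f["images"][...].astype(np.float64)
        labels = f["labels"][...]
        attrs = pd.DataFrame({k: f["attributes"][k][...] for k in f["attributes"]})
    return SyntheticDataset(images=images, labels=labels, attributes=attrs)


def export_png(image: np.ndarray, path) -> None:
    """8-bit grayscale PNG export (the only place intensities are quantized)."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    PILImage.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def import_png(path) -> np.ndarray:
    with PILImage.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0
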