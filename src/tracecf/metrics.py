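"""Evaluation metrics for counterfactual explanations.

Five per-counterfactual scores, each with a small brute-force-verifiable
kernel, plus batch aggregation:

* validity — fraction of counterfactuals achieving the desired class
  (categorical) or mean absolute percentage error to the desired value
  (continuous);
* confidence — softmax probability assigned to the desired class;
* sparsity — fraction of pixels altered beyond a change threshold
  (default one 8-bit quantization step, since "altered at all" is ill-posed
  in floating point);
* proximity — mean latent-space L2 distance from the counterfactual to its
  K nearest training samples;
* realism — manifold-closeness score: the max over real feature vectors of
  the ratio between their own K-th-neighbor distance and their distance to
  the generated sample.  High near the data manifold, decaying off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .lbc import CalibratedPredictor, class_probabilities
from .wae import WAEModel, encode, encoder_features

__all__ = [
    "MetricsReport", "validity", "confidence", "sparsity",
    "proximity", "proximity_from_latents", "realism", "evaluate_batch",
]


@dataclass
class MetricsReport:
    rows: pd.DataFrame
    aggregates: pd.DataFrame  # mean / std per metric

    @property
    def n(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def summary(self) -> dict:
        return {col: {"mean": float(self.aggregates.loc["mean", col]),
                      "std": float(self.aggregates.loc["std", col])}
                for col in self.aggregates.columns}


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def validity(predictions, targets, mode: str = "categorical") -> float:
    """Categorical: match fraction.  Continuous: mean |target - pred| / |target|."""
    predictions = np.asarray(predictions)
    targets = np.asarray(targets)
    if len(predictions) != len(targets):
        raise ValueError("predictions and targets must be aligned")
    if mode == "categorical":
        return float(np.mean(predictions == targets))
    if mode == "continuous":
        t = targets.astype(np.float64)
        if np.any(t == 0):
            raise ValueError("continuous targets must be nonzero for MAPE")
        return float(np.mean(np.abs((t - predictions.astype(np.float64)) / t)))
    raise ValueError(f"unknown mode {mode!r}")


def confidence(model, z_bar: np.ndarray, target_class: int,
               wae: WAEModel | None = None) -> float:
    """Softmax probability of the desired class at a counterfactual.

    ``z_bar`` is a latent code, or — when ``wae`` is given — a counterfactual
    image, which is first mapped through the encoder (predictions on images
    always go through the encoder).
    """
    z = encode(wae, np.asarray(z_bar)) if wae is not None else np.asarray(z_bar)
    if isinstance(model, CalibratedPredictor):
        p = class_probabilities(model, z)
        k = model.n_outputs
    else:  # any object exposing .probabilities / .n_classes (SoftmaxClassifier)
        p = model.probabilities(z)
        k = model.n_classes
    if not 0 <= int(target_class) < k:
        raise ValueError(f"class index {target_class} out of range for K={k}")
    return float(p[int(target_class)])


def sparsity(x: np.ndarray, x_bar: np.ndarray,
             change_epsilon: float = 1.0 / 255.0) -> float:
    """Fraction of pixels whose absolute change exceeds ``change_epsilon``."""
    x = np.asarray(x)
    x_bar = np.asarray(x_bar)
    if x.shape != x_bar.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_bar.shape}")
    return float(np.mean(np.abs(x - x_bar) > change_epsilon))


def proximity_from_latents(z_bar: np.ndarray, train_latents: np.ndarray,
                           K: int = 5) -> float:
    """Mean L2 distance to the K nearest training latents."""
    train_latents = np.asarray(train_latents, dtype=np.float64)
    if K > len(train_latents):
        raise ValueError(f"K={K} exceeds training-set size {len(train_latents)}")
    d = np.linalg.norm(train_latents - np.asarray(z_bar, dtype=np.float64), axis=1)
    return float(np.sort(d)[:K].mean())


def proximity(x_bar: np.ndarray, training_images: np.ndarray, wae: WAEModel,
              K: int = 5) -> float:
    """Proximity computed from images through the autoencoder's encoder."""
    z_bar = encode(wae, x_bar)
    zt = encode(wae, training_images)
    return proximity_from_latents(z_bar, zt, K)


def realism(feature_g: np.ndarray, real_features: np.ndarray, K: int = 3,
            sentinel: float = 1e6) -> float:
    """Manifold realism score of a generated sample's feature vector.

    max_j ||psi_j - psi_j^(K)|| / ||psi_j - psi_g||, where psi_j^(K) is the
    K-th nearest neighbor of psi_j among the real set excluding psi_j itself.
    Returns ``sentinel`` when psi_g coincides exactly with some real vector.
    """
    psi = np.asarray(real_features, dtype=np.float64)
    g = np.asarray(feature_g, dtype=np.float64)
    if len(psi) < K + 1:
        raise ValueError(f"need at least K+1={K + 1} real feature vectors, "
                         f"got {len(psi)}")
    d_real = cdist(psi, psi)
    np.fill_diagonal(d_real, np.inf)
    kth = np.sort(d_real, axis=1)[:, K - 1]
    d_g = np.linalg.norm(psi - g, axis=1)
    if np.any(d_g == 0.0):
        return float(sentinel)
    return float(np.max(kth / d_g))


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------


def evaluate_batch(counterfactuals, queries: np.ndarray, targets,
                   model, wae: WAEModel, train_images: np.ndarray,
                   feature_extractor=None, k_proximity: int = 5,
                   k_realism: int = 3,
                   change_epsilon: float = 1.0 / 255.0) -> MetricsReport:
    """Score a batch of counterfactuals and aggregate (mean, std) per metric.

    ``counterfactuals`` are CounterfactualResult objects (or anything with
    ``z_bar`` and ``x_bar``), aligned with query images and target classes.
    Validity, confidence and proximity are computed on the decoded
    counterfactual *image* (re-encoded through the autoencoder), matching
    their definitions on x_bar rather than on the raw optimized latent — an
    off-manifold latent that does not survive the decode/encode round trip
    earns no validity.  ``feature_extractor`` maps an image stack to feature
    vectors for the realism score; by default the autoencoder's final hidden
    activations.
    """
    cfs = list(counterfactuals)
    queries = np.asarray(queries)
    targets = np.asarray(targets)
    if not (len(cfs) == len(queries) == len(targets)):
        raise ValueError("counterfactuals, queries and targets must be aligned")
    if feature_extractor is None:
        feature_extractor = lambda imgs: encoder_features(wae, imgs)  # noqa: E731

    train_latents = encode(wae, train_images)
    real_feats = np.asarray(feature_extractor(train_images), dtype=np.float64)

    rows = []
    for cf, xq, tgt in zip(cfs, queries, targets):
        z_img = encode(wae, cf.x_bar)
        if isinstance(model, CalibratedPredictor):
            probs = class_probabilities(model, z_img)
        else:
            probs = model.probabilities(z_img)
        pred = int(np.argmax(probs))
        feat_g = np.asarray(feature_extractor(cf.x_bar[None])[0], dtype=np.float64)
        rows.append({
            "validity": float(pred == int(tgt)),
            "confidence": float(probs[int(tgt)]),
            "sparsity": sparsity(xq, cf.x_bar, change_epsilon),
            "proximity": proximity_from_latents(z_img, train_latents, k_proximity),
            "realism": realism(feat_g, real_feats, k_realism),
        })
    df = pd.DataFrame(rows)
    agg = pd.DataFrame({c: {"mean": df[c].mean(), "std": df[c].std(ddof=0)}
                        for c in df.columns})
    return MetricsReport(rows=df, aggregates=agg)
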