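"""Shared fixtures.

The expensive artifacts — a trained autoencoder over a 500-image synthetic
cohort plus calibrated and vanilla classifiers on its latent space — are
session-scoped and shared by the behavioural and acceptance tests, mirroring
how one latent space serves every method in the study design.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from tracecf.counterfactual import train_softmax_classifier
from tracecf.lbc import LbcConfig, train_lbc
from tracecf.synthetic import generate_dataset
from tracecf.wae import WAEConfig, encode, train_wae

BENCH_SEED = 20_240_101


@dataclass
class Bench:
    dataset: object
    test_set: object
    wae: object
    latents: np.ndarray
    test_latents: np.ndarray
    lbc: object
    classifier: object


@pytest.fixture(scope="session")
def bench() -> Bench:
    """500-image 64x64 cohort, scaled-training WAE, LbC + vanilla classifiers."""
    ds = generate_dataset(500, class_balance=0.5, seed=BENCH_SEED)
    test = generate_dataset(120, class_balance=0.5, seed=BENCH_SEED + 1)
    wae = train_wae(ds, WAEConfig(latent_dim=32, epochs=20, warmup_epochs=5,
                                  batch_size=32, lr_schedule={12: 2.0, 17: 5.0}),
                    seed=0)
    z = encode(wae, ds.images)
    zt = encode(wae, test.images)
    lbc = train_lbc(z, ds.labels, "classification",
                    LbcConfig(f_hidden=(64, 64), g_hidden=(64, 64),
                              epochs=80, min_epochs=40), seed=0)
    clf = train_softmax_classifier(z, ds.labels, seed=0)
    return Bench(dataset=ds, test_set=test, wae=wae, latents=z,
                 test_latents=zt, lbc=lbc, classifier=clf)
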