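"""Shared fixtures: small synthetic datasets and the (expensive, run-once)
desk-scale training session used by the learnability checks."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from pixelbnn.cli import preprocess_for_network
from pixelbnn.metrics import confusion, kpis
from pixelbnn.network import PixelBNN, SMOKE_NETWORK
from pixelbnn.preprocess import SMOKE_AUGMENT, clahe_enhance
from pixelbnn.synthfundus import SceneParams, generate_pair
from pixelbnn.training import SMOKE_TRAIN, TrackedDataset, train

#: generator settings for 64x64 training imagery: thinner vessels and fewer
#: roots keep the vessel class a clear minority at this tiny resolution
SMOKE_SCENE = SceneParams(image_size=64, width_root=3.0, n_roots=3)


def smoke_pairs(n=4, seed=0):
    return [generate_pair(replace(SMOKE_SCENE, seed=seed + i)) for i in range(n)]


@pytest.fixture(scope="session")
def smoke_dataset():
    """Four 64x64 synthetic fundus/mask pairs."""
    return smoke_pairs(4, seed=0)


@pytest.fixture(scope="session")
def smoke_run(smoke_dataset):
    """One 500-step desk-scale training run (base 8, 2 stages, 64x64 crops,
    lr 1e-3) on a fixed batch of four synthetic pairs; shared by the
    learnability, loss-reduction and round-trip checks."""
    enhanced = [(clahe_enhance(img), mask) for img, mask in smoke_dataset]
    model = PixelBNN(SMOKE_NETWORK, seed=0)
    result = train(
        model,
        TrackedDataset(enhanced),
        SMOKE_TRAIN,
        rng=np.random.default_rng(0),
        augment=SMOKE_AUGMENT,
    )
    f1s = []
    for img, mask in smoke_dataset:
        prob = model.forward(preprocess_for_network(img, 64)[None])[0]
        f1s.append(kpis(confusion(prob > 0.5, mask.pixels))["F1"])
    return {
        "model": model,
        "result": result,
        "train_f1": float(np.mean(f1s)),
        "per_image_f1": f1s,
    }
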