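"""Shared fixtures: synthetic datasets and the smoke-trained model."""

import numpy as np
import pytest

from tinyweednet.config import default_config
from tinyweednet.data import (
    generate_synthetic_dataset,
    resize_bundle,
    stratified_split,
)
from tinyweednet.network import assemble_network
from tinyweednet.train import TrainConfig, train

#: desk-scale smoke protocol: reduced input side, momentum-accelerated SGD,
#: stop as soon as the training set is fit
SMOKE_SIDE = 64
SMOKE_TC = TrainConfig(
    learning_rate=0.05,
    momentum=0.9,
    max_epochs=20,
    patience=10,
    seed=0,
    monitor="train_accuracy",
    target_accuracy=95.0,
)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Small 9-class synthetic set at native resolution (data-level tests)."""
    return generate_synthetic_dataset(n_per_class=6, num_classes=9, side=64, seed=11)


@pytest.fixture(scope="session")
def smoke_run():
    """Train the reference architecture at reduced input side on the easy
    synthetic set (30 images/class); shared by the training and robustness
    acceptance checks."""
    bundle = generate_synthetic_dataset(n_per_class=30, num_classes=9, side=256, seed=11)
    small = resize_bundle(bundle, SMOKE_SIDE)
    train_b, test_b = stratified_split(small, 0.8, seed=42)
    net = assemble_network(default_config(input_side=SMOKE_SIDE), seed=0)
    history = train(net, train_b, test_b, SMOKE_TC)
    return {"net": net, "train": train_b, "test": test_b, "history": history}
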