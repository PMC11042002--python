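"""Shared fixtures.

The expensive fixture is ``trained_easy``: one full training run of the
depth-reduced network on the synthetic five-class benchmark.  It is session
scoped so the learnability check and the heat-map localization check share a
single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from diatomnet import archspec as A
from diatomnet import network as N
from diatomnet import synthetic_data as S
from diatomnet import training as T
from diatomnet import evaluation as EV


def tiny_toy_spec(num_classes: int = 3) -> A.ArchitectureSpec:
    """A <=1000-parameter spec exercising every layer kind (for oracles)."""
    layers = (
        A.LayerSpec(
            kind="convolution",
            label="c1",
            patch=(3, 3),
            stride=2,
            padding_mode="same",
            out_channels=4,
            depth_contribution=1,
        ),
        A.LayerSpec(kind="max_pool", label="p1", patch=(3, 3), stride=2, padding_mode="valid_ceil"),
        A.LayerSpec(kind="cross_channel_norm", label="n1", norm_params=(3, 2.0, 1e-2, 0.75)),
        A.LayerSpec(
            kind="inception",
            label="i1",
            inception=A.InceptionConfig(2, 2, 3, 2, 2, 2),
            depth_contribution=2,
        ),
        A.LayerSpec(kind="avg_pool", label="ap", patch=(3, 3), stride=1, padding_mode="valid_floor"),
        A.LayerSpec(kind="dropout", label="do", rate=0.0),
        A.LayerSpec(kind="linear", label="fc", out_channels=num_classes, depth_contribution=1),
        A.LayerSpec(kind="softmax", label="sm"),
    )
    return A.ArchitectureSpec(
        input_height=12, input_width=14, input_channels=2, num_classes=num_classes, layers=layers
    )


@pytest.fixture(scope="session")
def toy_spec() -> A.ArchitectureSpec:
    return tiny_toy_spec()


@pytest.fixture(scope="session")
def easy_small():
    """A reduced-size copy of the synthetic benchmark for cheap tests."""
    crops, manifest = S.easy_benchmark(seed=1, per_class=10)
    return crops, manifest


@pytest.fixture(scope="session")
def trained_easy():
    """The canonical benchmark training run (5 classes x 100 crops, seed 0).

    Returns (net, train log, test report, crops, manifest).
    """
    crops, manifest = S.easy_benchmark(seed=0, per_class=100)
    net = N.build_network(A.reduced_diatomnet_spec(5), seed=0)
    config = T.TrainConfig(
        learning_rate=0.03,
        momentum=0.9,
        batch_size=16,
        max_epochs=20,
        patience=10,
        seed=0,
        val_accuracy_goal=0.97,
    )
    net, log = T.train(net, manifest, config, crops=crops)
    report = EV.evaluate(net, manifest, "test", crops=crops)
    return net, log, report, crops, manifest
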