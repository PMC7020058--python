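"""Shared fixtures: small simulated meals and a lightweight trained model."""

from __future__ import annotations

import numpy as np
import pytest

from bitekit.detector import ModelConfig, TrainedModel, _Scaler
from bitekit.nn import TwoStreamNet
from bitekit.preprocess import (
    assemble_features,
    clean_sequence,
    select_mouth_side,
    smooth_sequence,
)
from bitekit.synth import SimConfig, simulate_meal

# quarter-length profile for 120 s test meals: keeps the per-second bite
# density of a typical ~8 min / ~55 bite meal
PROFILE_120S = tuple(c * 0.25 for c in (6.909, -0.7409, 0.0683))


@pytest.fixture(scope="session")
def noisefree_meal():
    cfg = SimConfig(
        duration_s=60.0,
        rate_profile=tuple(c * 0.125 for c in (6.909, -0.7409, 0.0683)),
        jitter_px=0.0,
        dropout_prob=0.0,
        outlier_prob=0.0,
        seed=11,
    )
    return simulate_meal(cfg), cfg


@pytest.fixture(scope="session")
def noisy_meal():
    cfg = SimConfig(duration_s=120.0, rate_profile=PROFILE_120S, seed=7)
    return simulate_meal(cfg), cfg


@pytest.fixture(scope="session")
def meal_features(noisy_meal):
    (seq, log), cfg = noisy_meal
    seq = smooth_sequence(clean_sequence(seq))
    side = select_mouth_side(seq)
    return assemble_features(seq, side, meal_id="fixture"), log


@pytest.fixture(scope="session")
def random_model():
    """An untrained (random-weight) model for inference-contract tests."""
    net = TwoStreamNet(
        body_dim=44, mouth_dim=9, conv_blocks=((8, 3), (8, 3)),
        lstm_units=(8,), fusion_units=8, dropout=0.0, seed=5,
    )
    ident = _Scaler(np.zeros(44), np.ones(44))
    ident_m = _Scaler(np.zeros(9), np.ones(9))
    return TrainedModel(
        net=net, config=ModelConfig(conv_blocks=((8, 3), (8, 3)), lstm_units=(8,),
                                    fusion_units=8, dropout=0.0, seed=5),
        body_scaler=ident, mouth_scaler=ident_m, window_frames=50, fps=25.0,
    )
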