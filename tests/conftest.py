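"""Shared fixtures: fast synthetic configurations and recording builders."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wheelmi.synthetic import (
    SynthConfig,
    condition_meta,
    generate_recording,
    reference_meta,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


NO_SIGNATURES = {"RELAX": (), "LEFT": (), "RIGHT": ()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Small, noisy-but-realistic generator config (1 s epochs, 4 epochs/rec)."""
    return SynthConfig(n_trials_per_class=1, epoch_s=1.0, seed=7)


@pytest.fixture
def clean_cfg():
    """Deterministic artifact-only config: zero background, zero signatures,
    zero sensor noise.  Calibration on this config must be exact."""
    return SynthConfig(
        n_trials_per_class=1,
        epoch_s=1.0,
        class_signatures=NO_SIGNATURES,
        noise_rms=0.0,
        accel_noise_rms=0.0,
        true_weight_factors={"surface": 0.8, "subject": 1.0, "wheelchair": 1.25},
        seed=11,
    )


def one_factor_design(cfg, seed=0, trials=1):
    """Reference + baseline-motion + one-factor-at-a-time cells.

    Returns (reference_recording, motion_recordings); every factor gets its
    full set of non-reference levels, each varied alone.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(4096))
    ref, _ = generate_recording(cfg, reference_meta(cfg), next(children))
    motion = []
    for t in range(trials):
        motion.append(
            generate_recording(
                cfg, condition_meta(cfg, cfg.reference_surface, 0, 0, t), next(children)
            )[0]
        )
    surfaces = list(cfg.friction_table)
    for s in surfaces[1:]:
        for t in range(trials):
            motion.append(
                generate_recording(cfg, condition_meta(cfg, s, 0, 0, t), next(children))[0]
            )
    for idx in range(1, len(cfg.subject_weights)):
        for t in range(trials):
            motion.append(
                generate_recording(
                    cfg, condition_meta(cfg, surfaces[0], idx, 0, t), next(children)
                )[0]
            )
    for idx in range(1, len(cfg.wheelchair_weights)):
        for t in range(trials):
            motion.append(
                generate_recording(
                    cfg, condition_meta(cfg, surfaces[0], 0, idx, t), next(children)
                )[0]
            )
    return ref, motion


@pytest.fixture
def calibration_design(clean_cfg):
    return one_factor_design(clean_cfg, seed=21)
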