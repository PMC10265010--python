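"""Shared fixtures and test helpers."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gapcross.synthetic import GeneratorParams, generate_trial_markers
from gapcross.types import MarkerTrajectorySet, Obstacle, Participant, TrialSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Reference participant (cohort-mean body mass and leg length).
PARTICIPANT = Participant("P00", 72.3, 0.88)


def make_spec(
    strategy="OVER",
    depth=0.3,
    length=0.5,
    steps_in_base=None,
    speed=1.3,
    seed=11,
    dropout=None,
    condition="preferred",
):
    if steps_in_base is None:
        steps_in_base = 0 if strategy == "OVER" else 1
    return TrialSpec(
        participant=PARTICIPANT,
        obstacle=Obstacle(depth, length, PARTICIPANT.leg_length),
        strategy=strategy,
        condition=condition,
        approach_speed_target=speed,
        steps_in_base=steps_in_base,
        dropout=dropout,
        seed=seed,
        trial_id=f"{strategy}_d{depth:g}_l{length:g}",
    )


def clean_trial(**kw):
    """Noise-free trial (jitter sigma = 0) with construction ground truth in
    ``meta['truth']``."""
    spec = make_spec(**kw)
    mset = generate_trial_markers(spec, GeneratorParams(jitter_sigma=0.0))
    return spec, mset


@pytest.fixture(scope="session")
def participant():
    return PARTICIPANT


@pytest.fixture(scope="session")
def over_trial():
    return clean_trial(strategy="OVER", depth=0.3, length=0.8)


@pytest.fixture(scope="session")
def in_trial():
    return clean_trial(strategy="IN", depth=0.3, length=0.8, steps_in_base=1)


def single_marker_set(signal: np.ndarray, frame_rate: float = 120.0):
    """A one-marker trajectory set whose x coordinate is ``signal``."""
    n = len(signal)
    arr = np.column_stack([signal, np.zeros(n), np.zeros(n)])
    return MarkerTrajectorySet(frame_rate, {"M": arr}, PARTICIPANT)


def walking_foot_set(
    foot_x: np.ndarray, hip_speed: float = 1.0, frame_rate: float = 120.0
):
    """Marker set with left-foot markers following ``foot_x`` and hips
    advancing at ``hip_speed`` (so mean forward speed is well defined)."""
    n = len(foot_x)
    t = np.arange(n) / frame_rate
    zeros = np.zeros(n)
    foot = np.column_stack([foot_x, zeros, zeros])
    hip = np.column_stack([hip_speed * t, zeros, zeros + 0.9])
    return MarkerTrajectorySet(
        frame_rate,
        {
            "L_MT5": foot.copy(),
            "L_ANK": foot.copy(),
            "L_HIP": hip.copy(),
            "R_HIP": hip.copy(),
        },
        PARTICIPANT,
    )
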