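"""Shared fixtures: small, fast synthetic sessions built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from p300select import (
    ComponentSpec,
    EpochSet,
    ProtocolSpec,
    STANDARD_MONTAGE,
    SimulationConfig,
    SubjectProfile,
    simulate_subject,
)

from p300select import Montage

#: six mid-line/central channels used for cheap selection toys
TOY_CHANNELS = ("F3", "Fz", "F4", "C3", "Cz", "C4")

#: a 6-electrode montage whose "default 8" is the {Fz, Cz} pair, so the
#: default-vs-custom machinery can run on tiny sessions
TOY_MONTAGE = Montage(
    names=TOY_CHANNELS,
    positions=tuple(
        tuple(STANDARD_MONTAGE.position(n)) for n in TOY_CHANNELS
    ),
    default16=TOY_CHANNELS,
    default8=("Fz", "Cz"),
)


def noise_free_profile(center=(0.0, -1.0), spread=4.0, amplitude=8.0) -> SubjectProfile:
    return SubjectProfile(
        label="typical",
        topography_center=center,
        topography_spread=spread,
        components=(
            ComponentSpec(polarity=-1, amplitude=amplitude / 2, latency_ms=200.0, width_ms=40.0),
            ComponentSpec(polarity=+1, amplitude=amplitude, latency_ms=350.0, width_ms=80.0),
        ),
        noise_sd=0.0,
        pink_sd=0.0,
        common_mode_sd=0.0,
        artifact_rate=0.0,
    )


def noisy_profile(center=(0.0, -1.0), spread=4.0, amplitude=8.0, noise=4.0) -> SubjectProfile:
    prof = noise_free_profile(center, spread, amplitude)
    from dataclasses import replace

    return replace(prof, noise_sd=noise, pink_sd=noise / 2)


def toy_session(
    seed: int,
    n_trials: int = 6,
    center=(-2.0, 0.0),  # C3
    spread=0.8,
    amplitude=4.0,
    noise=4.0,
    channels=TOY_CHANNELS,
    sample_rate: float = 256.0,
) -> EpochSet:
    """A small 6-channel session with one informative region around C3."""
    cfg = SimulationConfig(
        profile=noisy_profile(center, spread, amplitude, noise),
        n_trials=n_trials,
        protocol=ProtocolSpec(sample_rate=sample_rate),
        seed=seed,
        montage=TOY_MONTAGE if tuple(channels) == TOY_CHANNELS else STANDARD_MONTAGE,
        channels=tuple(channels) if tuple(channels) != TOY_CHANNELS else None,
    )
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def montage():
    return STANDARD_MONTAGE


@pytest.fixture(scope="session")
def small_session() -> EpochSet:
    """A reusable 6-trial noisy session on the full 32-channel montage."""
    cfg = SimulationConfig(
        profile=noisy_profile(),
        n_trials=6,
        protocol=ProtocolSpec(sample_rate=256.0),
        seed=11,
    )
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def noise_free_session() -> EpochSet:
    cfg = SimulationConfig(
        profile=noise_free_profile(),
        n_trials=3,
        protocol=ProtocolSpec(sample_rate=256.0),
        seed=5,
    )
    return simulate_subject(cfg)
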