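"""Seeded synthetic ERP sessions with controllable spatial topographies.

The generator emulates the statistical structure the electrode-selection
analysis relies on, not biophysical EEG: target flashes add a subject
topography (a single Gaussian spatial profile over schematic electrode
positions) times a temporal ERP template (negative N200-like plus positive
P300-like Gaussian deflections); all flashes receive white, 1/f (pink) and
shared common-mode noise plus rare high-amplitude artifact transients.

Three presets mirror the study's cohorts qualitatively: ``typical`` (broad
centro-parietal topography, moderate noise), ``mild_atypical`` (narrower,
slightly shifted), and ``severe_atypical`` (restricted, left-lateralized
around C5 — disjoint from the default-8 electrode set — with elevated
noise).  Preset numbers are package choices tuned only to reproduce the
qualitative group pattern; the study's participants' waveform parameters
are unknown.

Every draw flows from one explicit seed through named child streams, so a
cohort and any single subject within it are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SchemaError
from .montage import Montage, STANDARD_MONTAGE
from .sessions import EpochSet, ProtocolSpec, n_window_samples

__all__ = [
    "ComponentSpec",
    "SubjectProfile",
    "SimulationConfig",
    "PRESETS",
    "get_preset",
    "spatial_weights",
    "informative_channels",
    "simulate_subject",
    "make_cohort",
    "CohortMember",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian ERP deflection in the target response.

    ``center_offset`` shifts this component's topography relative to the
    subject's ``topography_center``; distinct offsets make components carry
    spatially complementary information, as the N200 (posterior) and P300
    (centro-parietal) do in real recordings.
    """

    polarity: int  # +1 or -1
    amplitude: float  # µV, peak before spatial weighting
    latency_ms: float
    width_ms: float
    center_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise SchemaError("component polarity must be +1 or -1")
        if self.amplitude < 0:
            raise SchemaError("component amplitude must be >= 0")
        if self.width_ms <= 0:
            raise SchemaError("component width must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject."""

    label: str  # typical | mild_atypical | severe_atypical
    topography_center: tuple[float, float]
    #: Gaussian scale in montage grid units; a scalar for an isotropic
    #: topography or an (x, y) pair for an elongated/ridge-like one.
    topography_spread: float | tuple[float, float]
    components: tuple[ComponentSpec, ...]
    noise_sd: float  # µV, white noise
    pink_sd: float  # µV, 1/f noise
    pink_exponent: float = 1.0
    common_mode_sd: float = 0.0  # µV, noise shared across channels
    artifact_rate: float = 0.0  # fraction of epochs with a large transient
    artifact_amplitude: float = 75.0  # µV

    def __post_init__(self) -> None:
        spread = np.atleast_1d(np.asarray(self.topography_spread, float))
        if (spread <= 0).any():
            raise SchemaError("topography_spread must be positive")
        if min(self.noise_sd, self.pink_sd, self.common_mode_sd) < 0:
            raise SchemaError("noise scales must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise SchemaError("artifact_rate must lie in [0, 1]")

    def scale_amplitudes(self, factor: float) -> "SubjectProfile":
        comps = tuple(
            replace(c, amplitude=c.amplitude * factor) for c in self.components
        )
        return replace(self, components=comps)


_N200 = ComponentSpec(polarity=-1, amplitude=4.0, latency_ms=200.0, width_ms=40.0)
_P300 = ComponentSpec(polarity=+1, amplitude=8.0, latency_ms=350.0, width_ms=80.0)

PRESETS: dict[str, SubjectProfile] = {
    # Broad centro-parietal topography covering the default-8 electrodes.
    "typical": SubjectProfile(
        label="typical",
        topography_center=(0.0, -1.0),  # around CPz
        topography_spread=4.0,
        components=(_N200, _P300),
        noise_sd=3.5,
        pink_sd=6.5,
        common_mode_sd=2.0,
        artifact_rate=0.01,
    ),
    # Narrower, slightly left-shifted topography; intermediate noise and
    # reduced component amplitudes.
    "mild_atypical": SubjectProfile(
        label="mild_atypical",
        topography_center=(-1.0, -1.0),  # around CP1
        topography_spread=2.0,
        components=(_N200, replace(_P300, amplitude=7.0)),
        noise_sd=3.75,
        pink_sd=8.0,
        common_mode_sd=2.0,
        artifact_rate=0.02,
    ),
    # Severely restricted, lateralized topography: a narrow left-lateral
    # ridge over C5/CP5 (disjoint from the default-8 set) with the P300
    # centered anteriorly (C5) and the N200 posteriorly (CP5), so each
    # ridge electrode carries partly unique information.  Component
    # amplitudes are small and 1/f noise elevated, mirroring the noisier,
    # lower-SNR recordings of the severe cohort.
    "severe_atypical": SubjectProfile(
        label="severe_atypical",
        topography_center=(-3.0, -0.5),  # between C5 and CP5
        topography_spread=(0.7, 0.45),
        components=(
            replace(_N200, amplitude=3.0, center_offset=(0.0, -0.5)),
            replace(_P300, amplitude=3.25, center_offset=(0.0, +0.5)),
        ),
        noise_sd=4.0,
        pink_sd=10.0,
        common_mode_sd=1.5,
        artifact_rate=0.04,
    ),
}


def get_preset(name: str) -> SubjectProfile:
    try:
        return PRESETS[name]
    except KeyError:
        raise SchemaError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SimulationConfig:
    profile: SubjectProfile
    n_trials: int = 30
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    seed: int = 0
    montage: Montage = STANDARD_MONTAGE
    channels: tuple[str, ...] | None = None  # simulate a channel subset only
    window_ms: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise SchemaError("n_trials must be >= 1")
        if self.seed is None:
            raise SchemaError("an explicit seed is required")


def _gaussian_weights(
    profile: SubjectProfile,
    montage: Montage,
    channels,
    offset: tuple[float, float],
) -> np.ndarray:
    pos = montage.position_array(tuple(channels) if channels else None)
    center = np.asarray(profile.topography_center, float) + np.asarray(offset, float)
    spread = np.broadcast_to(
        np.atleast_1d(np.asarray(profile.topography_spread, float)), (2,)
    )
    d2 = (((pos - center) / spread) ** 2).sum(axis=1)
    w = np.exp(-d2 / 2.0)
    return w / w.max()


def spatial_weights(
    profile: SubjectProfile, montage: Montage, channels=None
) -> np.ndarray:
    """Per-channel topography weight in (0, 1].

    Each component contributes a Gaussian of scalp distance from its
    (possibly offset) center, normalized to max 1; the profile-level weight
    is the amplitude-weighted RMS over components, renormalized to max 1.
    With co-centered components this reduces to the plain Gaussian
    exp(-d² / (2·spread²)) of distance from ``topography_center``.
    """
    if not profile.components:
        return _gaussian_weights(profile, montage, channels, (0.0, 0.0))
    total = np.zeros(
        len(tuple(channels)) if channels else montage.size, dtype=float
    )
    for c in profile.components:
        w = _gaussian_weights(profile, montage, channels, c.center_offset)
        total += (c.amplitude * w) ** 2
    total = np.sqrt(total)
    m = total.max()
    return total / m if m > 0 else np.ones_like(total)


def informative_channels(
    profile: SubjectProfile, montage: Montage, threshold: float = 0.5
) -> tuple[str, ...]:
    """Channels whose topography weight reaches ``threshold`` (montage order)."""
    w = spatial_weights(profile, montage)
    return tuple(n for n, wi in zip(montage.names, w) if wi >= threshold)


def _erp_template(profile: SubjectProfile, times_ms: np.ndarray) -> np.ndarray:
    """Temporal target template (µV) before spatial weighting."""
    out = np.zeros_like(times_ms)
    for c in profile.components:
        out += (
            c.polarity
            * c.amplitude
            * np.exp(-((times_ms - c.latency_ms) ** 2) / (2.0 * c.width_ms**2))
        )
    return out


def _pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    exponent: float,
) -> np.ndarray:
    """1/f^exponent noise along the last axis, unit variance globally.

    Generated in the frequency domain (complex Gaussian coefficients with a
    1/f^(exponent/2) amplitude envelope, zero DC) and normalized by the
    realized global standard deviation, which is deterministic given the
    generator state.  float32 throughout: the session payload is float32.
    """
    from scipy.fft import irfft

    n_freq = n_samples // 2 + 1
    scale = np.zeros(n_freq, dtype=np.float32)
    scale[1:] = np.arange(1, n_freq, dtype=np.float32) ** np.float32(-exponent / 2.0)
    coef = np.empty((*shape, n_freq), dtype=np.complex64)
    coef.real = rng.standard_normal((*shape, n_freq), dtype=np.float32) * scale
    coef.imag = rng.standard_normal((*shape, n_freq), dtype=np.float32) * scale
    x = irfft(coef, n=n_samples, axis=-1)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(cfg: SimulationConfig) -> EpochSet:
    """Generate one seeded stimulus-locked calibration session.

    Per trial the four labels flash in repeated shuffled blocks (each label
    flashes once before any repeats); target epochs receive the weighted ERP
    template; every epoch receives white + pink + common-mode noise and,
    with probability ``artifact_rate``, one large smooth transient.
    """
    prof = cfg.profile
    proto = cfg.protocol
    montage = cfg.montage
    channels = tuple(cfg.channels) if cfg.channels else montage.names
    n_ch = len(channels)
    n_sa = n_window_samples(cfg.window_ms, proto.sample_rate)
    n_fl = proto.flashes_per_trial
    T = cfg.n_trials

    ss = np.random.SeedSequence(cfg.seed)
    rng_order, rng_target, rng_white, rng_pink, rng_common, rng_artifact = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    # flash sequence: shuffled block of all choices, repeated
    flashed = np.empty((T, n_fl), dtype=np.int64)
    for t in range(T):
        flashed[t] = np.concatenate(
            [rng_order.permutation(proto.n_choices) for _ in range(proto.flashes_per_choice)]
        )
    targets = rng_target.integers(0, proto.n_choices, size=T)

    epochs = np.zeros((T, n_fl, n_ch, n_sa), dtype=np.float32)
    if prof.noise_sd > 0:
        epochs += np.float32(prof.noise_sd) * rng_white.standard_normal(
            epochs.shape, dtype=np.float32
        )
    if prof.pink_sd > 0:
        epochs += prof.pink_sd * _pink_noise(
            rng_pink, (T, n_fl, n_ch), n_sa, prof.pink_exponent
        )
    if prof.common_mode_sd > 0:
        epochs += prof.common_mode_sd * _pink_noise(
            rng_common, (T, n_fl, 1), n_sa, prof.pink_exponent
        )
    if prof.artifact_rate > 0:
        times = cfg.window_ms[0] + np.arange(n_sa) * 1000.0 / proto.sample_rate
        hits = np.argwhere(rng_artifact.random((T, n_fl)) < prof.artifact_rate)
        for t, e in hits:
            center = rng_artifact.uniform(cfg.window_ms[0], cfg.window_ms[1])
            sign = 1.0 if rng_artifact.random() < 0.5 else -1.0
            amp = prof.artifact_amplitude * rng_artifact.uniform(0.75, 1.25)
            bump = sign * amp * np.exp(-((times - center) ** 2) / (2.0 * 100.0**2))
            epochs[t, e] += bump  # broadcast over channels

    # target signal: each component spatially weighted by its own topography
    times = cfg.window_ms[0] + np.arange(n_sa) * 1000.0 / proto.sample_rate
    signal = np.zeros((n_ch, n_sa))
    for c in prof.components:
        w = _gaussian_weights(prof, montage, channels, c.center_offset)
        wave = (
            c.polarity
            * c.amplitude
            * np.exp(-((times - c.latency_ms) ** 2) / (2.0 * c.width_ms**2))
        )
        signal += w[:, None] * wave[None, :]
    is_target = flashed == targets[:, None]
    epochs[is_target] += signal

    return EpochSet(
        montage=montage,
        protocol=proto,
        epochs=np.asarray(epochs, dtype=np.float32),
        flashed_label=flashed,
        target_choice=targets,
        window_ms=cfg.window_ms,
        channels=channels,
        provenance={
            "generator": "p300select.simulate",
            "profile": prof.label,
            "seed": int(cfg.seed),
        },
    )


@dataclass(frozen=True)
class CohortMember:
    """One synthetic participant: identity, group, profile and session recipe.

    Sessions are generated on demand (``simulate()``) so large cohorts do
    not hold every epoch array in memory at once; generation is
    deterministic from the stored config.
    """

    subject_id: str
    group: str
    profile: SubjectProfile
    config: SimulationConfig

    def simulate(self) -> EpochSet:
        return simulate_subject(self.config)


def make_cohort(
    group_sizes: dict[str, int],
    base_seed: int,
    n_trials: int = 30,
    protocol: ProtocolSpec | None = None,
    montage: Montage = STANDARD_MONTAGE,
) -> list[CohortMember]:
    """Build a cohort of jittered preset profiles with derived seeds.

    ``group_sizes`` maps preset names (``typical``, ``mild_atypical``,
    ``severe_atypical``) to subject counts.  Each subject gets a jittered
    copy of the group preset (topography center ±0.4 grid units, spread
    ±15%, component amplitudes ±20%, noise scales ±10%) and an independent
    child seed of ``base_seed``.
    """
    protocol = protocol or ProtocolSpec()
    members: list[CohortMember] = []
    for group, size in group_sizes.items():
        # stable per-group stream key (process-independent, unlike hash())
        group_key = int.from_bytes(group.encode("utf-8"), "big") % 2**31
        preset = get_preset(group)
        for i in range(size):
            child = np.random.SeedSequence(
                entropy=base_seed, spawn_key=(group_key, i)
            )
            jit = np.random.default_rng(child)
            cx, cy = preset.topography_center
            amp = jit.uniform(0.8, 1.2)
            noise = jit.uniform(0.9, 1.1)
            profile = replace(
                preset.scale_amplitudes(amp),
                topography_center=(
                    cx + jit.uniform(-0.25, 0.25),
                    cy + jit.uniform(-0.25, 0.25),
                ),
                topography_spread=tuple(
                    np.atleast_1d(np.asarray(preset.topography_spread, float))
                    * jit.uniform(0.85, 1.15)
                )
                if np.ndim(preset.topography_spread)
                else preset.topography_spread * jit.uniform(0.85, 1.15),
                noise_sd=preset.noise_sd * noise,
                pink_sd=preset.pink_sd * noise,
                common_mode_sd=preset.common_mode_sd * noise,
            )
            seed = int(jit.integers(0, 2**31 - 1))
            members.append(
                CohortMember(
                    subject_id=f"{group}-{i:02d}",
                    group=group,
                    profile=profile,
                    config=SimulationConfig(
                        profile=profile,
                        n_trials=n_trials,
                        protocol=protocol,
                        seed=seed,
                        montage=montage,
                    ),
                )
            )
    return members
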