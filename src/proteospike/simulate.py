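"""Synthetic spiking recordings and microsphere-diameter samples.

The generator emulates the statistical structure the downstream analysis
assumes: spike events whose amplitudes and inter-event intervals are drawn
i.i.d. from log-normal distributions moment-matched to a target mean and
standard deviation (log-normals because both quantities are positive and the
published per-character period summaries are strongly right-skewed, with
means far above medians).  Events are rendered onto a uniform time grid as
unit-peak Gaussian bumps on a configurable baseline (offset + linear drift +
slow sinusoid) plus additive white Gaussian noise.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded from
the config, so identical configs give bit-identical output across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .io import POTENTIAL_MV, CHANNEL_KINDS, CharacterProfile, Recording

__all__ = [
    "BaselineConfig",
    "GeneratorConfig",
    "EventTrain",
    "lognormal_params",
    "sample_event_train",
    "render_signal",
    "simulate_recording",
    "sample_diameters",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Deterministic baseline b(t) = offset + drift·t + A·sin(2πt/T)."""

    offset: float = 0.0          # mV (or °C)
    drift: float = 0.0           # mV/s
    sin_amplitude: float = 0.0   # mV
    sin_period: float = 0.0      # s; 0 disables the sinusoid

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        b = self.offset + self.drift * t
        if self.sin_amplitude != 0.0 and self.sin_period > 0.0:
            b = b + self.sin_amplitude * np.sin(2.0 * np.pi * t / self.sin_period)
        return b


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spiking-recording generator.

    ``amplitude_mean``/``amplitude_sd`` (mV) and ``period_mean``/``period_sd``
    (s) are the target moments of the spike-amplitude and inter-event-interval
    distributions — typically one row of the reference profile table.  A zero
    sd degenerates to a point mass.
    """

    amplitude_mean: float
    period_mean: float
    amplitude_sd: float = 0.0
    period_sd: float = 0.0
    duration: float = 10_000.0       # s
    spike_width: float = 20.0        # s, Gaussian bump scale
    noise_sd: float = 0.05           # mV additive white noise
    sampling_interval: float = 1.0   # s
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    seed: int = 0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.amplitude_mean <= 0 or self.period_mean <= 0:
            raise ValueError("amplitude_mean and period_mean must be positive")
        if self.amplitude_sd < 0 or self.period_sd < 0 or self.noise_sd < 0:
            raise ValueError("dispersions must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not 0 < self.spike_width < self.period_mean / 5:
            raise ValueError(
                f"spike_width must lie in (0, period_mean/5) = "
                f"(0, {self.period_mean / 5:g}), got {self.spike_width:g}"
            )

    @classmethod
    def from_profile(cls, profile: CharacterProfile, **overrides) -> "GeneratorConfig":
        """Config with moments taken from one reference-table row."""
        overrides.setdefault("label", profile.label)
        return cls(
            amplitude_mean=profile.amplitude.mean,
            amplitude_sd=profile.amplitude.sd,
            period_mean=profile.period.mean,
            period_sd=profile.period.sd,
            **overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EventTrain:
    """Latent spike events: strictly increasing times, positive amplitudes."""

    event_times: np.ndarray       # s
    event_amplitudes: np.ndarray  # mV
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_times", np.asarray(self.event_times, float))
        object.__setattr__(
            self, "event_amplitudes", np.asarray(self.event_amplitudes, float)
        )
        if len(self.event_times) != len(self.event_amplitudes):
            raise ValueError("event_times and event_amplitudes must have equal length")
        if len(self.event_times) and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("event_amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.event_times)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and standard deviation.

    mu = ln(m² / sqrt(v + m²)), sigma² = ln(1 + v/m²).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    v = sd * sd
    mu = math.log(mean * mean / math.sqrt(v + mean * mean))
    sigma = math.sqrt(math.log1p(v / (mean * mean)))
    return mu, sigma


def _draw_positive(rng, mean, sd, size):
    if sd == 0.0:
        return np.full(size, float(mean))
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size)


def _rng_for(config: GeneratorConfig, stream: int):
    # independent deterministic streams for event sampling vs. noise rendering
    return np.random.default_rng([int(config.seed), stream])


def sample_event_train(
    config: GeneratorConfig, n_events: Optional[int] = None
) -> EventTrain:
    """Draw a spike-event train from the configured distributions.

    Inter-event intervals and amplitudes are i.i.d. log-normal, moment-matched
    to the config.  The first event falls one interval after t = 0.  With
    ``n_events=None`` events accumulate until ``config.duration`` would be
    exceeded (events at t >= duration are dropped); with ``n_events`` given,
    exactly that many events are drawn regardless of duration.
    """
    rng = _rng_for(config, 0)
    if n_events is not None:
        if n_events < 0:
            raise ValueError("n_events must be nonnegative")
        intervals = _draw_positive(rng, config.period_mean, config.period_sd, n_events)
        amps = _draw_positive(rng, config.amplitude_mean, config.amplitude_sd, n_events)
        return EventTrain(np.cumsum(intervals), amps, config.label)

    times = []
    t = 0.0
    # draw in chunks to keep the rng stream layout simple and deterministic
    expected = max(8, int(config.duration / config.period_mean * 1.5))
    while True:
        intervals = _draw_positive(rng, config.period_mean, config.period_sd, expected)
        for dt in intervals:
            t += dt
            if t >= config.duration:
                amps = _draw_positive(
                    rng, config.amplitude_mean, config.amplitude_sd, len(times)
                )
                return EventTrain(np.array(times), amps, config.label)
            times.append(t)


def render_signal(
    events: EventTrain,
    config: GeneratorConfig,
    channel_kind: str = POTENTIAL_MV,
) -> Recording:
    """Render an event train to a uniformly sampled recording.

    signal(t) = baseline(t) + Σ_k a_k · exp(−((t − t_k)/spike_width)²/2)
              + N(0, noise_sd²)

    The bump is unit-peak, so an isolated noiseless spike's local maximum
    equals baseline + amplitude (to within the sampling granularity).
    """
    if channel_kind not in CHANNEL_KINDS:
        raise ValueError(f"unknown channel_kind {channel_kind!r}")
    if len(events) and events.event_times[-1] > config.duration:
        raise ValueError(
            f"event at t={events.event_times[-1]:g} s extends beyond "
            f"duration {config.duration:g} s"
        )
    dt = config.sampling_interval
    n = int(math.floor(config.duration / dt)) + 1
    t = np.arange(n) * dt
    signal = config.baseline.evaluate(t).astype(float)

    w = config.spike_width
    half = 6.0 * w  # beyond 6 widths the bump is < 2e-8 of its peak
    for tk, ak in zip(events.event_times, events.event_amplitudes):
        lo = max(0, int(math.ceil((tk - half) / dt)))
        hi = min(n, int(math.floor((tk + half) / dt)) + 1)
        if lo < hi:
            u = (t[lo:hi] - tk) / w
            signal[lo:hi] += ak * np.exp(-0.5 * u * u)

    if config.noise_sd > 0:
        signal += _rng_for(config, 1).normal(0.0, config.noise_sd, n)
    return Recording(t, signal, channel_kind, events.label, sampling_interval=dt)


def simulate_recording(
    config: GeneratorConfig,
    n_events: Optional[int] = None,
    channel_kind: str = POTENTIAL_MV,
) -> tuple[Recording, EventTrain]:
    """Sample an event train and render it; returns (recording, ground truth).

    With ``n_events`` given, the grid is extended past the last event so
    nothing is clipped.
    """
    events = sample_event_train(config, n_events=n_events)
    if n_events is not None and len(events):
        needed = float(events.event_times[-1] + 6.0 * config.spike_width)
        if needed > config.duration:
            import dataclasses

            config = dataclasses.replace(config, duration=needed)
    return render_signal(events, config, channel_kind), events


def sample_diameters(
    n: int, mean: float = 1600.0, sd: float = 200.0, seed: int = 0
) -> np.ndarray:
    """i.i.d. normal microsphere diameters (nm), truncated at zero."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if sd == 0.0:
        return np.full(n, float(mean))
    rng = np.random.default_rng(seed)
    a = (0.0 - mean) / sd  # truncation at zero in standard units
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
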