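"""Blend-ratio stimulus programs.

A stimulus is a binary odour blend described by the ratio ``rho`` (the
proportion of total concentration carried by receptor channel 1) and a
pulse schedule.  During a pulse the two-channel input vector is
``(rho * amplitude, (1 - rho) * amplitude)``; between pulses it is zero.
Total concentration is held at 1 by default so that ``rho`` alone
parameterizes the blend.  Pulse edges are square at the integration
resolution (no rise-time model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusProgram",
    "make_pulse",
    "make_pulse_train",
    "make_random_plume",
    "sample_ratios",
]

DEFAULT_ONSET_MS = 100.0


class ScheduleError(ValueError):
    """Raised for malformed pulse schedules."""


@dataclass(frozen=True)
class StimulusProgram:
    """A blend ratio plus a time-ordered, non-overlapping pulse list.

    ``pulses`` holds (onset, offset) pairs in ms; offsets are exclusive.
    """

    ratio: float
    pulses: tuple[tuple[float, float], ...]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ScheduleError(f"ratio must lie in [0, 1], got {self.ratio}")
        if self.amplitude < 0:
            raise ScheduleError("amplitude must be non-negative")
        prev_off = -np.inf
        for onset, offset in self.pulses:
            if offset <= onset:
                raise ScheduleError(f"empty or inverted pulse ({onset}, {offset})")
            if onset < prev_off:
                raise ScheduleError("pulses overlap or are out of order")
            prev_off = offset

    @property
    def channel_levels(self) -> tuple[float, float]:
        """Input per channel while a pulse is on."""
        return (self.ratio * self.amplitude, (1.0 - self.ratio) * self.amplitude)

    @property
    def onset(self) -> float:
        """Time of the first pulse onset (stimulus onset)."""
        if not self.pulses:
            raise ScheduleError("program has no pulses")
        return self.pulses[0][0]

    @property
    def end(self) -> float:
        """Offset of the last pulse."""
        if not self.pulses:
            raise ScheduleError("program has no pulses")
        return self.pulses[-1][1]

    def gate(self, t: np.ndarray | float) -> np.ndarray:
        """1.0 where some pulse covers t (onset-inclusive), else 0.0."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=float)
        for onset, offset in self.pulses:
            on = np.maximum(on, ((t >= onset) & (t < offset)).astype(float))
        return on

    def values_at(self, t: np.ndarray | float) -> np.ndarray:
        """Two-channel input G(t), shape (2,) + shape(t)."""
        g = self.gate(t)
        lv = self.channel_levels
        return np.stack([lv[0] * g, lv[1] * g])

    def to_series(self, duration_ms: float, dt: float = 1.0) -> np.ndarray:
        """Expand to a (2, T) series sampled at the left edge of each step."""
        t = np.arange(0.0, duration_ms, dt)
        return self.values_at(t)


def make_pulse(
    ratio: float,
    onset: float = DEFAULT_ONSET_MS,
    duration_ms: float = 500.0,
    amplitude: float = 1.0,
) -> StimulusProgram:
    """A single square pulse."""
    return StimulusProgram(ratio, ((onset, onset + duration_ms),), amplitude)


def make_pulse_train(
    ratio: float,
    onset: float = DEFAULT_ONSET_MS,
    n_pulses: int = 5,
    pulse_ms: float = 50.0,
    gap_ms: float = 50.0,
    amplitude: float = 1.0,
) -> StimulusProgram:
    """A periodic train of ``n_pulses`` pulses separated by ``gap_ms``."""
    if n_pulses < 1 or pulse_ms <= 0 or gap_ms < 0:
        raise ScheduleError("need n_pulses >= 1, pulse_ms > 0, gap_ms >= 0")
    pulses = tuple(
        (onset + k * (pulse_ms + gap_ms), onset + k * (pulse_ms + gap_ms) + pulse_ms)
        for k in range(n_pulses)
    )
    return StimulusProgram(ratio, pulses, amplitude)


def make_random_plume(
    ratio: float,
    span_ms: float,
    seed: int,
    onset: float = DEFAULT_ONSET_MS,
    min_pulse_ms: float = 40.0,
    mean_rate_hz: float = 2.0,
    mean_excess_ms: float = 60.0,
    amplitude: float = 1.0,
) -> StimulusProgram:
    """Randomly timed pulses emulating odour-plume intermittency.

    A renewal process: waiting times between pulse onsets are
    exponential with rate ``mean_rate_hz``; each pulse lasts
    ``min_pulse_ms`` plus an exponential excess with mean
    ``mean_excess_ms``, so no pulse is shorter than the plume-realistic
    minimum (40 ms by default).  Pulses that do not fit before
    ``onset + span_ms`` are dropped.  Deterministic per seed.
    """
    if span_ms <= 0:
        raise ScheduleError("span_ms must be positive")
    rng = np.random.default_rng(seed)
    pulses: list[tuple[float, float]] = []
    t = float(onset)
    end = onset + span_ms
    if mean_rate_hz > 0:
        while True:
            t = t + rng.exponential(1000.0 / mean_rate_hz)
            dur = min_pulse_ms + rng.exponential(mean_excess_ms)
            if t + dur > end:
                break
            pulses.append((t, t + dur))
            t += dur
    return StimulusProgram(ratio, tuple(pulses), amplitude)


def sample_ratios(n: int, seed: int) -> np.ndarray:
    """``n`` blend ratios drawn uniformly on [0, 1], reproducible per seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return np.random.default_rng(seed).random(n)
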