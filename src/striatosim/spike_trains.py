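"""Dopamine-neuron spike-train generators.

Two firing regimes with the same long-run mean rate (4 Hz by default):

* tonic — independent homogeneous Poisson trains per neuron;
* phasic — the tonic background interrupted by synchronized ~20 Hz burst
  epochs and silent pause epochs.  Each burst is paired with one pause and
  sized so the extra burst spikes exactly cancel the spikes lost to the
  pause, keeping the mean rate at ``mean_rate`` regardless of how many
  events occur.

Reproducibility: one master seed fans out into counter-based substreams
(one per neuron plus one for the epoch schedule), so changing ``n_neurons``
never reshuffles the trains of earlier neurons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ConfigError, FiringConfig

__all__ = [
    "Epoch",
    "SpikeTrainSet",
    "make_schedule",
    "generate_tonic",
    "generate_phasic",
    "generate",
    "empirical_rate",
]

# substream codes for SeedSequence spawn keys
_STREAM_SCHEDULE = 0
_STREAM_BACKGROUND = 1
_STREAM_BURST = 2


@dataclass(frozen=True)
class Epoch:
    """Half-open time interval [start, end) with a label."""

    start: float
    end: float
    kind: str  # "tonic", "phasic_background", "burst", "pause"

    @property
    def duration(self) -> float:
        return self.end - self.start


ModeSchedule = List[Tuple[float, float, str]]


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times plus the epoch schedule that produced them."""

    n_neurons: int
    duration: float
    spikes: List[np.ndarray]
    schedule: List[Epoch] = field(default_factory=list)
    mode_schedule: ModeSchedule = field(default_factory=list)

    def pooled(self) -> np.ndarray:
        """All spike times across neurons, sorted."""
        if not self.spikes:
            return np.empty(0)
        return np.sort(np.concatenate(self.spikes))

    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def epochs_of_kind(self, *kinds: str) -> List[Epoch]:
        return [e for e in self.schedule if e.kind in kinds]


def make_schedule(duration: float, switch_time: float) -> ModeSchedule:
    """Tonic mode on [0, switch_time), phasic mode on [switch_time, duration)."""
    if duration < 0:
        raise ConfigError("duration must be non-negative")
    if not 0.0 <= switch_time <= duration:
        raise ConfigError(
            f"switch_time {switch_time} outside [0, {duration}]"
        )
    sched: ModeSchedule = []
    if switch_time > 0:
        sched.append((0.0, switch_time, "tonic"))
    if switch_time < duration:
        sched.append((switch_time, duration, "phasic"))
    return sched


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson event times on [t0, t1)."""
    span = t1 - t0
    if span <= 0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return t0 + np.sort(rng.random(n)) * span


def _place_events(
    rng: np.random.Generator, cfg: FiringConfig, t0: float, t1: float
) -> List[Epoch]:
    """Place paired burst+pause events in [t0, t1) by a thinned Poisson process.

    Candidate event starts arrive at ``event_rate``; candidates overlapping an
    already-accepted event (or running past t1) are rejected.  Each accepted
    event is a burst epoch immediately followed by a pause epoch.
    """
    event_len = cfg.burst_duration + cfg.pause_duration
    pause_fraction = cfg.pause_event_rate * cfg.pause_duration
    burst_fraction = cfg.event_rate * cfg.burst_duration
    if pause_fraction + burst_fraction > 1.0:
        raise ConfigError(
            "infeasible burst/pause balance: scheduled epochs exceed total time "
            f"(burst fraction {burst_fraction:.3f} + pause fraction {pause_fraction:.3f} > 1)"
        )
    epochs: List[Epoch] = []
    if cfg.balanced_pairs:
        # one burst + one pause cancel exactly: place them as contiguous pairs
        starts = _poisson_times(rng, cfg.event_rate, t0, t1)
        last_end = t0
        for s in starts:
            if s < last_end or s + event_len > t1:
                continue
            epochs.append(Epoch(s, s + cfg.burst_duration, "burst"))
            epochs.append(Epoch(s + cfg.burst_duration, s + event_len, "pause"))
            last_end = s + event_len
        return epochs
    # unbalanced durations: independent burst and pause event streams whose
    # frequencies satisfy the rate-balance identity; overlaps thinned greedily
    bursts = _poisson_times(rng, cfg.event_rate, t0, t1)
    pauses = _poisson_times(rng, cfg.pause_event_rate, t0, t1)
    cand = sorted(
        [(s, cfg.burst_duration, "burst") for s in bursts]
        + [(s, cfg.pause_duration, "pause") for s in pauses]
    )
    last_end = t0
    for s, length, kind in cand:
        if s < last_end or s + length > t1:
            continue
        epochs.append(Epoch(s, s + length, kind))
        last_end = s + length
    return epochs


def _delete_in_epochs(times: np.ndarray, epochs: Sequence[Epoch]) -> np.ndarray:
    if len(times) == 0 or not epochs:
        return times
    keep = np.ones(len(times), dtype=bool)
    for e in epochs:
        keep &= ~((times >= e.start) & (times < e.end))
    return times[keep]


def _burst_spikes(rng: np.random.Generator, cfg: FiringConfig, bursts: Sequence[Epoch]) -> np.ndarray:
    """Regular within-burst spiking at ``burst_rate`` with a random phase per burst."""
    isi = 1.0 / cfg.burst_rate
    out: List[np.ndarray] = []
    for b in bursts:
        phase = rng.random() * isi
        t = np.arange(b.start + phase, b.end, isi)
        out.append(t)
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def generate(
    n_neurons: int,
    mode_schedule: ModeSchedule,
    config: FiringConfig,
    seed: int,
) -> SpikeTrainSet:
    """Generate spike trains following a tonic/phasic mode schedule.

    Tonic-mode intervals carry independent Poisson firing at ``mean_rate``;
    phasic-mode intervals additionally carry synchronized burst/pause events
    (shared across neurons when ``config.synchrony`` is set, otherwise drawn
    independently per neuron).
    """
    if n_neurons < 1:
        raise ConfigError("n_neurons must be >= 1")
    if config.mean_rate < 0:
        raise ConfigError("mean_rate must be non-negative")
    duration = mode_schedule[-1][1] if mode_schedule else 0.0

    phasic_intervals = [(a, b) for a, b, m in mode_schedule if m == "phasic"]
    if phasic_intervals and config.burst_rate <= config.mean_rate:
        raise ConfigError("burst_rate must exceed mean_rate for phasic firing")

    # shared epoch schedule (synchronous case)
    sched_rng = _rng(seed, _STREAM_SCHEDULE)
    shared_events: List[Epoch] = []
    for a, b in phasic_intervals:
        shared_events.extend(_place_events(sched_rng, config, a, b))

    schedule: List[Epoch] = []
    for a, b, m in mode_schedule:
        kind = "tonic" if m == "tonic" else "phasic_background"
        schedule.append(Epoch(a, b, kind))
    schedule.extend(shared_events)
    schedule.sort(key=lambda e: (e.start, e.end))

    spikes: List[np.ndarray] = []
    for i in range(n_neurons):
        bg_rng = _rng(seed, _STREAM_BACKGROUND, i)
        t = _poisson_times(bg_rng, config.mean_rate, 0.0, duration)
        if config.synchrony:
            events = shared_events
        else:
            ev_rng = _rng(seed, _STREAM_SCHEDULE, i + 1)
            events = []
            for a, b in phasic_intervals:
                events.extend(_place_events(ev_rng, config, a, b))
        if events:
            t = _delete_in_epochs(t, events)
            burst_rng = _rng(seed, _STREAM_BURST, i)
            bursts = [e for e in events if e.kind == "burst"]
            t = np.concatenate([t, _burst_spikes(burst_rng, config, bursts)])
        t = np.sort(t)
        spikes.append(t)

    return SpikeTrainSet(
        n_neurons=n_neurons,
        duration=duration,
        spikes=spikes,
        schedule=schedule,
        mode_schedule=list(mode_schedule),
    )


def generate_tonic(
    n_neurons: int, duration: float, config: FiringConfig, seed: int
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains at ``mean_rate`` per neuron."""
    if duration < 0:
        raise ConfigError("duration must be non-negative")
    return generate(n_neurons, make_schedule(duration, duration), config, seed)


def generate_phasic(
    n_neurons: int, duration: float, config: FiringConfig, seed: int
) -> SpikeTrainSet:
    """Tonic background with synchronized burst/pause events throughout."""
    if duration <= 0:
        raise ConfigError("duration must be positive")
    return generate(n_neurons, make_schedule(duration, 0.0), config, seed)


def empirical_rate(
    trains: SpikeTrainSet, window: Optional[Tuple[float, float]] = None
) -> float:
    """Pooled firing rate: total spikes in window / (window length × n_neurons)."""
    if window is None:
        window = (0.0, trains.duration)
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("empirical_rate window must have positive length")
    if t0 < 0 or t1 > trains.duration + 1e-12:
        raise ConfigError("window outside [0, duration]")
    n = sum(int(np.sum((s >= t0) & (s < t1))) for s in trains.spikes)
    return n / ((t1 - t0) * trains.n_neurons)
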