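"""Stimulation protocols: which populations receive the simulated
channelrhodopsin current, at what intensity, and when.

A protocol is an ordered list of epochs. Each epoch targets a subset of
populations with a constant intensity or a periodic pulse train, over a
half-open window ``[t_on, t_on + duration)``. Epochs may also be scheduled
relative to a detected respiratory landmark (phase-locked onset); such
protocols must be resolved to absolute times before evaluation — see
:func:`respcpg.simulate.run_phase_locked`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusEpoch",
    "StimulusProtocol",
    "PhaseLockedOnset",
    "stimulus_intensity_at",
    "segment_edges",
]


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulation episode.

    Parameters
    ----------
    targets : population indices (1-based) receiving the light.
    intensity : dimensionless light intensity stim_ChR, >= 0.
    t_on : onset time, ms (absolute, or relative to the phase-locking
        landmark when the protocol carries a phase-locked onset rule).
    duration : epoch length, ms; ``None`` means open-ended.
    waveform : ``"constant"`` or ``"pulse-train"``. A pulse train delivers
        ``pulse_width``-ms pulses every ``pulse_period`` ms, starting at
        ``t_on``, for the whole epoch.
    """

    targets: frozenset
    intensity: float
    t_on: float
    duration: Optional[float] = None
    waveform: str = "constant"
    pulse_width: Optional[float] = None
    pulse_period: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(int(i) for i in self.targets))
        if not self.targets <= {1, 2, 3, 4, 5}:
            raise ValueError("targets must be population indices in 1..5")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.waveform not in ("constant", "pulse-train"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.waveform == "pulse-train":
            if self.pulse_width is None or self.pulse_period is None:
                raise ValueError("pulse-train requires pulse_width and pulse_period")
            if not 0 < self.pulse_width <= self.pulse_period:
                raise ValueError("need 0 < pulse_width <= pulse_period")

    @property
    def t_off(self) -> float:
        return np.inf if self.duration is None else self.t_on + self.duration

    def active_at(self, t: float) -> bool:
        """Is the light on at time ``t``? Windows are half-open [on, off)."""
        if not (self.t_on <= t < self.t_off):
            return False
        if self.waveform == "constant":
            return True
        phase = (t - self.t_on) % self.pulse_period
        return phase < self.pulse_width

    def edges_within(self, t0: float, t1: float) -> list:
        """All on/off switching times of this epoch inside [t0, t1]."""
        edges = []
        if self.waveform == "constant":
            candidates = [self.t_on, self.t_off]
        else:
            candidates = [self.t_off]
            end = min(self.t_off, t1)
            k0 = max(0, int(np.floor((t0 - self.t_on) / self.pulse_period)) - 1)
            k = k0
            while True:
                rise = self.t_on + k * self.pulse_period
                if rise > end:
                    break
                candidates += [rise, min(rise + self.pulse_width, self.t_off)]
                k += 1
        for c in candidates:
            if t0 < c < t1 and np.isfinite(c):
                edges.append(float(c))
        return edges


@dataclass(frozen=True)
class PhaseLockedOnset:
    """Onset rule referencing epoch times to a detected respiratory landmark.

    ``reference`` is the landmark of the selected cycle ("inspiration-onset"
    or "expiration-onset", the latter being the inspiratory burst offset);
    epoch ``t_on`` values are then offsets in ms from that landmark, or, if
    ``offset_fraction`` is set, the fraction of the corresponding phase
    duration (inspiratory for inspiration-onset, expiratory otherwise).
    """

    reference: str = "inspiration-onset"
    cycle_index: int = 0
    offset_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reference not in ("inspiration-onset", "expiration-onset"):
            raise ValueError(f"unknown reference {self.reference!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered collection of stimulation epochs plus an onset rule."""

    epochs: tuple = ()
    onset_rule: object = "absolute-time"   # or a PhaseLockedOnset

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if self.onset_rule == "absolute-time":
            self._check_overlap()

    def _check_overlap(self) -> None:
        for pop in range(1, 6):
            spans = sorted(
                (e.t_on, e.t_off) for e in self.epochs if pop in e.targets
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping epochs for population {pop}")

    @property
    def is_resolved(self) -> bool:
        return self.onset_rule == "absolute-time"

    def resolved(self, landmark_time: float, phase_duration: float = None) -> "StimulusProtocol":
        """Convert a phase-locked protocol to absolute times.

        ``landmark_time`` is the absolute time of the referenced landmark;
        ``phase_duration`` supplies the phase length when the onset rule uses
        a fractional offset.
        """
        rule = self.onset_rule
        if rule == "absolute-time":
            return self
        epochs = []
        for e in self.epochs:
            shift = e.t_on
            if rule.offset_fraction is not None:
                if phase_duration is None:
                    raise ValueError("fractional offset needs phase_duration")
                shift = rule.offset_fraction * phase_duration + e.t_on
            epochs.append(dataclasses.replace(e, t_on=landmark_time + shift))
        return StimulusProtocol(tuple(epochs), "absolute-time")


def stimulus_intensity_at(protocol: StimulusProtocol, t: float) -> np.ndarray:
    """Per-population intensity vector at time ``t`` (length 5)."""
    if not protocol.is_resolved:
        raise ValueError("phase-locked protocol not yet resolved to absolute times")
    stim = np.zeros(5)
    for epoch in protocol.epochs:
        if epoch.active_at(t):
            for pop in epoch.targets:
                stim[pop - 1] += epoch.intensity
    return stim


def segment_edges(protocol: StimulusProtocol, t0: float, t1: float) -> np.ndarray:
    """Sorted integration breakpoints: t0, t1 and every stimulus on/off
    discontinuity in between. The integrator restarts at each edge so no
    switching event is stepped over."""
    if not protocol.is_resolved:
        raise ValueError("phase-locked protocol not yet resolved to absolute times")
    edges = {float(t0), float(t1)}
    for epoch in protocol.epochs:
        edges.update(epoch.edges_within(t0, t1))
    return np.array(sorted(edges))
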