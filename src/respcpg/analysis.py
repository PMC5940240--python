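"""Respiratory event detection and the simulated-optogenetics experiments.

Burst detection mirrors the experimental convention for phrenic-nerve
recordings: an inspiratory event begins when the pre-I/I output crosses a
threshold at 20% of the (median cycle) peak amplitude and ends at the next
downward crossing. All higher-level measurements — periods, phase durations,
rebound and reset latencies, frequency–intensity curves, suppression
thresholds, entrainment — are built on those crossings.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import DEFAULT_INITIAL_STATE, NetworkState
from .parameters import ModelParameters
from .protocol import PhaseLockedOnset, StimulusEpoch, StimulusProtocol
from .simulate import SolverSettings, Trace, integrate_model, run_phase_locked

__all__ = [
    "BurstTrain",
    "CycleMetrics",
    "SweepResult",
    "PhaseScanResult",
    "EntrainmentResult",
    "bisect_threshold",
    "detect_bursts",
    "cycle_metrics",
    "rebound_latency",
    "reset_latency",
    "phase_sensitivity_scan",
    "frequency_intensity_sweep",
    "find_suppression_threshold",
    "entrainment_test",
    "min_entrained_period",
    "settled_state",
]

#: crossings closer than this are merged into one burst, ms
MERGE_WINDOW_MS = 10.0
#: supra-threshold episodes shorter than this are not inspiratory bursts, ms
#: (inspiratory bursts last hundreds of ms; ms-scale disinhibition blips at
#: stimulus offsets must not be scored as events)
MIN_BURST_MS = 50.0


# ---------------------------------------------------------------------------
# event detection and cycle metrics


@dataclass
class BurstTrain:
    """Detected inspiratory events. Empty onsets signal apnea."""

    onsets: np.ndarray
    offsets: np.ndarray
    peak_values: np.ndarray
    detection_threshold: float       # fraction of the reference peak
    reference_peak: float            # median cycle peak used for the threshold

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0,1)")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def is_apnea(self) -> bool:
        return len(self.onsets) == 0


def _crossings(t: np.ndarray, x: np.ndarray, threshold: float):
    above = x >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    return t[up], t[down]


def _pair_events(ups: np.ndarray, downs: np.ndarray):
    """Pair upward with subsequent downward crossings, merging gaps shorter
    than MERGE_WINDOW_MS into a single burst."""
    onsets, offsets = [], []
    for u in ups:
        if len(offsets) < len(onsets):      # last burst never closed
            continue
        if offsets and u < offsets[-1]:     # inside the previous burst
            continue
        later = downs[downs > u]
        if offsets and u - offsets[-1] < MERGE_WINDOW_MS:
            offsets.pop()                   # brief dip: extend previous burst
            if len(later):
                offsets.append(later[0])
            continue
        onsets.append(u)
        if len(later):
            offsets.append(later[0])
    onsets, offsets = np.array(onsets), np.array(offsets)
    if len(offsets):
        # drop blips shorter than the minimum burst duration; an unfinished
        # trailing burst (onset without offset) is kept
        dur = offsets - onsets[: len(offsets)]
        keep = dur >= MIN_BURST_MS
        tail = onsets[len(offsets):]
        onsets = np.concatenate([onsets[: len(offsets)][keep], tail])
        offsets = offsets[keep]
    return onsets, offsets


def detect_bursts(
    trace: Trace,
    source_pop: int = 1,
    threshold_fraction: float = 0.2,
    reference_peak: Optional[float] = None,
    t_start: Optional[float] = None,
) -> BurstTrain:
    """Detect inspiratory bursts by threshold crossing of a population output.

    The threshold is ``threshold_fraction`` of the median cycle peak of the
    selected output (computed in two passes: a provisional threshold at the
    global maximum locates cycles, whose median peak then fixes the final
    threshold). Pass ``reference_peak`` to measure a stimulated trace against
    its unstimulated baseline amplitude instead.
    """
    if len(trace.t) == 0:
        raise ValueError("empty trace")
    sel = slice(None) if t_start is None else trace.t >= t_start
    t = trace.t[sel]
    x = trace.f[source_pop - 1][sel]
    if len(t) == 0:
        return BurstTrain(np.array([]), np.array([]), np.array([]),
                          threshold_fraction, 0.0)

    if reference_peak is None:
        peak = float(x.max())
        if peak <= 0.0:
            return BurstTrain(np.array([]), np.array([]), np.array([]),
                              threshold_fraction, 0.0)
        ups, downs = _crossings(t, x, threshold_fraction * peak)
        ons, offs = _pair_events(ups, downs)
        if len(ons) >= 2:
            peaks = [x[(t >= a) & (t < b)].max() for a, b in zip(ons, offs)]
            if peaks:
                peak = float(np.median(peaks))
    else:
        peak = float(reference_peak)

    threshold = threshold_fraction * peak
    ups, downs = _crossings(t, x, threshold)
    ons, offs = _pair_events(ups, downs)
    peaks = np.array([
        x[(t >= a) & (t < b)].max()
        for a, b in zip(ons, offs[: len(ons)])
    ]) if len(offs) else np.array([])
    return BurstTrain(ons, offs, peaks, threshold_fraction, peak)


@dataclass
class CycleMetrics:
    """Per-cycle periods and phase durations derived from a burst train.

    A period spans inspiration onset to the next inspiration onset and
    decomposes exactly into the inspiratory (onset→offset) and expiratory
    (offset→next onset) durations. Frequencies are in Hz (periods in ms).
    """

    periods: np.ndarray
    inspiratory_durations: np.ndarray
    expiratory_durations: np.ndarray

    @property
    def is_apnea(self) -> bool:
        return len(self.periods) == 0

    @property
    def mean_period(self) -> float:
        return float(np.mean(self.periods)) if len(self.periods) else np.nan

    @property
    def frequency(self) -> float:
        """Mean frequency, Hz; 0 for apnea."""
        return 1000.0 / self.mean_period if len(self.periods) else 0.0

    @property
    def per_cycle_frequency(self) -> np.ndarray:
        return 1000.0 / self.periods


def cycle_metrics(bursts: BurstTrain) -> CycleMetrics:
    """Reduce a burst train to periods and phase durations."""
    ons, offs = bursts.onsets, bursts.offsets
    if len(ons) < 2:
        empty = np.array([])
        return CycleMetrics(empty, empty, empty)
    n = len(ons) - 1
    t_i = np.array([offs[offs > ons[k]][0] - ons[k] for k in range(n)])
    periods = np.diff(ons)
    return CycleMetrics(periods, t_i, periods - t_i)


# ---------------------------------------------------------------------------
# latencies


def rebound_latency(
    trace: Trace,
    stimulus_end: float,
    bursts: Optional[BurstTrain] = None,
    baseline_period: Optional[float] = None,
    **detect_kwargs,
) -> Optional[float]:
    """Delay from stimulus end to the next inspiratory burst onset, ms.

    Returns ``None`` (non-rebounding) if no onset occurs within 5 baseline
    periods of the stimulus end (when ``baseline_period`` is given).
    """
    if bursts is None:
        bursts = detect_bursts(trace, **detect_kwargs)
    later = bursts.onsets[bursts.onsets > stimulus_end]
    if len(later) == 0:
        return None
    latency = float(later[0] - stimulus_end)
    if baseline_period is not None and latency > 5 * baseline_period:
        return None
    return latency


def reset_latency(
    trace: Trace,
    stimulus_onset: float,
    pulse_width: float,
    bursts: Optional[BurstTrain] = None,
    **detect_kwargs,
) -> Optional[float]:
    """Delay from stimulus onset to the evoked inspiratory burst onset, ms.

    An onset counts as evoked only if it falls during the pulse or within one
    pulse width after it; otherwise the rhythm was not reset and ``None`` is
    returned.
    """
    if bursts is None:
        bursts = detect_bursts(trace, **detect_kwargs)
    window_end = stimulus_onset + 2.0 * pulse_width
    evoked = bursts.onsets[(bursts.onsets > stimulus_onset) & (bursts.onsets <= window_end)]
    if len(evoked) == 0:
        return None
    return float(evoked[0] - stimulus_onset)


# ---------------------------------------------------------------------------
# baseline caching


@functools.lru_cache(maxsize=16)
def settled_state(
    params: ModelParameters,
    settings: SolverSettings = SolverSettings(),
    transient: float = 20000.0,
    measure: float = 40000.0,
):
    """Integrate past the transient and characterize the unstimulated rhythm.

    Returns ``(state, baseline)`` where ``state`` is the network state at the
    end of the transient and ``baseline`` a dict with the mean period,
    frequency and the median cycle peak of the pre-I/I output measured over
    ``measure`` ms after the transient. Cached per parameter set.
    """
    trace = integrate_model(params, StimulusProtocol(), (0.0, transient + measure),
                            settings=settings)
    idx = int(np.searchsorted(trace.t, transient))
    state = NetworkState(
        V=trace.V[:, idx].copy(), h_NaP=float(trace.h_NaP[idx]), m_AD=trace.m_AD[:, idx].copy()
    )
    bursts = detect_bursts(trace, t_start=transient)
    metrics = cycle_metrics(bursts)
    baseline = {
        "period": metrics.mean_period,
        "frequency": metrics.frequency,
        "peak_f1": bursts.reference_peak,
    }
    return state, baseline


# ---------------------------------------------------------------------------
# sweeps, thresholds, phase scans, entrainment


@dataclass
class SweepResult:
    """Tidy frequency–intensity sweep output (one row per intensity)."""

    intensities: np.ndarray
    frequency_ratio: np.ndarray       # mean frequency / baseline frequency
    rhythm_present: np.ndarray        # bool per intensity
    baseline_frequency: float
    targets: tuple

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "intensity": self.intensities,
            "frequency_ratio": self.frequency_ratio,
            "rhythm_present": self.rhythm_present,
        })


def _epoch_rhythm(
    params: ModelParameters,
    targets: Sequence[int],
    intensity: float,
    epoch_duration: float,
    settings: SolverSettings,
    guard: float = 2000.0,
):
    """Apply a constant epoch from the settled state; return (n_onsets, freq).

    Onsets are counted against the baseline burst amplitude, skipping a short
    guard window at the epoch start so the burst already underway at light
    onset is not scored as an evoked event.
    """
    state, baseline = settled_state(params, settings)
    protocol = StimulusProtocol((
        StimulusEpoch(frozenset(targets), intensity, t_on=0.0, duration=epoch_duration),
    ))
    trace = integrate_model(params, protocol, (0.0, epoch_duration), state, settings)
    bursts = detect_bursts(trace, reference_peak=baseline["peak_f1"], t_start=guard)
    metrics = cycle_metrics(bursts)
    return len(bursts), metrics.frequency, baseline


def frequency_intensity_sweep(
    params: ModelParameters,
    targets: Sequence[int],
    intensities: Sequence[float],
    epoch_duration: float = 60000.0,
    settings: SolverSettings = SolverSettings(),
) -> SweepResult:
    """Mean-frequency response to sustained constant stimulation.

    For each intensity the targeted populations receive a constant epoch of
    ``epoch_duration`` ms starting from the settled (post-transient) state;
    the mean frequency over the epoch is expressed as a ratio to the
    unstimulated baseline.
    """
    intensities = np.asarray(sorted(intensities), dtype=float)
    if len(intensities) < 2:
        raise ValueError("need at least 2 intensities")
    ratios, present = [], []
    for s in intensities:
        n_onsets, freq, baseline = _epoch_rhythm(params, targets, float(s),
                                                 epoch_duration, settings)
        ratios.append(freq / baseline["frequency"])
        present.append(n_onsets >= 2)
    return SweepResult(
        intensities=intensities,
        frequency_ratio=np.array(ratios),
        rhythm_present=np.array(present, dtype=bool),
        baseline_frequency=baseline["frequency"],
        targets=tuple(targets),
    )


def find_suppression_threshold(
    params: ModelParameters,
    targets: Sequence[int],
    bracket=(1.0, 3.0),
    resolution: float = 0.05,
    epoch_duration: float = 60000.0,
    settings: SolverSettings = SolverSettings(),
) -> float:
    """Smallest intensity whose sustained epoch abolishes inspiratory bursts.

    Bisection on the apnea predicate (zero pre-I/I onsets during the epoch,
    measured against the baseline amplitude) down to ``resolution``. The
    bracket must straddle the boundary: rhythm at the low end, apnea at the
    high end.
    """
    def apnea(s: float) -> bool:
        n_onsets, _, _ = _epoch_rhythm(params, targets, s, epoch_duration, settings)
        return n_onsets == 0

    return bisect_threshold(apnea, bracket, resolution)


def bisect_threshold(predicate, bracket, resolution: float) -> float:
    """Locate the boundary where a monotone boolean predicate switches on.

    Requires ``predicate(lo) == False`` and ``predicate(hi) == True``;
    bisects until the bracket is narrower than ``resolution`` and returns the
    upper end (the smallest probed value satisfying the predicate).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if predicate(lo) or not predicate(hi):
        raise ValueError(
            f"predicate not bracketed on [{lo}, {hi}]; widen the bracket"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class PhaseScanResult:
    """Reset outcomes of a pulse delivered across the expiratory phase."""

    offsets_ms: np.ndarray            # pulse onset, ms after inspiration offset
    reset: np.ndarray                 # bool per phase
    latencies: np.ndarray             # ms from pulse onset (nan if no reset)
    insensitive_window: float         # contiguous no-reset span from expiration start, ms
    expiratory_duration: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "offset_ms": self.offsets_ms,
            "reset": self.reset,
            "latency_ms": self.latencies,
        })


def phase_sensitivity_scan(
    params: ModelParameters,
    targets: Sequence[int] = (1, 2, 5),
    intensity: float = 0.2,
    duration: float = 300.0,
    n_phases: int = 20,
    settings: SolverSettings = SolverSettings(),
    transient: float = 20000.0,
) -> PhaseScanResult:
    """Deliver one pulse at ``n_phases`` onsets spanning one expiratory phase.

    Uses the two-pass phase-locking scheme for every onset (the model is
    deterministic, so pass 2 reproduces pass 1 exactly up to the pulse). The
    insensitive window is the span from inspiration offset to the first
    onset whose pulse resets the rhythm (full expiration if none does).
    """
    # pass 1 once: landmarks of the first post-transient cycle
    probe = StimulusProtocol(
        (StimulusEpoch(frozenset(targets), intensity, t_on=0.0, duration=duration),),
        PhaseLockedOnset("expiration-onset"),
    )
    _, _, baseline = run_phase_locked(
        params, probe, (0.0, transient + 20000.0), settings=settings, transient=transient
    )
    T_E = baseline["T_E"]
    landmark = baseline["inspiration_offset"]
    peak = baseline["peak_f1"]

    fracs = (np.arange(n_phases) + 0.5) / n_phases
    offsets = fracs * T_E
    reset_flags, latencies = [], []
    for off in offsets:
        t_on = landmark + off
        t_end = t_on + 2.0 * duration + 1500.0
        resolved = StimulusProtocol((
            StimulusEpoch(frozenset(targets), intensity, t_on=t_on, duration=duration),
        ))
        trace = integrate_model(params, resolved, (0.0, t_end), settings=settings)
        bursts = detect_bursts(trace, reference_peak=peak, t_start=transient)
        lat = reset_latency(trace, t_on, duration, bursts=bursts)
        reset_flags.append(lat is not None)
        latencies.append(np.nan if lat is None else lat)

    reset_arr = np.array(reset_flags, dtype=bool)
    if reset_arr.all():
        window = 0.0
    elif not reset_arr.any():
        window = T_E
    else:
        first_reset = int(np.argmax(reset_arr))
        window = float(offsets[first_reset]) if first_reset > 0 else 0.0
    return PhaseScanResult(
        offsets_ms=offsets,
        reset=reset_arr,
        latencies=np.array(latencies),
        insensitive_window=window,
        expiratory_duration=T_E,
    )


@dataclass
class EntrainmentResult:
    """1:1 phase-locking verdict for periodic pulse stimulation."""

    pulse_period: float
    locked: bool
    onsets_per_period: np.ndarray     # counts over the scored periods
    phase_sd: float                   # ms, onset phase SD over scored periods
    n_periods: int


def entrainment_test(
    params: ModelParameters,
    pulse_period: float,
    targets: Sequence[int] = (1, 2, 5),
    intensity: float = 0.2,
    pulse_width: float = 300.0,
    n_periods: int = 45,
    n_score: int = 10,
    settings: SolverSettings = SolverSettings(),
) -> EntrainmentResult:
    """Test 1:1 locking to a periodic pulse train.

    The train runs for ``n_periods`` stimulus periods from the settled state;
    locking requires exactly one inspiration onset in each of the final
    ``n_score`` periods with onset-phase standard deviation below 5% of the
    period.
    """
    if pulse_period <= pulse_width:
        raise ValueError("pulse_period must exceed pulse width")
    state, baseline = settled_state(params, settings)
    total = n_periods * pulse_period
    protocol = StimulusProtocol((
        StimulusEpoch(frozenset(targets), intensity, t_on=0.0, duration=total,
                      waveform="pulse-train", pulse_width=pulse_width,
                      pulse_period=pulse_period),
    ))
    trace = integrate_model(params, protocol, (0.0, total), state, settings)
    bursts = detect_bursts(trace, reference_peak=baseline["peak_f1"])
    counts, phases = [], []
    for k in range(n_periods - n_score, n_periods):
        a, b = k * pulse_period, (k + 1) * pulse_period
        inside = bursts.onsets[(bursts.onsets >= a) & (bursts.onsets < b)]
        counts.append(len(inside))
        if len(inside) == 1:
            phases.append(inside[0] - a)
    counts = np.array(counts)
    sd = float(np.std(phases)) if len(phases) == n_score else np.inf
    locked = bool((counts == 1).all() and sd < 0.05 * pulse_period)
    return EntrainmentResult(pulse_period, locked, counts, sd, n_periods)


def min_entrained_period(
    params: ModelParameters,
    targets: Sequence[int] = (1, 2, 5),
    intensity: float = 0.2,
    pulse_width: float = 300.0,
    step: float = 100.0,
    start_period: Optional[float] = None,
    settings: SolverSettings = SolverSettings(),
    **kwargs,
) -> dict:
    """Scan the pulse period downward until 1:1 locking fails.

    Starts at the intrinsic period (rounded down to the scan step) and
    returns the smallest period that still locked, with the per-period
    verdicts.
    """
    _, baseline = settled_state(params, settings)
    if start_period is None:
        start_period = np.floor(baseline["period"] / step) * step
    results = []
    last_locked = None
    period = start_period
    while period > pulse_width:
        res = entrainment_test(params, period, targets, intensity, pulse_width,
                               settings=settings, **kwargs)
        results.append(res)
        if not res.locked:
            break
        last_locked = period
        period -= step
    return {
        "min_locked_period": last_locked,
        "intrinsic_period": baseline["period"],
        "results": results,
    }
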