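"""Named presets reproducing the simulated optogenetic experiments.

Each preset encodes one stimulation scenario — target populations, intensity,
timing rule — together with the analysis recipe that summarizes it and a tag
naming its qualitative outcome. Pulse timings within a phase are fixed as
fractions of the baseline phase durations (0.3 of the inspiratory duration
for "during inspiration", 0.5 of the expiratory duration for "during
expiration", 0.9 for "end of expiration").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .analysis import (
    cycle_metrics,
    detect_bursts,
    entrainment_test,
    find_suppression_threshold,
    frequency_intensity_sweep,
    min_entrained_period,
    phase_sensitivity_scan,
    rebound_latency,
    reset_latency,
    settled_state,
)
from .parameters import BOTC_POPS, PRE_BOTC_POPS, ModelParameters
from .protocol import PhaseLockedOnset, StimulusEpoch, StimulusProtocol
from .simulate import SolverSettings, integrate_model, run_phase_locked

__all__ = ["ExperimentPreset", "RunRecord", "PRESETS", "SWEEP_SUITES",
           "run_preset", "run_sweep_suite", "list_presets"]

PRE_BOTC_INHIBITORY = (2, 5)      # early-I, post-I_pBC
BOTC_INHIBITORY = (3, 4)          # aug-E, post-I


@dataclass(frozen=True)
class ExperimentPreset:
    """A runnable stimulation scenario with its expected qualitative outcome."""

    name: str
    kind: str                     # pulse | sustained | train | phase-scan
    description: str
    expected_outcome: str
    targets: tuple = ()
    intensity: float = 0.0
    duration: float = 300.0       # pulse/epoch length, ms
    reference: str = "expiration-onset"
    offset_fraction: float = 0.5
    pulse_period: Optional[float] = None

    def config(self) -> dict:
        return dataclasses.asdict(self)


def _pulse_preset(name, targets, intensity, duration, reference, frac, tag, desc):
    return ExperimentPreset(
        name=name, kind="pulse", description=desc, expected_outcome=tag,
        targets=tuple(targets), intensity=intensity, duration=duration,
        reference=reference, offset_fraction=frac,
    )


PRESETS = {p.name: p for p in [
    # -- short pulses to the inhibitory pre-BötC populations (early-I, post-I_pBC)
    _pulse_preset("fig10A", PRE_BOTC_INHIBITORY, 1.0, 300.0, "inspiration-onset", 0.3,
                  "rhythm-unperturbed",
                  "weak 300 ms pulse during inspiration leaves the rhythm intact"),
    _pulse_preset("fig10B", PRE_BOTC_INHIBITORY, 1.0, 1000.0, "inspiration-onset", 0.3,
                  "rebound-advance",
                  "weak 1 s pulse outlasting inspiration advances the next burst"),
    _pulse_preset("fig10C", PRE_BOTC_INHIBITORY, 1.0, 300.0, "expiration-onset", 0.5,
                  "rebound-advance",
                  "weak 300 ms pulse in mid-expiration advances the next burst"),
    _pulse_preset("fig10D", PRE_BOTC_INHIBITORY, 1.0, 300.0, "expiration-onset", 0.9,
                  "inspiration-delayed",
                  "weak pulse at end-expiration delays inspiration until light off"),
    _pulse_preset("fig10E", PRE_BOTC_INHIBITORY, 2.0, 300.0, "inspiration-onset", 0.3,
                  "burst-truncated",
                  "strong 300 ms pulse during inspiration terminates the burst"),
    _pulse_preset("fig10F", PRE_BOTC_INHIBITORY, 2.0, 300.0, "expiration-onset", 0.5,
                  "rebound-advance",
                  "strong 300 ms pulse in expiration advances the next burst"),
    # -- sustained stimulation of the inhibitory pre-BötC populations
    ExperimentPreset("fig11A", "sustained",
                     "sustained pre-BötC inhibitory stimulation, low intensity",
                     "frequency-increase", PRE_BOTC_INHIBITORY, 0.3, 20000.0),
    ExperimentPreset("fig11B", "sustained",
                     "sustained pre-BötC inhibitory stimulation, high intensity",
                     "rhythm-present", PRE_BOTC_INHIBITORY, 1.6, 20000.0),
    ExperimentPreset("fig11C", "sustained",
                     "sustained pre-BötC inhibitory stimulation, stronger still",
                     "rhythm-present", PRE_BOTC_INHIBITORY, 2.0, 20000.0),
    # -- short/long pulses to the inhibitory BötC populations (aug-E, post-I)
    _pulse_preset("fig12A", BOTC_INHIBITORY, 1.0, 300.0, "inspiration-onset", 0.3,
                  "burst-truncated",
                  "300 ms BötC pulse during inspiration terminates the burst"),
    _pulse_preset("fig12B", BOTC_INHIBITORY, 1.0, 300.0, "expiration-onset", 0.5,
                  "rebound-advance",
                  "300 ms BötC pulse in expiration, rebound after light off"),
    _pulse_preset("fig12C", BOTC_INHIBITORY, 1.0, 5000.0, "inspiration-onset", 0.3,
                  "suppressed-during-pulse",
                  "5 s BötC pulse suppresses inspiratory activity throughout"),
    _pulse_preset("fig12D", BOTC_INHIBITORY, 1.0, 5000.0, "expiration-onset", 0.5,
                  "suppressed-during-pulse",
                  "5 s BötC pulse from expiration suppresses activity throughout"),
    # -- sustained stimulation of the inhibitory BötC populations
    ExperimentPreset("fig13A", "sustained",
                     "sustained BötC inhibitory stimulation, sub-threshold",
                     "frequency-decrease", BOTC_INHIBITORY, 0.14, 20000.0),
    ExperimentPreset("fig13B", "sustained",
                     "sustained BötC inhibitory stimulation, near threshold",
                     "frequency-decrease", BOTC_INHIBITORY, 0.18, 20000.0),
    # -- all pre-BötC populations (inhibitory + excitatory pre-I/I)
    ExperimentPreset("fig14A", "sustained",
                     "sustained stimulation of all pre-BötC populations",
                     "frequency-increase", PRE_BOTC_POPS, 0.18, 20000.0),
    ExperimentPreset("fig14B", "train",
                     "periodic 300 ms pulses to all pre-BötC populations",
                     "entrained", PRE_BOTC_POPS, 0.2, 300.0,
                     pulse_period=1500.0),
    ExperimentPreset("fig15B", "phase-scan",
                     "300 ms pulse to all pre-BötC populations across expiration",
                     "insensitive-window-present", PRE_BOTC_POPS, 0.2, 300.0),
]}

SWEEP_SUITES = ("preBotC-inhibitory", "BotC-inhibitory", "preBotC-all")


@dataclass
class RunRecord:
    """Provenance and summary of one preset or sweep-suite execution."""

    name: str
    config_hash: str
    version: str
    timestamp: str
    outputs: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _config_hash(*parts) -> str:
    payload = json.dumps(parts, sort_keys=True, default=_jsonable)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def list_presets() -> list:
    return sorted(PRESETS)


# ---------------------------------------------------------------------------
# preset execution


def _run_pulse(preset, params, settings) -> tuple:
    protocol = StimulusProtocol(
        (StimulusEpoch(frozenset(preset.targets), preset.intensity,
                       t_on=0.0, duration=preset.duration),),
        PhaseLockedOnset(preset.reference, cycle_index=0,
                         offset_fraction=preset.offset_fraction),
    )
    trace, resolved, baseline = run_phase_locked(
        params, protocol, (0.0, 48000.0 + preset.duration), settings=settings
    )
    epoch = resolved.epochs[0]
    bursts = detect_bursts(trace, reference_peak=baseline["peak_f1"], t_start=18000.0)
    metrics = cycle_metrics(bursts)

    onset_k = baseline["inspiration_onset"]
    burst_of_cycle = bursts.offsets[bursts.offsets > onset_k]
    perturbed_offset = float(burst_of_cycle[0]) if len(burst_of_cycle) else np.nan
    after = bursts.onsets[bursts.onsets > epoch.t_off]
    next_onset_after_pulse = float(after[0]) if len(after) else np.nan
    f1 = trace.f[0]
    during = (trace.t >= epoch.t_on + 50.0) & (trace.t < epoch.t_off)
    threshold = bursts.detection_threshold * bursts.reference_peak

    summary = {
        "pulse_on": epoch.t_on,
        "pulse_off": epoch.t_off,
        "baseline": baseline,
        "perturbed_burst_offset": perturbed_offset,
        "burst_truncated": bool(abs(perturbed_offset - epoch.t_on) <= 50.0),
        "next_onset_after_pulse": next_onset_after_pulse,
        "advance_ms": baseline["next_inspiration_onset"] - next_onset_after_pulse,
        "rebound_latency": rebound_latency(trace, epoch.t_off, bursts=bursts,
                                           baseline_period=baseline["period"]),
        "suppressed_during_pulse": bool(np.all(f1[during] < threshold)),
        "perturbed_cycle_period": (
            float(next_onset_after_pulse - onset_k)
            if np.isfinite(next_onset_after_pulse) else np.nan
        ),
        "steady_period_after": (
            float(np.mean(np.diff(after))) if len(after) >= 3 else np.nan
        ),
        "mean_period_after": metrics.mean_period,
    }
    return trace, summary


def _run_sustained(preset, params, settings) -> tuple:
    state, baseline = settled_state(params, settings)
    protocol = StimulusProtocol((
        StimulusEpoch(frozenset(preset.targets), preset.intensity,
                      t_on=0.0, duration=preset.duration),
    ))
    trace = integrate_model(params, protocol, (0.0, preset.duration), state, settings)
    bursts = detect_bursts(trace, reference_peak=baseline["peak_f1"], t_start=2000.0)
    metrics = cycle_metrics(bursts)
    summary = {
        "baseline": baseline,
        "n_bursts": len(bursts),
        "apnea": bursts.is_apnea,
        "frequency": metrics.frequency,
        "frequency_ratio": metrics.frequency / baseline["frequency"],
    }
    return trace, summary


def _run_train(preset, params, settings) -> tuple:
    res = entrainment_test(
        params, preset.pulse_period, preset.targets, preset.intensity,
        preset.duration, settings=settings,
    )
    _, baseline = settled_state(params, settings)
    summary = {
        "baseline": baseline,
        "pulse_period": res.pulse_period,
        "locked": res.locked,
        "onsets_per_period": res.onsets_per_period,
        "phase_sd": res.phase_sd,
    }
    return None, summary


def _run_phase_scan(preset, params, settings) -> tuple:
    scan = phase_sensitivity_scan(
        params, preset.targets, preset.intensity, preset.duration,
        n_phases=20, settings=settings,
    )
    summary = {
        "insensitive_window": scan.insensitive_window,
        "expiratory_duration": scan.expiratory_duration,
        "n_reset": int(scan.reset.sum()),
        "n_phases": len(scan.reset),
        "median_reset_latency": float(np.nanmedian(scan.latencies))
        if scan.reset.any() else np.nan,
    }
    return scan, summary


#: predicates validating each qualitative outcome tag against a run summary
OUTCOME_CHECKS = {
    # no burst termination, no lasting period change, at most a small
    # transient phase shift of the cycle containing the pulse
    "rhythm-unperturbed": lambda s: (
        not s["burst_truncated"]
        and abs(s["steady_period_after"] - s["baseline"]["period"])
        <= 0.02 * s["baseline"]["period"]
        and abs(s["perturbed_cycle_period"] - s["baseline"]["period"])
        <= 0.05 * s["baseline"]["period"]
    ),
    "burst-truncated": lambda s: s["burst_truncated"],
    "rebound-advance": lambda s: s["advance_ms"] > 50.0,
    "inspiration-delayed": lambda s: (
        -s["advance_ms"] > 50.0
        and s["next_onset_after_pulse"] > s["pulse_off"]
    ),
    "suppressed-during-pulse": lambda s: s["suppressed_during_pulse"],
    "frequency-increase": lambda s: s["frequency_ratio"] > 1.02,
    "frequency-decrease": lambda s: 0 < s["frequency_ratio"] < 0.98,
    "rhythm-present": lambda s: not s["apnea"],
    "apnea": lambda s: s["apnea"],
    "entrained": lambda s: s["locked"],
    "insensitive-window-present": lambda s: (
        0 < s["insensitive_window"] < s["expiratory_duration"]
    ),
}


def run_preset(
    name: str,
    output_dir=None,
    params: ModelParameters = ModelParameters(),
    settings: SolverSettings = SolverSettings(),
) -> RunRecord:
    """Execute a named preset; optionally write trace CSV and metrics JSON."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}")
    preset = PRESETS[name]
    runner = {
        "pulse": _run_pulse,
        "sustained": _run_sustained,
        "train": _run_train,
        "phase-scan": _run_phase_scan,
    }[preset.kind]
    trace, summary = runner(preset, params, settings)
    summary["outcome"] = preset.expected_outcome
    summary["outcome_confirmed"] = bool(OUTCOME_CHECKS[preset.expected_outcome](summary))

    record = RunRecord(
        name=name,
        config_hash=_config_hash(preset.config(), params.to_dict(),
                                 dataclasses.asdict(settings)),
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        summary=summary,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if trace is not None and hasattr(trace, "to_csv"):
            trace.to_csv(out / f"{name}_trace.csv")
            record.outputs["trace"] = str(out / f"{name}_trace.csv")
        elif trace is not None and hasattr(trace, "to_dataframe"):
            trace.to_dataframe().to_csv(out / f"{name}_scan.csv", index=False)
            record.outputs["scan"] = str(out / f"{name}_scan.csv")
        record.to_json(out / f"{name}_metrics.json")
        record.outputs["metrics"] = str(out / f"{name}_metrics.json")
    return record


def run_sweep_suite(
    suite: str,
    output_dir=None,
    params: ModelParameters = ModelParameters(),
    settings: SolverSettings = SolverSettings(),
    epoch_duration: float = 60000.0,
) -> RunRecord:
    """Run one of the frequency/threshold/entrainment sweep suites."""
    if suite not in SWEEP_SUITES:
        raise KeyError(f"unknown suite {suite!r}; available: {SWEEP_SUITES}")

    summary, tables = {}, {}
    if suite == "preBotC-inhibitory":
        sweep = frequency_intensity_sweep(
            params, PRE_BOTC_INHIBITORY, np.arange(0.1, 1.81, 0.1),
            epoch_duration, settings)
        threshold = find_suppression_threshold(
            params, PRE_BOTC_INHIBITORY, (1.0, 3.0), 0.05, epoch_duration, settings)
        summary = {
            "targets": PRE_BOTC_INHIBITORY,
            "suppression_threshold": threshold,
            "scan_resolution": 0.05,
            "max_ratio_intensity": float(
                sweep.intensities[int(np.argmax(sweep.frequency_ratio))]),
        }
        tables["sweep"] = sweep.to_dataframe()
    elif suite == "BotC-inhibitory":
        sweep = frequency_intensity_sweep(
            params, BOTC_INHIBITORY, np.arange(0.02, 0.221, 0.02),
            epoch_duration, settings)
        threshold = find_suppression_threshold(
            params, BOTC_INHIBITORY, (0.05, 0.5), 0.01, epoch_duration, settings)
        summary = {
            "targets": BOTC_INHIBITORY,
            "suppression_threshold": threshold,
            "scan_resolution": 0.01,
        }
        tables["sweep"] = sweep.to_dataframe()
    else:  # preBotC-all: entrainment scan
        scan = min_entrained_period(params, PRE_BOTC_POPS, 0.2, 300.0,
                                    settings=settings)
        import pandas as pd

        tables["entrainment"] = pd.DataFrame({
            "pulse_period_ms": [r.pulse_period for r in scan["results"]],
            "locked": [r.locked for r in scan["results"]],
            "phase_sd_ms": [r.phase_sd for r in scan["results"]],
        })
        summary = {
            "targets": PRE_BOTC_POPS,
            "min_locked_period_ms": scan["min_locked_period"],
            "intrinsic_period_ms": scan["intrinsic_period"],
        }

    record = RunRecord(
        name=suite,
        config_hash=_config_hash(suite, params.to_dict(),
                                 dataclasses.asdict(settings), epoch_duration),
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        summary=summary,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in tables.items():
            path = out / f"{suite}_{key}.csv"
            df.to_csv(path, index=False)
            record.outputs[key] = str(path)
        record.to_json(out / f"{suite}_summary.json")
        record.outputs["summary"] = str(out / f"{suite}_summary.json")
    return record
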