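# Methods

## Model

The package implements a five-population activity-based (firing-rate) model of
the respiratory central pattern generator spanning the pre-Bötzinger and
Bötzinger complexes. Each population is reduced to one average membrane
potential *V*ᵢ; its output f(Vᵢ), a sigmoid in [0, 1], stands in for the
population firing rate. The description is conductance-based but omits the
fast spike-generating currents, so the state space is small (9 variables) and
the mechanisms stay analyzable:

* **pre-I/I** (*i* = 1, excitatory, pre-BötC) — carries the persistent sodium
  current I_NaP = ḡ_NaP·m_NaP(V₁)·h_NaP·(V₁ − E_Na) with instantaneous
  activation and slow inactivation h_NaP (the rhythmogenic slow variable),
  plus a delayed-rectifier current I_K = ḡ_K·m_K⁴(V₁)·(V₁ − E_K).
* **early-I** (*i* = 2, inhibitory, pre-BötC), **aug-E** (*i* = 3, inhibitory,
  BötC), **post-I** (*i* = 4, inhibitory, BötC), **post-I_pBC** (*i* = 5,
  inhibitory, pre-BötC) — each adapts through an outward current
  I_AD,i = ḡ_AD·m_AD,i·(Vᵢ − E_K), with τ_AD,i·ṁ_AD,i = k_AD,i·f(Vᵢ) − m_AD,i.

All populations receive a leak current, a tonic excitatory synaptic drive
(the early-I population additionally receives phasic excitation a₁₂·f(V₁)
from the burster), inhibition g_SynI·Σⱼ b_ji·f(Vⱼ)·(Vᵢ − E_SynI) from the four
inhibitory populations, and a simulated channelrhodopsin current
I_ChR = ḡ_ChR·stim_ChR(t)·(Vᵢ − E_ChR) when targeted by light. Units are mV,
ms, nS and pF, under which nS·mV/pF = mV/ms and no conversion constants
appear.

Gating functions (pre-I/I): m_NaP = 1/(1+exp[−(V₁+40)/6]),
h∞ = 1/(1+exp[(V₁+48)/6]), τ_h = τ_max/cosh[(V₁+48)/12],
m_K = 1/(1+exp[−(V₁+30)/4]).

Two equation-reading choices are deliberate and recorded here:

1. **Gate sign convention.** The activation expressions are implemented with
   half-activations at −40 mV (m_NaP) and −30 mV (m_K) and positive slopes.
   The alternative literal grouping of the printed gate strings would place
   the half-activations at +40/+30 mV, giving essentially zero activation at
   physiological voltages and no bursting at all; the adopted convention is
   the one used throughout this model lineage.
2. **Delayed-rectifier composition.** I_K is ḡ_K·m_K⁴·(V₁ − E_K). The source
   description typesets an additional h_NaP factor in I_K; delayed rectifiers
   in the predecessor models are not gated by persistent-sodium inactivation
   and we treat that factor as a typesetting artifact. The literal form is
   available as the parameter toggle `delayed_rectifier_gated_by_hnap` for
   sensitivity checks; with default parameters it changes the baseline period
   by about 1% and none of the qualitative behaviors.

The output function is hard-clamped to exactly 0 below −60 mV. This
discontinuity is part of the model definition and is kept exact rather than
smoothed; the integrator absorbs it with adaptive stepping (see below). One
degenerate corner is worth knowing about: a silent fixed point lying exactly
at −60 mV (e.g. with all drives zero and E_L = −60) sits *on* the
discontinuity and makes adaptive solvers chatter. The test suite probes the
rest state with E_L moved just below the cutoff.

## Default parameters

The default `ModelParameters()` construction is the published set: C = 20 pF;
ḡ_NaP = 5, ḡ_K = 5, ḡ_AD = 10, ḡ_L = 2.8, ḡ_SynE = 10, ḡ_SynI = 60,
ḡ_ChR = 8 nS; E_Na = 50, E_K = −85, E_L = −60, E_SynE = 0, E_SynI = −75,
E_ChR = 0 mV; a₁₂ = 0.5; the 4×5 inhibitory weight table b (sources 2–5 ×
targets 1–5); drives (0.21, 0.59, 0.73, 0.72, 0.3); V½ = −30 mV, k_V =
(8, 4, 4, 4, 4) mV; τ_hNaP,max = 2000 ms, τ_AD = (2000, 1500, 1000, 500) ms,
k_AD = (0.9, 0.9, 1.3, 1.7). The strongest single weight, post-I_pBC → pre-I/I
(b₅₁ = 1.4), is what lets the novel pre-BötC post-inspiratory population
terminate inspiration and produce rebound bursts; the fast, strong adaptation
of that population (τ = 500 ms, k = 1.7) shapes its brief transient firing.

With these values the unstimulated network converges to the three-phase
rhythm with a 2.92 s cycle (0.34 Hz), 0.79 s inspiration, 2.14 s expiration
(computed by the worked example in the README and asserted by the tests).
The aug-E output is the lowest-amplitude signal of the five (peak ≈ 0.08 at
baseline): its augmenting ramp is clearly resolved but small, because the
printed weights keep it under strong post-I and post-I_pBC inhibition for
most of expiration.

## Numerics

* **Integrator.** LSODA (adaptive variable-order multistep, stiffness-
  switching) with rtol = atol = 1e−8 and max step 50 ms. The baseline cycle
  period agrees within 0.1% with a rerun at 1e−10 (asserted in the suite).
* **Stimulus discontinuities.** Integration is segmented at every stimulus
  on/off edge (pulse trains are expanded into their individual edges), so no
  switching event can be stepped over; within a segment the applied intensity
  is constant.
* **Output grid.** Uniform 1 ms sampling (configurable); fine enough to
  resolve the ~100 ms-scale latencies the analysis reports.
* **Initial conditions and transient.** The sources do not state initial
  conditions. We use Vᵢ = −60 mV, h_NaP = 0.6, m_AD = 0 (inside the invariant
  ranges h ∈ [0,1], m_AD,i ∈ [0, k_AD,i], which the flow preserves) and
  discard the first 20 s before any measurement; cycle-to-cycle period
  differences fall below 0.5% well within that window.
* **Determinism.** There is no randomness anywhere: identical calls produce
  bitwise-identical traces. Solver settings carry a `seed` field that is
  recorded in metadata for forward compatibility but never used.

## Stimulation protocols and phase locking

Protocols are ordered lists of epochs (targets, intensity, onset, duration,
constant or pulse-train waveform) with half-open active windows
[t_on, t_off). Phase-referenced delivery uses a two-pass scheme: pass 1
simulates without stimulation and detects inspiratory burst onsets/offsets;
the requested landmark (inspiration onset or expiration onset, plus an offset
in ms or as a fraction of the corresponding phase duration) is converted to
an absolute time; pass 2 re-simulates from the identical initial state with
the epoch placed there. Because the model is deterministic, pass 2 reproduces
pass 1 exactly up to the stimulus. Whether the original simulated experiments
triggered on detected onsets or on a pre-computed schedule is not stated in
the sources; the onset-referenced two-pass scheme is this package's choice
and is recorded in every resolved protocol.

Sustained stimulation is modeled as a constant intensity (the experimental
counterpart used 20 Hz light trains; under continuous light ChR2 partially
inactivates, which is why sustained model intensities occupy a range about
half that of short pulses). The 20 Hz train remains available as an explicit
pulse-train waveform for sensitivity checks.

Pulse presets place "during inspiration" at 0.3 of the inspiratory duration
after onset, "during expiration" at 0.5 of the expiratory duration after the
burst offset, and "end of expiration" at 0.9 — the sources do not specify the
panel timings numerically, so these fractions are fixed conventions recorded
in each preset.

## Analysis conventions

* **Burst detection** mirrors the experimental criterion for integrated
  phrenic-nerve signals: threshold at 20% of the median cycle peak of the
  pre-I/I output, onset at upward crossing, offset at the next downward
  crossing. Crossings closer than 10 ms are merged; supra-threshold episodes
  shorter than 50 ms are discarded (stimulus-offset disinhibition produces
  1–3 ms blips in f₁ that no smoothed experimental record would register as a
  breath — inspiratory bursts last ~800 ms). Onsets shift by ~7 ms between
  15% and 25% thresholds (the burst rise time), leaving all periods and
  latencies effectively unchanged; this sensitivity is asserted in the suite.
  Stimulated traces are scored against the *baseline* amplitude, so that an
  epoch that suppresses the rhythm is not re-thresholded against its own
  residual ripple.
* **Apnea** during an epoch = zero detected onsets (after a 2 s settle guard
  at the epoch start, so the burst already underway at light onset is not
  scored); a trace with fewer than two onsets yields an apnea metrics object
  with frequency 0.
* **Rebound latency** is referenced to the end of the stimulus (the
  experimental definition for inhibitory-population protocols); **reset
  latency** is referenced to the stimulus onset (used for the all-population
  protocols), and an onset counts as evoked only if it falls during the pulse
  or within one pulse width after it. Both references are reported in result
  objects to avoid ambiguity. The reset latency is measured to burst onset
  (the sources do not say onset vs. peak; onset is adopted).
* **Insensitive window** (phase scan): the pulse is delivered at n = 20
  onsets placed at the midpoints of equal subdivisions of one expiratory
  phase; the window is the span from inspiration offset to the first onset
  whose pulse resets the rhythm.
* **Suppression thresholds**: bisection on the apnea predicate, each probe a
  60 s constant epoch entered from the settled (20 s) state; resolution 0.05
  for pre-BötC scans and 0.01 for BötC scans, matching the magnitude of the
  reported boundaries.
* **Frequency ratios**: mean frequency over a 60 s epoch (≥ 10 post-transient
  cycles at baseline rate) divided by the unstimulated baseline frequency.
* **Entrainment**: 1:1 locking requires, over the final 10 of 45 stimulus
  periods, exactly one inspiration onset per period with onset-phase standard
  deviation below 5% of the period. The sources state only that entrainment
  occurs; this operational criterion (counts + phase jitter) is ours.

These problem sizes (60 s epochs, 45-period trains, 20-phase scans) keep
every experiment deterministic and desk-scale while leaving ≥ 10 cycles in
every averaged quantity.

## What the simulated experiments do and do not show

All inputs are model-generated; there is no external data. Passing tests
demonstrate that the implemented equations reproduce the network mechanisms —
three-phase ordering, phase- and intensity-dependent pulse responses, rebound
with fixed latency gated by aug-E release, the post-inspiratory refractory
window set by post-I adaptation, entrainment. They do not certify the
biological system: the model has homogeneous populations, no noise, no
spiking, no sensory feedback, and its quantitative constants were tuned by
the original authors to a particular in situ preparation.

## Known limitations

* **Sustained-stimulation regime is integration-accuracy sensitive.** At
  tightly converged tolerances, sustained activation of the two inhibitory
  pre-BötC populations abolishes the rhythm only near stim_ChR ≈ 2.84 (the
  stimulated populations keep escaping through their own adaptation cycles),
  the biphasic frequency-ratio curve peaks near 0.3 and first crosses unity
  near 0.65, and the BötC suppression boundary is ≈ 0.226 with a 60 s epoch.
  Reported boundaries for this model family are lower (≈ 1.8, turnover ≈ 1,
  ≈ 0.18). Loosely-toleranced multistep integration (rtol ~1e−3), typical of
  legacy solver defaults, smears the fast escape cycles through the −60 mV
  output cutoff and suppresses the rhythm at visibly lower intensities — we
  verified that the tight-tolerance solutions are solver-independent
  (LSODA 1e−8 vs 1e−10) and kept them, reporting the converged values. Near
  the BötC boundary the cycle period also diverges, so that threshold
  additionally depends on the epoch length used to declare apnea.
* The pulse-based quantities are robust: mid-expiratory reset latency 187 ms,
  insensitive window 267 ms (20-phase scan), minimum entrained period 1.3 s,
  rebound latencies independent of intensity and duration within 10% — all
  recomputed by `scripts/acceptance.py` and the test suite.
* The hard output cutoff makes the right-hand side discontinuous in state;
  LSODA handles it robustly away from degenerate fixed points, but
  equilibria placed exactly at the cutoff (drive-free networks with
  E_L = −60) integrate very slowly. This is a property of the printed model,
  not of the implementation.
* Population-level outputs cannot be mapped one-to-one onto single-neuron
  firing or synaptic conductances; comparisons with experiments are
  qualitative by construction.
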