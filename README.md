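# respcpg

An activity-based computational model of the core respiratory central pattern
generator — the pre-Bötzinger complex (pre-BötC) and Bötzinger complex (BötC)
microcircuits of the mammalian medulla — together with a simulated-optogenetics
protocol engine and an analysis layer for the perturbation experiments such a
model is built to explain: phase-dependent light pulses, sustained
photostimulation, frequency–intensity curves, rhythm reset, the
post-inspiratory refractory window, and entrainment by periodic pulses.

It is written for computational neuroscientists and respiratory physiologists
who want to run, probe, or extend the five-population network model of
inspiratory–expiratory pattern generation with inhibitory interactions between
the two compartments.

## The model

Five neural populations interact: the excitatory pre-inspiratory/inspiratory
population (pre-I/I, *i* = 1), the inhibitory early-inspiratory (early-I,
*i* = 2) and post-inspiratory (post-I_pBC, *i* = 5) populations of the
pre-BötC, and the inhibitory augmenting-expiratory (aug-E, *i* = 3) and
post-inspiratory (post-I, *i* = 4) populations of the BötC. Each population is
an activity-based (firing-rate) unit: its average membrane potential *V*ᵢ obeys

    C dV₁/dt = −I_NaP − I_K − I_L − I_SynE − I_SynI − I_ChR       (pre-I/I)
    C dVᵢ/dt = −I_AD,i − I_L − I_SynE − I_SynI − I_ChR            (i = 2..5)

with population output f(Vᵢ) = 1/(1 + exp[−(Vᵢ − V½)/k_Vi]) for Vᵢ ≥ −60 mV
and 0 below. The pre-I/I population carries a persistent sodium current
I_NaP = ḡ_NaP·m_NaP·h_NaP·(V₁ − E_Na) whose slow inactivation h_NaP is the
rhythmogenic variable; populations 2–5 instead adapt through an outward
current I_AD,i = ḡ_AD·m_AD,i·(Vᵢ − E_K) with τ_AD,i·dm_AD,i/dt =
k_AD,i·f(Vᵢ) − m_AD,i. Inhibitory synaptic weights b_ji couple the four
inhibitory populations to every other population; simulated channelrhodopsin
stimulation enters as an ohmic current I_ChR = ḡ_ChR·stim_ChR(t)·(Vᵢ − E_ChR)
on the targeted populations. With the default parameter set the network
produces the eupneic three-phase rhythm: inspiration (pre-I/I + early-I),
post-inspiration (post-I decrementing, a brief post-I_pBC transient), then
late expiration (aug-E augmenting).

See `docs/methods.md` for the full equations, parameter table rationale,
numerical choices and known limitations, and `schema/parameters.schema.json`
for the parameter file format.

## Worked example

```python
from respcpg import ModelParameters, StimulusProtocol, integrate_model
from respcpg.analysis import detect_bursts, cycle_metrics

trace = integrate_model(ModelParameters(), StimulusProtocol(), (0, 60_000))
bursts = detect_bursts(trace, t_start=20_000)        # discard the transient
m = cycle_metrics(bursts)
print(f"period {m.mean_period:.0f} ms   frequency {m.frequency:.3f} Hz")
print(f"T_I {m.inspiratory_durations.mean():.0f} ms   T_E {m.expiratory_durations.mean():.0f} ms")
```

prints

```
period 2923 ms   frequency 0.342 Hz
T_I 787 ms   T_E 2136 ms
```

i.e. the unstimulated network breathes at 0.34 Hz with ~0.8 s inspiratory and
~2.1 s expiratory phases. Stimulation experiments are available as named
presets from the command line; for example, a strong (stim_ChR = 2) 300 ms
pulse to the two inhibitory pre-BötC populations delivered mid-inspiration:

```
$ respcpg preset fig10E -o results/
fig10E: outcome=burst-truncated confirmed=True
```

which writes the dense trace (`fig10E_trace.csv`) and the measured latencies
and periods (`fig10E_metrics.json`). `respcpg list-presets` enumerates all
panels; `respcpg sweep preBotC-inhibitory` runs the frequency–intensity sweep
and suppression-threshold search for sustained stimulation of the inhibitory
pre-BötC populations.

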