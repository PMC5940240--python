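"""Right-hand side of the population ODE system.

State layout (9 dynamical variables, packed into a length-10 vector for the
integrator): average voltages ``V_1..V_5`` (mV), the persistent-sodium
inactivation ``h_NaP`` of the pre-I/I population, and the adaptation levels
``m_AD_i`` of populations 2–5.

The pre-I/I population carries a persistent sodium current I_NaP (with
instantaneous activation and slow inactivation h_NaP) and a delayed-rectifier
potassium current I_K; populations 2–5 instead carry an adaptive outward
potassium current I_AD driven toward ``k_AD_i * f_i``. Every population
receives a leak current, tonic excitatory synaptic drive, inhibitory synaptic
input weighted by the ``b`` table, and an ohmic channelrhodopsin current
proportional to the applied light intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cosh, exp

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "NetworkState",
    "GateValues",
    "CurrentDecomposition",
    "output_activity",
    "output_activities",
    "gate_steady_states",
    "membrane_currents",
    "state_derivative",
    "make_rhs",
    "DEFAULT_INITIAL_STATE",
]

#: below this average voltage a population is considered fully silent and its
#: output is clamped to exactly zero (hard cutoff of the output function)
SILENCE_CUTOFF_MV = -60.0


@dataclass
class NetworkState:
    """The 9 dynamical variables of the network."""

    V: np.ndarray          # (5,) average voltages, mV
    h_NaP: float           # persistent-sodium inactivation of pop 1, in [0,1]
    m_AD: np.ndarray       # (4,) adaptation of pops 2..5

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.m_AD = np.asarray(self.m_AD, dtype=float)
        if self.V.shape != (5,):
            raise ValueError("V must have shape (5,)")
        if self.m_AD.shape != (4,):
            raise ValueError("m_AD must have shape (4,)")

    def to_vector(self) -> np.ndarray:
        return np.concatenate((self.V, [self.h_NaP], self.m_AD))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "NetworkState":
        y = np.asarray(y, dtype=float)
        return cls(V=y[:5].copy(), h_NaP=float(y[5]), m_AD=y[6:10].copy())

    def copy(self) -> "NetworkState":
        return NetworkState(self.V.copy(), self.h_NaP, self.m_AD.copy())


#: voltages at leak reversal, h_NaP mid-range, adaptation fully recovered
DEFAULT_INITIAL_STATE = NetworkState(
    V=np.full(5, -60.0), h_NaP=0.6, m_AD=np.zeros(4)
)


@dataclass(frozen=True)
class GateValues:
    """Instantaneous gating variables of the pre-I/I population."""

    m_NaP: float       # persistent-sodium activation (instantaneous)
    h_inf_NaP: float   # steady-state persistent-sodium inactivation
    tau_hNaP: float    # inactivation time constant, ms
    m_K: float         # delayed-rectifier activation (instantaneous)


def output_activity(V: float, pop_index: int, params: ModelParameters) -> float:
    """Population output f_i(V_i) in [0, 1].

    A sigmoid with shared half-activation ``V_half`` and per-population slope
    ``k_V_i``, hard-clamped to 0 below −60 mV (silent population).

    Parameters
    ----------
    V : average voltage, mV.
    pop_index : population index, 1-based (1..5).
    """
    if not 1 <= pop_index <= 5:
        raise ValueError(f"pop_index must be in 1..5, got {pop_index}")
    if V < SILENCE_CUTOFF_MV:
        return 0.0
    return 1.0 / (1.0 + exp(-(V - params.V_half) / params.k_V[pop_index - 1]))


def output_activities(V, params: ModelParameters) -> np.ndarray:
    """Vectorized outputs; V may be shape (5,) or (5, T)."""
    V = np.asarray(V, dtype=float)
    k = np.asarray(params.k_V)
    if V.ndim == 2:
        k = k[:, None]
    f = 1.0 / (1.0 + np.exp(-(V - params.V_half) / k))
    return np.where(V < SILENCE_CUTOFF_MV, 0.0, f)


def gate_steady_states(V1: float, params: ModelParameters) -> GateValues:
    """Gating variables of the pre-I/I population at voltage ``V1``.

    Persistent-sodium activation half-activates at −40 mV (slope 6 mV) and
    the delayed rectifier at −30 mV (slope 4 mV); inactivation half-occurs at
    −48 mV with its time constant peaking there at ``tau_hNaP_max``.
    """
    return GateValues(
        m_NaP=1.0 / (1.0 + exp(-(V1 + 40.0) / 6.0)),
        h_inf_NaP=1.0 / (1.0 + exp((V1 + 48.0) / 6.0)),
        tau_hNaP=params.tau_hNaP_max / cosh((V1 + 48.0) / 12.0),
        m_K=1.0 / (1.0 + exp(-(V1 + 30.0) / 4.0)),
    )


@dataclass
class CurrentDecomposition:
    """Per-population membrane currents, nS·mV.

    Entries that do not exist for a population (I_NaP and I_K outside the
    pre-I/I population, I_AD for the pre-I/I population) are zero.
    """

    I_NaP: np.ndarray
    I_K: np.ndarray
    I_AD: np.ndarray
    I_L: np.ndarray
    I_SynE: np.ndarray
    I_SynI: np.ndarray
    I_ChR: np.ndarray

    def total(self) -> np.ndarray:
        return (self.I_NaP + self.I_K + self.I_AD + self.I_L
                + self.I_SynE + self.I_SynI + self.I_ChR)


def membrane_currents(
    state: NetworkState, params: ModelParameters, stim
) -> CurrentDecomposition:
    """Decompose the membrane current of every population.

    ``stim`` is the per-population instantaneous light intensity (length 5,
    all entries >= 0); the channelrhodopsin current is ohmic,
    ``g_ChR * stim_i * (V_i - E_ChR)``.
    """
    stim = np.asarray(stim, dtype=float)
    if stim.shape != (5,):
        raise ValueError("stim must have shape (5,)")
    if np.any(stim < 0):
        raise ValueError("stim intensities must be >= 0")

    V = state.V
    f = output_activities(V, params)
    gates = gate_steady_states(V[0], params)

    I_NaP = np.zeros(5)
    I_K = np.zeros(5)
    I_AD = np.zeros(5)
    I_NaP[0] = params.g_NaP * gates.m_NaP * state.h_NaP * (V[0] - params.E_Na)
    I_K[0] = params.g_K * gates.m_K ** 4 * (V[0] - params.E_K)
    if params.delayed_rectifier_gated_by_hnap:
        I_K[0] *= state.h_NaP
    I_AD[1:] = params.g_AD * state.m_AD * (V[1:] - params.E_K)

    syn_drive = params.drive_array.copy()
    syn_drive[1] += params.a12 * f[0]       # pre-I/I excites early-I
    I_SynE = params.g_SynE * syn_drive * (V - params.E_SynE)
    I_SynI = params.g_SynI * (f[1:] @ params.b_matrix) * (V - params.E_SynI)
    I_L = params.g_L * (V - params.E_L)
    I_ChR = params.g_ChR * stim * (V - params.E_ChR)

    return CurrentDecomposition(I_NaP, I_K, I_AD, I_L, I_SynE, I_SynI, I_ChR)


def state_derivative(t, state: NetworkState, params: ModelParameters, stim_fn) -> NetworkState:
    """Time derivative of the network state.

    ``stim_fn`` maps time (ms) to the per-population intensity vector.
    Returns a :class:`NetworkState` whose fields hold d/dt values.
    """
    currents = membrane_currents(state, params, stim_fn(t))
    dV = -currents.total() / params.C
    gates = gate_steady_states(state.V[0], params)
    dh = (gates.h_inf_NaP - state.h_NaP) / gates.tau_hNaP
    f = output_activities(state.V, params)
    dm = (np.asarray(params.k_AD) * f[1:] - state.m_AD) / np.asarray(params.tau_AD)
    return NetworkState(V=dV, h_NaP=float(dh), m_AD=dm)


def make_rhs(params: ModelParameters):
    """Compile the packed right-hand side ``f(t, y, stim)`` for the integrator.

    The returned callable works on the flat 10-vector state and a constant
    per-population stim vector; scalar arithmetic is unrolled for speed (this
    function sits in the innermost loop of every simulation).
    """
    C = params.C
    gNaP, gK, gAD, gL = params.g_NaP, params.g_K, params.g_AD, params.g_L
    gSynE, gSynI, gChR = params.g_SynE, params.g_SynI, params.g_ChR
    ENa, EK, EL = params.E_Na, params.E_K, params.E_L
    ESynE, ESynI, EChR = params.E_SynE, params.E_SynI, params.E_ChR
    a12, Vh = params.a12, params.V_half
    k1, k2, k3, k4, k5 = params.k_V
    (b21, b22, b23, b24, b25), (b31, b32, b33, b34, b35), \
        (b41, b42, b43, b44, b45), (b51, b52, b53, b54, b55) = params.b
    d1, d2, d3, d4, d5 = params.drive
    tau_h_max = params.tau_hNaP_max
    tA2, tA3, tA4, tA5 = params.tau_AD
    kA2, kA3, kA4, kA5 = params.k_AD
    ik_hnap = params.delayed_rectifier_gated_by_hnap
    cut = SILENCE_CUTOFF_MV

    def rhs(t, y, stim):
        V1, V2, V3, V4, V5, h, mA2, mA3, mA4, mA5 = y
        s1, s2, s3, s4, s5 = stim

        f1 = 0.0 if V1 < cut else 1.0 / (1.0 + exp(-(V1 - Vh) / k1))
        f2 = 0.0 if V2 < cut else 1.0 / (1.0 + exp(-(V2 - Vh) / k2))
        f3 = 0.0 if V3 < cut else 1.0 / (1.0 + exp(-(V3 - Vh) / k3))
        f4 = 0.0 if V4 < cut else 1.0 / (1.0 + exp(-(V4 - Vh) / k4))
        f5 = 0.0 if V5 < cut else 1.0 / (1.0 + exp(-(V5 - Vh) / k5))

        mNaP = 1.0 / (1.0 + exp(-(V1 + 40.0) / 6.0))
        mK = 1.0 / (1.0 + exp(-(V1 + 30.0) / 4.0))
        hinf = 1.0 / (1.0 + exp((V1 + 48.0) / 6.0))
        tauh = tau_h_max / cosh((V1 + 48.0) / 12.0)

        IK = gK * mK ** 4 * (V1 - EK)
        if ik_hnap:
            IK *= h
        I1 = (gNaP * mNaP * h * (V1 - ENa) + IK
              + gL * (V1 - EL) + gSynE * d1 * (V1 - ESynE)
              + gSynI * (b21 * f2 + b31 * f3 + b41 * f4 + b51 * f5) * (V1 - ESynI)
              + gChR * s1 * (V1 - EChR))
        I2 = (gAD * mA2 * (V2 - EK) + gL * (V2 - EL)
              + gSynE * (d2 + a12 * f1) * (V2 - ESynE)
              + gSynI * (b32 * f3 + b42 * f4 + b52 * f5) * (V2 - ESynI)
              + gChR * s2 * (V2 - EChR))
        I3 = (gAD * mA3 * (V3 - EK) + gL * (V3 - EL)
              + gSynE * d3 * (V3 - ESynE)
              + gSynI * (b23 * f2 + b43 * f4 + b53 * f5) * (V3 - ESynI)
              + gChR * s3 * (V3 - EChR))
        I4 = (gAD * mA4 * (V4 - EK) + gL * (V4 - EL)
              + gSynE * d4 * (V4 - ESynE)
              + gSynI * (b24 * f2 + b34 * f3 + b54 * f5) * (V4 - ESynI)
              + gChR * s4 * (V4 - EChR))
        I5 = (gAD * mA5 * (V5 - EK) + gL * (V5 - EL)
              + gSynE * d5 * (V5 - ESynE)
              + gSynI * (b25 * f2 + b35 * f3 + b45 * f4) * (V5 - ESynI)
              + gChR * s5 * (V5 - EChR))

        return np.array([
            -I1 / C, -I2 / C, -I3 / C, -I4 / C, -I5 / C,
            (hinf - h) / tauh,
            (kA2 * f2 - mA2) / tA2,
            (kA3 * f3 - mA3) / tA3,
            (kA4 * f4 - mA4) / tA4,
            (kA5 * f5 - mA5) / tA5,
        ])

    return rhs
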