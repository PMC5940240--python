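"""Model constants for the five-population respiratory CPG.

The network comprises five activity-based neural populations:

====== ============ ========= =============================================
index  name         location  firing profile
====== ============ ========= =============================================
1      pre-I/I      pre-BötC  excitatory, I_NaP-dependent intrinsic burster
2      early-I      pre-BötC  inhibitory, decrementing during inspiration
3      aug-E        BötC      inhibitory, augmenting through expiration
4      post-I       BötC      inhibitory, decrementing through expiration
5      post-I_pBC   pre-BötC  inhibitory, brief post-inspiratory transient
====== ============ ========= =============================================

Units follow the convention voltages in mV, time in ms, conductances in nS
and capacitance in pF, under which nS·mV/pF = mV/ms and the equations need
no conversion factors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ModelParameters", "INHIBITORY_SOURCES", "PRE_BOTC_POPS", "BOTC_POPS"]

#: population indices (1-based) of the inhibitory populations (synaptic sources)
INHIBITORY_SOURCES = (2, 3, 4, 5)
#: populations located in the pre-Bötzinger complex
PRE_BOTC_POPS = (1, 2, 5)
#: populations located in the Bötzinger complex
BOTC_POPS = (3, 4)

# inhibitory weight table b[j][i]: source j in {2,3,4,5} (rows), target i in
# {1..5} (columns); b[j][j] = 0 and post-I <-> post-I_pBC do not interact
_DEFAULT_B = (
    (0.0, 0.0, 0.37, 0.26, 0.27),   # early-I ->
    (0.2, 0.5, 0.0, 0.1, 0.2),      # aug-E ->
    (0.2, 0.1, 0.39, 0.0, 0.0),     # post-I ->
    (1.4, 0.7, 0.65, 0.0, 0.0),     # post-I_pBC ->
)


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the population ODE system.

    Default construction yields the published parameter set; every field can
    be overridden via :meth:`replace` or the constructor.
    """

    C: float = 20.0                       # membrane capacitance, pF

    # maximal conductances, nS
    g_NaP: float = 5.0
    g_K: float = 5.0
    g_AD: float = 10.0
    g_L: float = 2.8
    g_SynE: float = 10.0
    g_SynI: float = 60.0
    g_ChR: float = 8.0

    # reversal potentials, mV
    E_Na: float = 50.0
    E_K: float = -85.0
    E_L: float = -60.0
    E_SynE: float = 0.0
    E_SynI: float = -75.0
    E_ChR: float = 0.0

    #: excitatory weight pre-I/I -> early-I
    a12: float = 0.5
    #: inhibitory weights b[j][i], rows j = 2..5, columns i = 1..5
    b: tuple = _DEFAULT_B
    #: tonic excitatory drive per population, i = 1..5
    drive: tuple = (0.21, 0.59, 0.73, 0.72, 0.3)

    #: half-activation voltage of the output function, mV (shared)
    V_half: float = -30.0
    #: output-function slopes k_Vi, mV; the burster population is shallower
    k_V: tuple = (8.0, 4.0, 4.0, 4.0, 4.0)

    #: maximal time constant of I_NaP inactivation, ms
    tau_hNaP_max: float = 2000.0
    #: adaptation time constants tau_ADi for i = 2..5, ms
    tau_AD: tuple = (2000.0, 1500.0, 1000.0, 500.0)
    #: adaptation gains k_ADi for i = 2..5
    k_AD: tuple = (0.9, 0.9, 1.3, 1.7)

    #: keep the delayed rectifier multiplied by h_NaP, as typeset in the
    #: source description of I_K; off by default (see docs/methods.md)
    delayed_rectifier_gated_by_hnap: bool = False

    def __post_init__(self) -> None:
        for name in ("g_NaP", "g_K", "g_AD", "g_L", "g_SynE", "g_SynI", "g_ChR"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("C", "tau_hNaP_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "b", tuple(tuple(float(x) for x in row) for row in self.b))
        for name, length in (("drive", 5), ("k_V", 5), ("tau_AD", 4), ("k_AD", 4)):
            value = tuple(float(x) for x in getattr(self, name))
            if len(value) != length:
                raise ValueError(f"{name} must have length {length}")
            object.__setattr__(self, name, value)
        if len(self.b) != 4 or any(len(row) != 5 for row in self.b):
            raise ValueError("b must be a 4x5 table (sources 2..5 by targets 1..5)")
        if any(x < 0 for row in self.b for x in row) or any(x < 0 for x in self.drive):
            raise ValueError("synaptic weights and drives must be >= 0")
        if any(tau <= 0 for tau in self.tau_AD):
            raise ValueError("adaptation time constants must be > 0")

    # -- convenience views -------------------------------------------------

    @property
    def b_matrix(self) -> np.ndarray:
        """Inhibitory weights as a (4 sources, 5 targets) array."""
        return np.asarray(self.b, dtype=float)

    @property
    def drive_array(self) -> np.ndarray:
        return np.asarray(self.drive, dtype=float)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["b"] = [list(row) for row in self.b]
        for name in ("drive", "k_V", "tau_AD", "k_AD"):
            out[name] = list(out[name])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ModelParameters":
        """Load from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def __iter__(self) -> Iterator:
        return iter(dataclasses.asdict(self).items())
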