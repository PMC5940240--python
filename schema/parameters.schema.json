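{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "respcpg model parameters",
  "description": "Flat parameter document for the five-population respiratory CPG model. Field names match the model symbols; units: mV, ms, nS, pF. All fields are optional; omitted fields take the published defaults.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "C": {"type": "number", "exclusiveMinimum": 0, "description": "membrane capacitance, pF"},
    "g_NaP": {"type": "number", "minimum": 0},
    "g_K": {"type": "number", "minimum": 0},
    "g_AD": {"type": "number", "minimum": 0},
    "g_L": {"type": "number", "minimum": 0},
    "g_SynE": {"type": "number", "minimum": 0},
    "g_SynI": {"type": "number", "minimum": 0},
    "g_ChR": {"type": "number", "minimum": 0},
    "E_Na": {"type": "number"},
    "E_K": {"type": "number"},
    "E_L": {"type": "number"},
    "E_SynE": {"type": "number"},
    "E_SynI": {"type": "number"},
    "E_ChR": {"type": "number"},
    "a12": {"type": "number", "minimum": 0, "description": "excitatory weight pre-I/I -> early-I"},
    "b": {
      "type": "array",
      "description": "inhibitory weights b[j][i]; rows are sources j=2..5, columns targets i=1..5; b[j][j]=0",
      "minItems": 4, "maxItems": 4,
      "items": {
        "type": "array", "minItems": 5, "maxItems": 5,
        "items": {"type": "number", "minimum": 0}
      }
    },
    "drive": {
      "type": "array", "minItems": 5, "maxItems": 5,
      "items": {"type": "number", "minimum": 0},
      "description": "tonic excitatory drive per population"
    },
    "V_half": {"type": "number", "description": "output-function half-activation voltage, mV"},
    "k_V": {
      "type": "array", "minItems": 5, "maxItems": 5,
      "items": {"type": "number", "exclusiveMinimum": 0},
      "description": "output-function slopes, mV"
    },
    "tau_hNaP_max": {"type": "number", "exclusiveMinimum": 0},
    "tau_AD": {
      "type": "array", "minItems": 4, "maxItems": 4,
      "items": {"type": "number", "exclusiveMinimum": 0},
      "description": "adaptation time constants for populations 2..5, ms"
    },
    "k_AD": {
      "type": "array", "minItems": 4, "maxItems": 4,
      "items": {"type": "number", "minimum": 0},
      "description": "adaptation gains for populations 2..5"
    },
    "delayed_rectifier_gated_by_hnap": {
      "type": "boolean",
      "description": "keep the h_NaP factor in I_K as typeset in the source equations (sensitivity toggle)"
    }
  }
}
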