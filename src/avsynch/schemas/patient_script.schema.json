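{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PatientScript",
  "type": "object",
  "required": ["patient_id", "combos", "hourly_sinus_interval_ms"],
  "properties": {
    "patient_id": {"type": "string"},
    "archetype": {"type": "string"},
    "seed": {"type": "integer"},
    "combos": {
      "type": "object",
      "required": ["1+2", "1+3", "2+3", "1+2+3"],
      "additionalProperties": {
        "type": "object",
        "required": ["a3", "a4"],
        "properties": {
          "a3": {"$ref": "#/$defs/amplitude_distribution"},
          "a4": {"$ref": "#/$defs/amplitude_distribution"}
        }
      }
    },
    "hourly_sinus_interval_ms": {
      "type": "array",
      "items": {"type": "number", "exclusiveMinimum": 300},
      "minItems": 1
    },
    "interval_variability_fraction": {"type": "number", "minimum": 0, "maximum": 0.2},
    "pac_probability": {"type": "number", "minimum": 0, "maximum": 0.5},
    "pvc_probability": {"type": "number", "minimum": 0, "maximum": 0.5},
    "timing": {
      "type": "object",
      "properties": {
        "a2_delay_ms": {"type": "number", "minimum": 0},
        "a4_delay_ms": {"type": "number", "minimum": 0},
        "a3_signal_end_ms": {"type": "number", "minimum": 0},
        "a3_end_variation_sd_ms": {"enum": [0, 17, 33]},
        "auto_adjust_a3_end_with_rate": {"type": "boolean"},
        "a3_start_ms": {"type": "number", "minimum": 0},
        "a3_lobe_spacing_ms": {"type": "number", "exclusiveMinimum": 0},
        "a3_peak_offset_ms": {"type": "number", "minimum": 0},
        "a3_end_fraction": {"type": "number", "exclusiveMinimum": 0, "maximum": 1}
      }
    }
  },
  "$defs": {
    "amplitude_distribution": {
      "type": "object",
      "required": ["mean_m_s2", "sd_m_s2", "min_m_s2", "max_m_s2", "gain"],
      "properties": {
        "mean_m_s2": {"type": "number"},
        "sd_m_s2": {"type": "number", "minimum": 0},
        "min_m_s2": {"type": "number"},
        "max_m_s2": {"type": "number"},
        "gain": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  }
}
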