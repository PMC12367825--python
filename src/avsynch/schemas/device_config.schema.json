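{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "DeviceConfig",
  "type": "object",
  "properties": {
    "mode": {"enum": ["VDD", "VDI"]},
    "pvab_ms": {"type": "number", "exclusiveMinimum": 0},
    "upper_tracking_rate_bpm": {"type": "number", "exclusiveMinimum": 0},
    "lower_rate_bpm": {"type": "number", "exclusiveMinimum": 0},
    "a3_threshold": {"type": "number", "exclusiveMinimum": 0},
    "a4_threshold": {"type": "number", "exclusiveMinimum": 0},
    "a3_window_end_min_ms": {"type": "number", "multipleOf": 25},
    "a3_window_end_max_ms": {"type": "number", "multipleOf": 25},
    "am_to_vp_delay_ms": {"type": "number", "minimum": 0},
    "a3_amplitude_margin": {"type": "number", "minimum": 0}
  }
}
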