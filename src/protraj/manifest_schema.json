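{
  "type": "object",
  "required": ["seeds", "config", "stages", "warnings"],
  "properties": {
    "seeds": {"type": "object"},
    "config": {"type": "object"},
    "stages": {"type": "array", "items": {"type": "string"}},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "files": {"type": "object"},
    "time_unit": {"type": "string"},
    "log_base": {"type": "string"}
  }
}
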