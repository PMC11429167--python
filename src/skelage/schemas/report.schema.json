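{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "skelage analysis report",
  "type": "object",
  "required": ["provenance", "stages", "descriptives", "demography", "dimorphism", "comparisons", "correlations", "growth"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["input", "package_version", "timestamp", "config_hash"],
      "properties": {
        "input": {"type": "string"},
        "package_version": {"type": "string"},
        "timestamp": {"type": "string"},
        "config_hash": {"type": "string"}
      }
    },
    "stages": {"type": "object"},
    "descriptives": {"type": "object"},
    "demography": {"type": "object"},
    "dimorphism": {"type": "object"},
    "comparisons": {"type": "object"},
    "correlations": {"type": "object"},
    "growth": {"type": "object"}
  }
}
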