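{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "germfp synthetic-truth bundle",
  "type": "object",
  "required": ["marker_ids", "duplicate_groups", "mislabels", "crossovers",
               "origin_states", "donor_segments", "het_blocks"],
  "properties": {
    "marker_ids": {"type": "array", "items": {"type": "string"}},
    "duplicate_groups": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "string"}, "minItems": 2}
    },
    "mislabels": {
      "type": "object",
      "additionalProperties": {"type": "string"},
      "description": "emitted sample name -> name of the line whose genotype it carries"
    },
    "crossovers": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {"type": "array", "items": {"type": "integer"}},
        "description": "chromosome -> breakpoint bp positions of the diploid origin mosaic"
      }
    },
    "origin_states": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {"type": "integer", "enum": [0, 1, 2]},
        "description": "per-marker true parental origin: 0=parent1, 1=parent2, 2=heterozygous"
      }
    },
    "donor_segments": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "array",
          "prefixItems": [{"type": "string"}, {"type": "integer"}, {"type": "integer"}],
          "description": "[chromosome, start_bp, end_bp] of a donor-carrying run"
        }
      }
    },
    "het_blocks": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "array",
          "prefixItems": [{"type": "string"}, {"type": "integer"}, {"type": "integer"}]
        }
      }
    }
  }
}
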