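{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "isocat run report",
  "type": "object",
  "required": ["tool", "version", "seed", "config", "expression", "conservation", "screen"],
  "properties": {
    "tool": {"type": "string"},
    "version": {"type": "string"},
    "versions": {"type": "object"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "expression": {
      "type": "object",
      "required": ["n_genes", "n_upregulated"],
      "properties": {
        "n_genes": {"type": "integer"},
        "n_upregulated": {"type": "integer"}
      }
    },
    "conservation": {
      "type": "object",
      "required": ["n_genes", "n_strains"],
      "properties": {
        "n_genes": {"type": "integer"},
        "n_strains": {"type": "integer"}
      }
    },
    "screen": {
      "type": "object",
      "required": ["n_candidates", "hotspots"],
      "properties": {
        "n_candidates": {"type": "integer"},
        "hotspots": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["replicon_id", "start_rank", "end_rank", "locus_ids", "n_candidates", "span", "score"],
            "properties": {
              "replicon_id": {"type": "string"},
              "start_rank": {"type": "integer"},
              "end_rank": {"type": "integer"},
              "locus_ids": {"type": "array", "items": {"type": "string"}},
              "n_candidates": {"type": "integer"},
              "span": {"type": "integer"},
              "score": {"type": "integer"}
            }
          }
        },
        "enrichment": {
          "type": ["object", "null"],
          "required": ["contingency", "odds_ratio", "p_two_sided"],
          "properties": {
            "contingency": {"type": "array"},
            "p_two_sided": {"type": "number"}
          }
        }
      }
    },
    "growth": {
      "type": "object",
      "required": ["n_strains", "n_tests", "n_significant", "tests"],
      "properties": {
        "n_strains": {"type": "integer"},
        "n_tests": {"type": "integer"},
        "n_significant": {"type": "integer"},
        "tests": {"type": "array"}
      }
    },
    "mass": {
      "type": "object",
      "required": ["n_peaks", "annotations"],
      "properties": {
        "n_peaks": {"type": "integer"},
        "annotations": {"type": "array"}
      }
    }
  }
}
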