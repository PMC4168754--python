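{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pathwayviews node-link graph",
  "type": "object",
  "required": ["nodes", "edges"],
  "properties": {
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "attributes"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"type": "string", "enum": ["molecule", "group", "connector", "annotation"]},
          "attributes": {"type": "object"},
          "style": {"type": "object"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "source", "target", "interaction_type", "directed", "attributes"],
        "properties": {
          "id": {"type": "string"},
          "source": {"type": "string"},
          "target": {"type": "string"},
          "interaction_type": {"type": "string"},
          "directed": {"type": "boolean"},
          "attributes": {"type": "object"},
          "style": {"type": "object"}
        }
      }
    }
  }
}
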