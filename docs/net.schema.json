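{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Flexible Net description",
  "type": "object",
  "required": ["places", "transitions"],
  "properties": {
    "name": {"type": "string"},
    "places": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "m0": {"$ref": "#/$defs/valueOrInterval"}
        },
        "additionalProperties": false
      }
    },
    "transitions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "l0": {"$ref": "#/$defs/valueOrInterval"}
        },
        "additionalProperties": false
      }
    },
    "ehandlers": {"$ref": "#/$defs/handlerList"},
    "shandlers": {"$ref": "#/$defs/handlerList"},
    "m0cons": {"type": "array", "items": {"type": "string"}},
    "l0cons": {"type": "array", "items": {"type": "string"}}
  },
  "additionalProperties": false,
  "$defs": {
    "valueOrInterval": {
      "oneOf": [
        {"type": "number"},
        {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
      ]
    },
    "handlerList": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "connect"],
        "properties": {
          "id": {"type": "string"},
          "connect": {
            "type": "object",
            "description": "label -> [u, v] pair; the pair must touch the handler; place pairs keep their written direction (arcs for event handlers, undirected edges for intensity handlers) and symmetrically for transition pairs",
            "additionalProperties": {
              "type": "array",
              "items": {"type": "string"},
              "minItems": 2,
              "maxItems": 2
            }
          },
          "relations": {
            "type": "array",
            "items": {"type": "string"},
            "description": "linear relation chains over the labels; empty or absent means all labels equal"
          }
        },
        "additionalProperties": false
      }
    }
  }
}
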