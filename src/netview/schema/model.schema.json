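{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/netview/model.schema.json",
  "title": "netview rule-based model document",
  "type": "object",
  "required": ["format_version"],
  "properties": {
    "format_version": {"type": "string"},
    "metadata": {"type": "object"},
    "molecules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"$ref": "#/definitions/identifier"},
          "components": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name"],
              "properties": {
                "name": {"$ref": "#/definitions/identifier"},
                "state_variables": {"type": "array", "items": {"type": "string"}},
                "binding_sites": {"type": "array", "items": {"type": "string"}}
              }
            }
          }
        }
      }
    },
    "species": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"$ref": "#/definitions/identifier"},
          "molecule_instances": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "molecule"],
              "properties": {
                "id": {"$ref": "#/definitions/identifier"},
                "molecule": {"$ref": "#/definitions/identifier"}
              }
            }
          },
          "bonds": {
            "type": "array",
            "items": {
              "type": "array",
              "items": {"type": "integer", "minimum": 1},
              "minItems": 2,
              "maxItems": 2
            }
          },
          "complexes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name"],
              "properties": {
                "name": {"$ref": "#/definitions/identifier"},
                "states": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["instance", "component", "variable", "value"],
                    "properties": {
                      "instance": {"$ref": "#/definitions/identifier"},
                      "component": {"$ref": "#/definitions/identifier"},
                      "variable": {"$ref": "#/definitions/identifier"},
                      "value": {"enum": ["on", "off", "dont_care"]}
                    }
                  }
                }
              }
            }
          }
        }
      }
    },
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "category"],
        "properties": {
          "name": {"$ref": "#/definitions/identifier"},
          "category": {"enum": ["association", "dissociation", "transformation"]},
          "reactants": {"$ref": "#/definitions/complex_refs"},
          "products": {"$ref": "#/definitions/complex_refs"},
          "bond_sites": {
            "type": ["array", "null"],
            "items": {
              "type": "object",
              "required": ["species", "site"],
              "properties": {
                "species": {"$ref": "#/definitions/identifier"},
                "site": {"type": "integer", "minimum": 1}
              }
            },
            "minItems": 2,
            "maxItems": 2
          },
          "rate_constant": {"type": "number", "minimum": 0}
        }
      }
    }
  },
  "definitions": {
    "identifier": {"type": "string", "minLength": 1},
    "complex_refs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["species", "complex"],
        "properties": {
          "species": {"$ref": "#/definitions/identifier"},
          "complex": {"$ref": "#/definitions/identifier"}
        }
      }
    }
  }
}
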