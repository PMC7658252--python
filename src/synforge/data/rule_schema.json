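{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "synforge reaction-rule file",
  "description": "Published schema for the YAML rule format. The loader in synforge.rules enforces these constraints (plus SMARTS/SMIRKS parseability and rule-id uniqueness, which JSON Schema cannot express) and names the offending rule id and field in its errors.",
  "type": "object",
  "required": ["transforms"],
  "properties": {
    "transforms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "role_a", "role_b", "product_template"],
        "properties": {
          "id": {"type": "integer"},
          "name": {"type": "string", "minLength": 1},
          "role_a": {"type": "string", "description": "SMARTS for reactant role A"},
          "role_b": {"type": "string", "description": "SMARTS for reactant role B"},
          "product_template": {"type": "string", "description": "SMIRKS, two reactants to one product"},
          "leaving_groups": {
            "type": "array",
            "items": {"type": "string", "description": "SMILES fragment removed by the template"}
          },
          "ring_forming": {"type": "boolean"},
          "metadata": {"type": "object"},
          "clauses": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["scope", "action"],
              "properties": {
                "scope": {"enum": ["reactant_a", "reactant_b", "product"]},
                "action": {"enum": ["ADD", "SUBTRACT", "KILL"]},
                "value": {
                  "type": "integer",
                  "multipleOf": 5,
                  "minimum": 5,
                  "maximum": 30,
                  "description": "required for ADD/SUBTRACT, forbidden for KILL; the [5,30] multiple-of-five constraint is relaxed under the loader's permissive flag"
                },
                "smarts": {"type": "string"},
                "property": {"enum": ["heavy_atoms", "ring_count", "net_charge"]},
                "op": {"enum": ["gt", "ge", "lt", "le", "eq", "ne"]},
                "threshold": {"type": "number"}
              },
              "oneOf": [
                {"required": ["smarts"]},
                {"required": ["property", "op", "threshold"]}
              ]
            }
          }
        }
      }
    }
  }
}
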