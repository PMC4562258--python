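{
  "$defs": {
    "CheckRecord": {
      "description": "One restricted system subjected to trap-space computation and, when\nnon-trivial, completeness model checking.",
      "properties": {
        "variables": {
          "items": {
            "type": "string"
          },
          "title": "Variables",
          "type": "array"
        },
        "min_trap_spaces": {
          "items": {
            "type": "string"
          },
          "title": "Min Trap Spaces",
          "type": "array"
        },
        "complete": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Complete"
        },
        "counterexample": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Counterexample"
        }
      },
      "required": [
        "variables",
        "min_trap_spaces"
      ],
      "title": "CheckRecord",
      "type": "object"
    },
    "RefinementStep": {
      "properties": {
        "popped": {
          "title": "Popped",
          "type": "string"
        },
        "previously_checked": {
          "items": {
            "type": "string"
          },
          "title": "Previously Checked",
          "type": "array"
        },
        "percolated_to": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Percolated To"
        },
        "checks": {
          "items": {
            "$ref": "#/$defs/CheckRecord"
          },
          "title": "Checks",
          "type": "array"
        },
        "outcome": {
          "enum": [
            "confirmed",
            "extended",
            "refined",
            "failed"
          ],
          "title": "Outcome",
          "type": "string"
        },
        "pushed": {
          "items": {
            "type": "string"
          },
          "title": "Pushed",
          "type": "array"
        },
        "confirmed": {
          "items": {
            "type": "string"
          },
          "title": "Confirmed",
          "type": "array"
        },
        "percolation_deltas": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Percolation Deltas",
          "type": "object"
        }
      },
      "required": [
        "popped",
        "previously_checked",
        "outcome"
      ],
      "title": "RefinementStep",
      "type": "object"
    },
    "RefinementTrace": {
      "description": "Machine-readable record of the iterative completeness decision.",
      "properties": {
        "minimal_trap_spaces": {
          "items": {
            "type": "string"
          },
          "title": "Minimal Trap Spaces",
          "type": "array"
        },
        "steps": {
          "items": {
            "$ref": "#/$defs/RefinementStep"
          },
          "title": "Steps",
          "type": "array"
        },
        "complete": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Complete"
        }
      },
      "required": [
        "minimal_trap_spaces"
      ],
      "title": "RefinementTrace",
      "type": "object"
    },
    "TrapSpaceVerdict": {
      "properties": {
        "trap_space": {
          "title": "Trap Space",
          "type": "string"
        },
        "steady": {
          "title": "Steady",
          "type": "boolean"
        },
        "attractor_state": {
          "title": "Attractor State",
          "type": "string"
        },
        "univocal": {
          "title": "Univocal",
          "type": "boolean"
        },
        "faithful": {
          "title": "Faithful",
          "type": "boolean"
        }
      },
      "required": [
        "trap_space",
        "steady",
        "attractor_state",
        "univocal",
        "faithful"
      ],
      "title": "TrapSpaceVerdict",
      "type": "object"
    }
  },
  "description": "The complete approximation report for one network.",
  "properties": {
    "variables": {
      "items": {
        "type": "string"
      },
      "title": "Variables",
      "type": "array"
    },
    "minimal_trap_spaces": {
      "items": {
        "type": "string"
      },
      "title": "Minimal Trap Spaces",
      "type": "array"
    },
    "trap_spaces": {
      "items": {
        "$ref": "#/$defs/TrapSpaceVerdict"
      },
      "title": "Trap Spaces",
      "type": "array"
    },
    "complete": {
      "title": "Complete",
      "type": "boolean"
    },
    "completeness_method": {
      "enum": [
        "iterative",
        "naive"
      ],
      "title": "Completeness Method",
      "type": "string"
    },
    "outside_attractors": {
      "items": {
        "type": "string"
      },
      "title": "Outside Attractors",
      "type": "array"
    },
    "perfect": {
      "title": "Perfect",
      "type": "boolean"
    },
    "refinement": {
      "anyOf": [
        {
          "$ref": "#/$defs/RefinementTrace"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "variables",
    "minimal_trap_spaces",
    "trap_spaces",
    "complete",
    "completeness_method",
    "outside_attractors",
    "perfect"
  ],
  "title": "ApproximationReport",
  "type": "object"
}
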