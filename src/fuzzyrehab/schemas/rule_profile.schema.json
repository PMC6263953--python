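{
  "$defs": {
    "FISConfig": {
      "description": "A complete Mamdani system: inputs, one output, rule base.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "inputs": {
          "items": {
            "$ref": "#/$defs/LinguisticVariable"
          },
          "title": "Inputs",
          "type": "array"
        },
        "output": {
          "$ref": "#/$defs/LinguisticVariable"
        },
        "rules": {
          "items": {
            "$ref": "#/$defs/FuzzyRule"
          },
          "title": "Rules",
          "type": "array"
        },
        "defuzz_resolution": {
          "default": 1001,
          "title": "Defuzz Resolution",
          "type": "integer"
        },
        "default_output_label": {
          "title": "Default Output Label",
          "type": "string"
        },
        "tie_break": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tie Break"
        }
      },
      "required": [
        "name",
        "inputs",
        "output",
        "rules",
        "default_output_label"
      ],
      "title": "FISConfig",
      "type": "object"
    },
    "FuzzyRule": {
      "description": "If-Then rule: conjunction of per-variable label conditions.\n\nAn antecedent value of :data:`ANY` leaves that variable\nunconstrained (it contributes degree 1 to the conjunction).",
      "properties": {
        "antecedents": {
          "additionalProperties": {
            "type": "string"
          },
          "title": "Antecedents",
          "type": "object"
        },
        "consequent": {
          "title": "Consequent",
          "type": "string"
        }
      },
      "required": [
        "antecedents",
        "consequent"
      ],
      "title": "FuzzyRule",
      "type": "object"
    },
    "LinguisticVariable": {
      "description": "A named variable with a closed universe and a set of labelled fuzzy sets.",
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "universe": {
          "maxItems": 2,
          "minItems": 2,
          "prefixItems": [
            {
              "type": "number"
            },
            {
              "type": "number"
            }
          ],
          "title": "Universe",
          "type": "array"
        },
        "units": {
          "default": "",
          "title": "Units",
          "type": "string"
        },
        "labels": {
          "items": {
            "$ref": "#/$defs/MembershipFunction"
          },
          "title": "Labels",
          "type": "array"
        }
      },
      "required": [
        "name",
        "universe",
        "labels"
      ],
      "title": "LinguisticVariable",
      "type": "object"
    },
    "MFShape": {
      "enum": [
        "triangular",
        "trapezoidal",
        "crisp_singleton"
      ],
      "title": "MFShape",
      "type": "string"
    },
    "MembershipFunction": {
      "description": "A named fuzzy set over one variable's universe.\n\n``breakpoints`` are the ordered abscissae of the shape: 3 for a\ntriangle (left foot, peak, right foot), 4 for a trapezoid (left\nfoot, left shoulder, right shoulder, right foot), 1 for a crisp\nsingleton.  Degenerate (vertical) edges are allowed, e.g. a\nleft-shoulder trapezoid ``(0, 0, 20, 45)``.",
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "shape": {
          "$ref": "#/$defs/MFShape"
        },
        "breakpoints": {
          "items": {
            "type": "number"
          },
          "title": "Breakpoints",
          "type": "array"
        }
      },
      "required": [
        "label",
        "shape",
        "breakpoints"
      ],
      "title": "MembershipFunction",
      "type": "object"
    },
    "SignalConfig": {
      "description": "Parameters of the stress/interaction feature pipeline.\n\nwindow_size\n    Number of 1 Hz headset readings in the sliding window (default 10,\n    i.e. the last 10 s).\nstress_threshold\n    Cutoff on the raw reading; a sample at or above it counts as high.\navg_fraction\n    Trailing fraction of the step over which the windowed stress\n    percentage is averaged for the difficulty controller (default the\n    last quarter).\ntick_interval\n    Seconds between samples.",
      "properties": {
        "window_size": {
          "default": 10,
          "minimum": 1,
          "title": "Window Size",
          "type": "integer"
        },
        "stress_threshold": {
          "default": 0.5,
          "exclusiveMaximum": 1.0,
          "exclusiveMinimum": 0.0,
          "title": "Stress Threshold",
          "type": "number"
        },
        "avg_fraction": {
          "default": 0.25,
          "exclusiveMinimum": 0.0,
          "maximum": 1.0,
          "title": "Avg Fraction",
          "type": "number"
        },
        "tick_interval": {
          "default": 1.0,
          "exclusiveMinimum": 0.0,
          "title": "Tick Interval",
          "type": "number"
        }
      },
      "title": "SignalConfig",
      "type": "object"
    }
  },
  "description": "Named parameterization of both controllers plus the signal pipeline.",
  "properties": {
    "format_version": {
      "default": "1.0",
      "title": "Format Version",
      "type": "string"
    },
    "name": {
      "minLength": 1,
      "title": "Name",
      "type": "string"
    },
    "fis4h": {
      "$ref": "#/$defs/FISConfig"
    },
    "fis4d": {
      "$ref": "#/$defs/FISConfig"
    },
    "signal": {
      "$ref": "#/$defs/SignalConfig",
      "default": {
        "window_size": 10,
        "stress_threshold": 0.5,
        "avg_fraction": 0.25,
        "tick_interval": 1.0
      }
    }
  },
  "required": [
    "name",
    "fis4h",
    "fis4d"
  ],
  "title": "RuleProfile",
  "type": "object"
}
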