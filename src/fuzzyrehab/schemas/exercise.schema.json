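{
  "$defs": {
    "DifficultyLevelDef": {
      "properties": {
        "index": {
          "minimum": 1,
          "title": "Index",
          "type": "integer"
        },
        "elements": {
          "items": {
            "$ref": "#/$defs/ElementDef"
          },
          "title": "Elements",
          "type": "array"
        }
      },
      "required": [
        "index",
        "elements"
      ],
      "title": "DifficultyLevelDef",
      "type": "object"
    },
    "ElementDef": {
      "description": "One on-screen element: a target to select or a distractor to avoid.",
      "properties": {
        "id": {
          "title": "Id",
          "type": "string"
        },
        "kind": {
          "enum": [
            "target",
            "distractor"
          ],
          "title": "Kind",
          "type": "string"
        },
        "position": {
          "default": [
            0.5,
            0.5
          ],
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
          "title": "Position",
          "type": "array"
        },
        "sequence": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sequence"
        }
      },
      "required": [
        "id",
        "kind"
      ],
      "title": "ElementDef",
      "type": "object"
    },
    "ExerciseOptions": {
      "description": "Session-wide options mirroring the exercise editor's option block.",
      "properties": {
        "repetitions": {
          "default": 1,
          "minimum": 1,
          "title": "Repetitions",
          "type": "integer"
        },
        "help_type": {
          "$ref": "#/$defs/HelpType",
          "default": "both"
        },
        "max_exercise_time": {
          "default": 0.0,
          "minimum": 0.0,
          "title": "Max Exercise Time",
          "type": "number"
        },
        "cognitive_lives": {
          "default": 0,
          "minimum": 0,
          "title": "Cognitive Lives",
          "type": "integer"
        },
        "distractor_lives": {
          "default": 0,
          "minimum": 0,
          "title": "Distractor Lives",
          "type": "integer"
        },
        "initial_explanation": {
          "default": "",
          "title": "Initial Explanation",
          "type": "string"
        },
        "initial_explanation_time": {
          "default": 0.0,
          "minimum": 0.0,
          "title": "Initial Explanation Time",
          "type": "number"
        },
        "hit_points": {
          "default": 10,
          "minimum": 0,
          "title": "Hit Points",
          "type": "integer"
        },
        "error_points": {
          "default": 5,
          "minimum": 0,
          "title": "Error Points",
          "type": "integer"
        }
      },
      "title": "ExerciseOptions",
      "type": "object"
    },
    "HelpType": {
      "description": "Which assistance modality the exercise is configured to use.",
      "enum": [
        "visual",
        "haptic",
        "both",
        "none"
      ],
      "title": "HelpType",
      "type": "string"
    },
    "StepDef": {
      "properties": {
        "index": {
          "minimum": 1,
          "title": "Index",
          "type": "integer"
        },
        "levels": {
          "items": {
            "$ref": "#/$defs/DifficultyLevelDef"
          },
          "title": "Levels",
          "type": "array"
        },
        "base_level": {
          "minimum": 1,
          "title": "Base Level",
          "type": "integer"
        }
      },
      "required": [
        "index",
        "levels",
        "base_level"
      ],
      "title": "StepDef",
      "type": "object"
    }
  },
  "properties": {
    "format_version": {
      "default": "1.0",
      "title": "Format Version",
      "type": "string"
    },
    "id": {
      "title": "Id",
      "type": "string"
    },
    "steps": {
      "items": {
        "$ref": "#/$defs/StepDef"
      },
      "title": "Steps",
      "type": "array"
    },
    "options": {
      "$ref": "#/$defs/ExerciseOptions",
      "default": {
        "repetitions": 1,
        "help_type": "both",
        "max_exercise_time": 0.0,
        "cognitive_lives": 0,
        "distractor_lives": 0,
        "initial_explanation": "",
        "initial_explanation_time": 0.0,
        "hit_points": 10,
        "error_points": 5
      }
    }
  },
  "required": [
    "id",
    "steps"
  ],
  "title": "ExerciseDef",
  "type": "object"
}
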