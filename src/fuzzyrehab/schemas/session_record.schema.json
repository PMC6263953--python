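{
  "$defs": {
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
    "StepRecord": {
      "properties": {
        "step_index": {
          "title": "Step Index",
          "type": "integer"
        },
        "level_played": {
          "title": "Level Played",
          "type": "integer"
        },
        "status": {
          "enum": [
            "completed",
            "canceled",
            "interrupted"
          ],
          "title": "Status",
          "type": "string"
        },
        "samples": {
          "items": {
            "$ref": "#/$defs/TelemetrySample"
          },
          "title": "Samples",
          "type": "array"
        },
        "summary": {
          "$ref": "#/$defs/StepSummary"
        },
        "offset": {
          "maximum": 2,
          "minimum": -2,
          "title": "Offset",
          "type": "integer"
        }
      },
      "required": [
        "step_index",
        "level_played",
        "status",
        "samples",
        "summary",
        "offset"
      ],
      "title": "StepRecord",
      "type": "object"
    },
    "StepSummary": {
      "description": "What the difficulty controller sees about a finished step.",
      "properties": {
        "step_average_stress": {
          "maximum": 100.0,
          "minimum": 0.0,
          "title": "Step Average Stress",
          "type": "number"
        },
        "step_errors_ratio": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Step Errors Ratio",
          "type": "number"
        },
        "step_canceled": {
          "title": "Step Canceled",
          "type": "boolean"
        }
      },
      "required": [
        "step_average_stress",
        "step_errors_ratio",
        "step_canceled"
      ],
      "title": "StepSummary",
      "type": "object"
    },
    "TelemetrySample": {
      "description": "One 1 Hz log record taken during a step.",
      "properties": {
        "timestamp": {
          "title": "Timestamp",
          "type": "number"
        },
        "percent_completed": {
          "title": "Percent Completed",
          "type": "number"
        },
        "activated_elements": {
          "title": "Activated Elements",
          "type": "integer"
        },
        "cognitive_errors": {
          "title": "Cognitive Errors",
          "type": "integer"
        },
        "distractor_errors": {
          "title": "Distractor Errors",
          "type": "integer"
        },
        "elapsed_time": {
          "title": "Elapsed Time",
          "type": "number"
        },
        "current_stress": {
          "title": "Current Stress",
          "type": "number"
        },
        "time_without_interaction": {
          "title": "Time Without Interaction",
          "type": "number"
        },
        "consecutive_errors": {
          "title": "Consecutive Errors",
          "type": "integer"
        },
        "score": {
          "title": "Score",
          "type": "integer"
        },
        "visual_help": {
          "title": "Visual Help",
          "type": "boolean"
        },
        "haptic_help": {
          "title": "Haptic Help",
          "type": "boolean"
        },
        "screenshot": {
          "default": null,
          "title": "Screenshot",
          "type": "null"
        }
      },
      "required": [
        "timestamp",
        "percent_completed",
        "activated_elements",
        "cognitive_errors",
        "distractor_errors",
        "elapsed_time",
        "current_stress",
        "time_without_interaction",
        "consecutive_errors",
        "score",
        "visual_help",
        "haptic_help"
      ],
      "title": "TelemetrySample",
      "type": "object"
    }
  },
  "properties": {
    "format_version": {
      "default": "1.0",
      "title": "Format Version",
      "type": "string"
    },
    "exercise_id": {
      "title": "Exercise Id",
      "type": "string"
    },
    "options": {
      "$ref": "#/$defs/ExerciseOptions"
    },
    "steps": {
      "items": {
        "$ref": "#/$defs/StepRecord"
      },
      "title": "Steps",
      "type": "array"
    },
    "final_score": {
      "title": "Final Score",
      "type": "integer"
    },
    "completion_status": {
      "enum": [
        "complete",
        "incomplete"
      ],
      "title": "Completion Status",
      "type": "string"
    }
  },
  "required": [
    "exercise_id",
    "options",
    "steps",
    "final_score",
    "completion_status"
  ],
  "title": "SessionRecord",
  "type": "object"
}
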