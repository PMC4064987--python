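{
  "$defs": {
    "AIFReport": {
      "additionalProperties": false,
      "properties": {
        "A1": {
          "title": "A1",
          "type": "number"
        },
        "A2": {
          "title": "A2",
          "type": "number"
        },
        "m1": {
          "title": "M1",
          "type": "number"
        },
        "m2": {
          "title": "M2",
          "type": "number"
        },
        "rss": {
          "title": "Rss",
          "type": "number"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        }
      },
      "required": [
        "A1",
        "A2",
        "m1",
        "m2",
        "rss",
        "converged"
      ],
      "title": "AIFReport",
      "type": "object"
    },
    "GKMReport": {
      "additionalProperties": false,
      "properties": {
        "Ktrans": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ktrans"
        },
        "Kep": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Kep"
        },
        "ve": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ve"
        },
        "rss": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Rss"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "offset": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Offset"
        }
      },
      "required": [
        "Ktrans",
        "Kep",
        "ve",
        "rss",
        "converged"
      ],
      "title": "GKMReport",
      "type": "object"
    },
    "TwoStageReport": {
      "additionalProperties": false,
      "properties": {
        "split_min": {
          "title": "Split Min",
          "type": "number"
        },
        "method": {
          "title": "Method",
          "type": "string"
        },
        "stage2_mode": {
          "title": "Stage2 Mode",
          "type": "string"
        },
        "stage1": {
          "$ref": "#/$defs/GKMReport"
        },
        "stage2": {
          "$ref": "#/$defs/GKMReport"
        },
        "weighted_ve": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Weighted Ve"
        }
      },
      "required": [
        "split_min",
        "method",
        "stage2_mode",
        "stage1",
        "stage2",
        "weighted_ve"
      ],
      "title": "TwoStageReport",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "input": {
      "title": "Input",
      "type": "string"
    },
    "mode": {
      "title": "Mode",
      "type": "string"
    },
    "aif": {
      "$ref": "#/$defs/AIFReport"
    },
    "gkm": {
      "anyOf": [
        {
          "$ref": "#/$defs/GKMReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "two_stage": {
      "anyOf": [
        {
          "$ref": "#/$defs/TwoStageReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "input",
    "mode",
    "aif"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
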