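{
  "$defs": {
    "AssociationEntry": {
      "properties": {
        "ci_high": {
          "title": "Ci High",
          "type": "number"
        },
        "ci_low": {
          "title": "Ci Low",
          "type": "number"
        },
        "covariate_estimates": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Covariate Estimates",
          "type": "object"
        },
        "estimate": {
          "title": "Estimate",
          "type": "number"
        },
        "formula": {
          "title": "Formula",
          "type": "string"
        },
        "model": {
          "title": "Model",
          "type": "string"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "odds_ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Odds Ratio"
        },
        "outcome": {
          "title": "Outcome",
          "type": "string"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "se": {
          "title": "Se",
          "type": "number"
        }
      },
      "required": [
        "model",
        "outcome",
        "estimate",
        "se",
        "ci_low",
        "ci_high",
        "p_value",
        "n",
        "covariate_estimates",
        "formula"
      ],
      "title": "AssociationEntry",
      "type": "object"
    },
    "CohortSummary": {
      "properties": {
        "bdr_mean": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bdr Mean"
        },
        "bdr_sd": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bdr Sd"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "n_variants": {
          "title": "N Variants",
          "type": "integer"
        },
        "prs_raw_mean": {
          "title": "Prs Raw Mean",
          "type": "number"
        },
        "prs_raw_sd": {
          "title": "Prs Raw Sd",
          "type": "number"
        },
        "responder_fraction_12": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Responder Fraction 12"
        },
        "responder_fraction_8": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Responder Fraction 8"
        }
      },
      "required": [
        "n",
        "prs_raw_mean",
        "prs_raw_sd",
        "n_variants"
      ],
      "title": "CohortSummary",
      "type": "object"
    },
    "WeightTableSummary": {
      "properties": {
        "cadd_min": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cadd Min"
        },
        "n_selected": {
          "title": "N Selected",
          "type": "integer"
        },
        "p_max": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Max"
        },
        "provenance": {
          "default": "",
          "title": "Provenance",
          "type": "string"
        }
      },
      "required": [
        "n_selected"
      ],
      "title": "WeightTableSummary",
      "type": "object"
    }
  },
  "description": "Versioned, JSON-serializable record of one pipeline run.",
  "properties": {
    "association_results": {
      "items": {
        "$ref": "#/$defs/AssociationEntry"
      },
      "title": "Association Results",
      "type": "array"
    },
    "cohort_summary": {
      "$ref": "#/$defs/CohortSummary"
    },
    "config_echo": {
      "additionalProperties": true,
      "title": "Config Echo",
      "type": "object"
    },
    "interaction_p_values": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Interaction P Values",
      "type": "object"
    },
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "software_version": {
      "default": "0.1.0",
      "title": "Software Version",
      "type": "string"
    },
    "weight_table_summary": {
      "$ref": "#/$defs/WeightTableSummary"
    }
  },
  "required": [
    "weight_table_summary",
    "cohort_summary",
    "association_results"
  ],
  "title": "PipelineReport",
  "type": "object"
}
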