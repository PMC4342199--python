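{
  "$comment": "Structural schema for the Genome Report JSON packet",
  "type": "object",
  "required": [
    "case_id",
    "study_arm",
    "coverage",
    "indication_results",
    "monogenic_findings",
    "carrier_findings",
    "pgx_results",
    "blood_statuses",
    "abo_rh",
    "blood_summary",
    "blood_flags",
    "variant_details",
    "limitations",
    "methodology",
    "references",
    "findings",
    "schema_version"
  ],
  "properties": {
    "case_id": {
      "type": "string"
    },
    "study_arm": {
      "type": "string"
    },
    "schema_version": {
      "type": "string"
    },
    "coverage": {
      "type": "object",
      "required": [
        "mean_coverage",
        "pct_bases_ge_8x",
        "total_variants"
      ],
      "properties": {
        "mean_coverage": {
          "type": "number"
        },
        "pct_bases_ge_8x": {
          "type": "number"
        },
        "total_variants": {
          "type": "integer"
        }
      }
    },
    "indication_results": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "disease",
          "inheritance",
          "gene",
          "transcript",
          "c_hgvs",
          "p_hgvs",
          "variant_key",
          "classification",
          "zygosity"
        ],
        "properties": {
          "disease": {
            "type": "string"
          },
          "inheritance": {
            "type": "string"
          },
          "gene": {
            "type": "string"
          },
          "variant_key": {
            "type": "string"
          },
          "classification": {
            "type": "string"
          },
          "zygosity": {
            "type": "string"
          },
          "indication": {
            "type": "boolean"
          }
        }
      }
    },
    "monogenic_findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "disease",
          "inheritance",
          "gene",
          "transcript",
          "c_hgvs",
          "p_hgvs",
          "variant_key",
          "classification",
          "zygosity"
        ],
        "properties": {
          "disease": {
            "type": "string"
          },
          "inheritance": {
            "type": "string"
          },
          "gene": {
            "type": "string"
          },
          "variant_key": {
            "type": "string"
          },
          "classification": {
            "type": "string"
          },
          "zygosity": {
            "type": "string"
          },
          "indication": {
            "type": "boolean"
          }
        }
      }
    },
    "carrier_findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "disease",
          "inheritance",
          "gene",
          "transcript",
          "c_hgvs",
          "p_hgvs",
          "variant_key",
          "classification",
          "zygosity"
        ],
        "properties": {
          "disease": {
            "type": "string"
          },
          "inheritance": {
            "type": "string"
          },
          "gene": {
            "type": "string"
          },
          "variant_key": {
            "type": "string"
          },
          "classification": {
            "type": "string"
          },
          "zygosity": {
            "type": "string"
          },
          "indication": {
            "type": "boolean"
          }
        }
      }
    },
    "pgx_results": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "drug",
          "genes",
          "diplotype",
          "phenotype_phrase",
          "no_call"
        ],
        "properties": {
          "drug": {
            "type": "string"
          },
          "diplotype": {
            "type": "string"
          },
          "phenotype_phrase": {
            "type": "string"
          },
          "no_call": {
            "type": "boolean"
          },
          "diplotype_frequency": {
            "type": [
              "number",
              "null"
            ]
          }
        }
      }
    },
    "blood_statuses": {
      "type": "object"
    },
    "abo_rh": {
      "type": "string"
    },
    "blood_summary": {
      "type": "string"
    },
    "blood_flags": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "variant_details": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "variant_key",
          "gene",
          "disease",
          "interpretation"
        ]
      }
    },
    "limitations": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "methodology": {
      "type": "string"
    },
    "references": {
      "type": "array",
      "items": {
        "type": "string"
      }
    },
    "findings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "variant_key",
          "disease",
          "classification",
          "section"
        ]
      }
    }
  }
}
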