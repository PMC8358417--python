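{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Recurrent-ovarian-cancer trial record list",
 "type": "array",
 "items": {
  "$defs": {
   "ComparatorClass": {
    "description": "Curated annotation of what the control arm is, for the adequacy rule.",
    "enum": [
     "platinum_based",
     "guideline_listed",
     "placebo_or_no_treatment",
     "other"
    ],
    "title": "ComparatorClass",
    "type": "string"
   },
   "ConfidenceInterval": {
    "description": "A 95% confidence interval for a (dimensionless) hazard ratio.",
    "properties": {
     "lower": {
      "title": "Lower",
      "type": "number"
     },
     "upper": {
      "title": "Upper",
      "type": "number"
     }
    },
    "required": [
     "lower",
     "upper"
    ],
    "title": "ConfidenceInterval",
    "type": "object"
   },
   "Design": {
    "enum": [
     "phase3_rct",
     "phase2_rct",
     "other"
    ],
    "title": "Design",
    "type": "string"
   },
   "Endpoint": {
    "description": "Endpoint kinds a trial row can summarise.",
    "enum": [
     "os",
     "pfs",
     "orr",
     "qol_tox"
    ],
    "title": "Endpoint",
    "type": "string"
   },
   "EndpointSummary": {
    "description": "Published summary of one endpoint of one trial (or subgroup) row.",
    "properties": {
     "endpoint": {
      "$ref": "#/$defs/Endpoint"
     },
     "control_median": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Control Median"
     },
     "gain": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Gain"
     },
     "hazard_ratio": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Hazard Ratio"
     },
     "hr_ci": {
      "anyOf": [
       {
        "$ref": "#/$defs/ConfidenceInterval"
       },
       {
        "type": "null"
       }
      ],
      "default": null
     },
     "orr_pct": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ],
      "default": null,
      "title": "Orr Pct"
     },
     "significant": {
      "$ref": "#/$defs/Significance",
      "default": "exploratory_or_unreported"
     }
    },
    "required": [
     "endpoint"
    ],
    "title": "EndpointSummary",
    "type": "object"
   },
   "EvidenceFlags": {
    "description": "Quality-of-life / toxicity evidence driving the \u00b11 adjustment.\n\n``qol_subscale_improved`` is reserved for *prespecified* subscale\nanalyses (the only kind the scale credits).",
    "properties": {
     "qol_reported": {
      "default": false,
      "title": "Qol Reported",
      "type": "boolean"
     },
     "qol_global_improved": {
      "default": false,
      "title": "Qol Global Improved",
      "type": "boolean"
     },
     "qol_subscale_improved": {
      "default": false,
      "title": "Qol Subscale Improved",
      "type": "boolean"
     },
     "toxicity_reduced": {
      "default": false,
      "title": "Toxicity Reduced",
      "type": "boolean"
     },
     "toxicity_increased": {
      "default": false,
      "title": "Toxicity Increased",
      "type": "boolean"
     },
     "early_discontinuation_reduced": {
      "default": false,
      "title": "Early Discontinuation Reduced",
      "type": "boolean"
     }
    },
    "title": "EvidenceFlags",
    "type": "object"
   },
   "PrimaryEndpoint": {
    "description": "Primary endpoint declared by the trial (drives evaluation-form choice).",
    "enum": [
     "os",
     "pfs",
     "orr",
     "qol_tox",
     "noninferiority"
    ],
    "title": "PrimaryEndpoint",
    "type": "string"
   },
   "Setting": {
    "description": "Treatment setting within recurrent ovarian cancer.",
    "enum": [
     "platinum_sensitive",
     "maintenance",
     "platinum_resistant"
    ],
    "title": "Setting",
    "type": "string"
   },
   "Significance": {
    "description": "Tri-state significance status of an endpoint result.\n\n``CONFIRMED`` means a statistically significant *benefit of the study\narm* under the trial's prespecified, multiplicity-controlled test.  An\nexploratory analysis that was not corrected for multiple testing is\nnever ``CONFIRMED``, however small its p-value.",
    "enum": [
     "confirmed",
     "not_significant",
     "exploratory_or_unreported"
    ],
    "title": "Significance",
    "type": "string"
   }
  },
  "description": "One trial \u2014 or one prespecified subgroup row of a trial.\n\nA trial whose table row fans out into subgroup analyses (ITT / gBRCA /\nHRD \u2026) is stored as one parent record plus one record per subgroup with\n``subgroup_of`` pointing at the parent, mirroring the row structure of\nthe source tables: each row carries its own grade.",
  "properties": {
   "trial_id": {
    "title": "Trial Id",
    "type": "string"
   },
   "study_name": {
    "anyOf": [
     {
      "type": "string"
     },
     {
      "type": "null"
     }
    ],
    "default": null,
    "title": "Study Name"
   },
   "setting": {
    "$ref": "#/$defs/Setting"
   },
   "design": {
    "$ref": "#/$defs/Design"
   },
   "n": {
    "title": "N",
    "type": "integer"
   },
   "experimental_label": {
    "title": "Experimental Label",
    "type": "string"
   },
   "comparator_label": {
    "title": "Comparator Label",
    "type": "string"
   },
   "primary_endpoint": {
    "$ref": "#/$defs/PrimaryEndpoint"
   },
   "endpoints": {
    "items": {
     "$ref": "#/$defs/EndpointSummary"
    },
    "title": "Endpoints",
    "type": "array"
   },
   "evidence": {
    "$ref": "#/$defs/EvidenceFlags"
   },
   "subgroup_of": {
    "anyOf": [
     {
      "type": "string"
     },
     {
      "type": "null"
     }
    ],
    "default": null,
    "title": "Subgroup Of"
   },
   "subgroup_prespecified": {
    "default": false,
    "title": "Subgroup Prespecified",
    "type": "boolean"
   },
   "comparator_adequate": {
    "default": true,
    "title": "Comparator Adequate",
    "type": "boolean"
   },
   "terminated_early": {
    "default": false,
    "title": "Terminated Early",
    "type": "boolean"
   },
   "superseded": {
    "default": false,
    "title": "Superseded",
    "type": "boolean"
   },
   "comparator_class": {
    "anyOf": [
     {
      "$ref": "#/$defs/ComparatorClass"
     },
     {
      "type": "null"
     }
    ],
    "default": null
   }
  },
  "required": [
   "trial_id",
   "setting",
   "design",
   "n",
   "experimental_label",
   "comparator_label",
   "primary_endpoint"
  ],
  "title": "TrialRecord",
  "type": "object"
 }
}
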