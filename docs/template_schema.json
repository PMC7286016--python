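{
 "$defs": {
  "CostFunction": {
   "description": "One Monaco-style cost function.\n\n``isoconstraint`` is the user-set bound: an RMS excess in Gy for the\nquadratic kinds, a dose in Gy for ``max_dose``, an EUD in Gy for\n``serial_eud``.  ``shrink_margin`` erodes the structure away from the\nadjacent higher-priority target before the function is evaluated.\nA set ``fixed_weight`` moves the function out of the constraint set and\ninto the objective as a weighted penalty (manual-priority override).",
   "properties": {
    "eud_k": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Eud K"
    },
    "fixed_weight": {
     "anyOf": [
      {
       "exclusiveMinimum": 0.0,
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Fixed Weight"
    },
    "id": {
     "title": "Id",
     "type": "string"
    },
    "isoconstraint": {
     "minimum": 0.0,
     "title": "Isoconstraint",
     "type": "number"
    },
    "kind": {
     "enum": [
      "quadratic_underdose",
      "quadratic_overdose",
      "max_dose",
      "serial_eud"
     ],
     "title": "Kind",
     "type": "string"
    },
    "reference_dose": {
     "exclusiveMinimum": 0.0,
     "title": "Reference Dose",
     "type": "number"
    },
    "role": {
     "default": "constraint",
     "enum": [
      "objective",
      "constraint"
     ],
     "title": "Role",
     "type": "string"
    },
    "shrink_margin": {
     "default": 0.0,
     "minimum": 0.0,
     "title": "Shrink Margin",
     "type": "number"
    },
    "structure": {
     "title": "Structure",
     "type": "string"
    }
   },
   "required": [
    "id",
    "structure",
    "kind",
    "reference_dose",
    "isoconstraint"
   ],
   "title": "CostFunction",
   "type": "object"
  },
  "PrescriptionItem": {
   "description": "One dosimetric goal on a target or OAR.\n\n``threshold`` is a %-volume for the V_D metrics and a dose in Gy for the\nD_max / D_mean metrics.",
   "properties": {
    "direction": {
     "enum": [
      "lower_bound",
      "upper_bound"
     ],
     "title": "Direction",
     "type": "string"
    },
    "dose_gy": {
     "exclusiveMinimum": 0.0,
     "title": "Dose Gy",
     "type": "number"
    },
    "id": {
     "title": "Id",
     "type": "string"
    },
    "metric": {
     "enum": [
      "V_D_at_least",
      "V_D_at_most",
      "D_max_at_most",
      "D_mean_at_most"
     ],
     "title": "Metric",
     "type": "string"
    },
    "structure": {
     "title": "Structure",
     "type": "string"
    },
    "threshold": {
     "exclusiveMinimum": 0.0,
     "title": "Threshold",
     "type": "number"
    }
   },
   "required": [
    "id",
    "structure",
    "metric",
    "dose_gy",
    "threshold",
    "direction"
   ],
   "title": "PrescriptionItem",
   "type": "object"
  }
 },
 "description": "Versioned JSON plan template: cost functions with isoconstraints and shrink margins, prescription items, modifier bookkeeping.",
 "properties": {
  "caps": {
   "default": [
    15,
    15,
    30
   ],
   "maxItems": 3,
   "minItems": 3,
   "prefixItems": [
    {
     "type": "integer"
    },
    {
     "type": "integer"
    },
    {
     "type": "integer"
    }
   ],
   "title": "Caps",
   "type": "array"
  },
  "case_ref": {
   "default": "",
   "title": "Case Ref",
   "type": "string"
  },
  "cost_functions": {
   "items": {
    "$ref": "#/$defs/CostFunction"
   },
   "title": "Cost Functions",
   "type": "array"
  },
  "prescription_items": {
   "items": {
    "$ref": "#/$defs/PrescriptionItem"
   },
   "title": "Prescription Items",
   "type": "array"
  },
  "stage_state": {
   "default": 1,
   "maximum": 3,
   "minimum": 1,
   "title": "Stage State",
   "type": "integer"
  },
  "trial_index": {
   "default": 0,
   "title": "Trial Index",
   "type": "integer"
  },
  "version": {
   "default": "1",
   "title": "Version",
   "type": "string"
  }
 },
 "required": [
  "cost_functions",
  "prescription_items"
 ],
 "title": "Plan template",
 "type": "object"
}
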