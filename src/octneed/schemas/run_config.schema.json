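{
 "$defs": {
  "BiomarkerSection": {
   "properties": {
    "min_size": {
     "default": 20,
     "minimum": 0,
     "title": "Min Size",
     "type": "integer"
    },
    "relative_threshold": {
     "default": 0.45,
     "exclusiveMinimum": 0,
     "title": "Relative Threshold",
     "type": "number"
    },
    "smooth_sigma": {
     "default": 0.7,
     "minimum": 0,
     "title": "Smooth Sigma",
     "type": "number"
    }
   },
   "title": "BiomarkerSection",
   "type": "object"
  },
  "CohortSection": {
   "properties": {
    "activity_mu": {
     "default": 2.5,
     "title": "Activity Mu",
     "type": "number"
    },
    "activity_sigma": {
     "default": 1.1,
     "title": "Activity Sigma",
     "type": "number"
    },
    "decay_rate": {
     "default": 0.15,
     "title": "Decay Rate",
     "type": "number"
    },
    "horizon_weeks": {
     "default": 104,
     "minimum": 52,
     "title": "Horizon Weeks",
     "type": "integer"
    },
    "late_start_fraction": {
     "default": 0.5,
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "Late Start Fraction",
     "type": "number"
    },
    "max_interval_weeks": {
     "default": 16,
     "title": "Max Interval Weeks",
     "type": "integer"
    },
    "min_interval_weeks": {
     "default": 8,
     "title": "Min Interval Weeks",
     "type": "integer"
    },
    "n_patients": {
     "default": 40,
     "exclusiveMinimum": 0,
     "title": "N Patients",
     "type": "integer"
    },
    "noise_sd": {
     "default": 0.35,
     "title": "Noise Sd",
     "type": "number"
    },
    "srf_gain": {
     "default": 2.5,
     "title": "Srf Gain",
     "type": "number"
    },
    "step_weeks": {
     "default": 2,
     "title": "Step Weeks",
     "type": "integer"
    }
   },
   "title": "CohortSection",
   "type": "object"
  },
  "DeviceSection": {
   "properties": {
    "axial_um_per_px": {
     "default": 7.0,
     "exclusiveMinimum": 0,
     "title": "Axial Um Per Px",
     "type": "number"
    },
    "bscan_spacing_um": {
     "default": 120.0,
     "exclusiveMinimum": 0,
     "title": "Bscan Spacing Um",
     "type": "number"
    },
    "height_px": {
     "default": 192,
     "exclusiveMinimum": 0,
     "title": "Height Px",
     "type": "integer"
    },
    "intensity_gamma": {
     "default": 1.0,
     "exclusiveMinimum": 0,
     "title": "Intensity Gamma",
     "type": "number"
    },
    "lateral_um_per_px": {
     "default": 23.3333333333,
     "exclusiveMinimum": 0,
     "title": "Lateral Um Per Px",
     "type": "number"
    },
    "n_bscans": {
     "default": 31,
     "minimum": 28,
     "title": "N Bscans",
     "type": "integer"
    },
    "speckle_sd": {
     "default": 0.22,
     "minimum": 0,
     "title": "Speckle Sd",
     "type": "number"
    },
    "width_px": {
     "default": 144,
     "exclusiveMinimum": 0,
     "title": "Width Px",
     "type": "integer"
    }
   },
   "title": "DeviceSection",
   "type": "object"
  },
  "EvaluateSection": {
   "properties": {
    "experiments": {
     "default": [
      "1",
      "2y1",
      "2y2",
      "3"
     ],
     "items": {
      "type": "string"
     },
     "title": "Experiments",
     "type": "array"
    },
    "l2_strength": {
     "default": 1.0,
     "exclusiveMinimum": 0,
     "title": "L2 Strength",
     "type": "number"
    },
    "model": {
     "default": "logreg",
     "title": "Model",
     "type": "string"
    },
    "repeats": {
     "default": 5,
     "exclusiveMinimum": 0,
     "title": "Repeats",
     "type": "integer"
    }
   },
   "title": "EvaluateSection",
   "type": "object"
  }
 },
 "properties": {
  "biomarkers": {
   "$ref": "#/$defs/BiomarkerSection",
   "default": {
    "min_size": 20,
    "relative_threshold": 0.45,
    "smooth_sigma": 0.7
   }
  },
  "cohort": {
   "$ref": "#/$defs/CohortSection",
   "default": {
    "activity_mu": 2.5,
    "activity_sigma": 1.1,
    "decay_rate": 0.15,
    "horizon_weeks": 104,
    "late_start_fraction": 0.5,
    "max_interval_weeks": 16,
    "min_interval_weeks": 8,
    "n_patients": 40,
    "noise_sd": 0.35,
    "srf_gain": 2.5,
    "step_weeks": 2
   }
  },
  "device": {
   "$ref": "#/$defs/DeviceSection",
   "default": {
    "axial_um_per_px": 7.0,
    "bscan_spacing_um": 120.0,
    "height_px": 192,
    "intensity_gamma": 1.0,
    "lateral_um_per_px": 23.3333333333,
    "n_bscans": 31,
    "speckle_sd": 0.22,
    "width_px": 144
   }
  },
  "evaluate": {
   "$ref": "#/$defs/EvaluateSection",
   "default": {
    "experiments": [
     "1",
     "2y1",
     "2y2",
     "3"
    ],
    "l2_strength": 1.0,
    "model": "logreg",
    "repeats": 5
   }
  },
  "log_level": {
   "default": "INFO",
   "title": "Log Level",
   "type": "string"
  },
  "output_root": {
   "default": "octneed_run",
   "title": "Output Root",
   "type": "string"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  }
 },
 "title": "RunConfig",
 "type": "object"
}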