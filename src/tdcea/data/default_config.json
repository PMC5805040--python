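{
 "cohort": {
  "deployment_size": {
   "value": 50000,
   "low": 35000,
   "high": 80000,
   "dist": "triangular"
  },
  "duration_months": {
   "value": 3.5,
   "low": 1.0,
   "high": 12.0,
   "dist": "triangular"
  },
  "monthly_incidence": {
   "value": 0.289,
   "low": 0.162,
   "high": 0.416,
   "dist": "normal"
  }
 },
 "parameters": {
  "p_no_mh": {
   "value": 0.6907,
   "low": 0.68,
   "high": 0.87,
   "dist": "triangular"
  },
  "p_run_course": {
   "value": 0.6,
   "low": 0.3,
   "high": 0.9,
   "dist": "triangular"
  },
  "p_self_success": {
   "value": 0.32,
   "low": 0.16,
   "high": 0.48,
   "dist": "triangular"
  },
  "p_self_failure": {
   "value": 0.08,
   "low": 0.04,
   "high": 0.12,
   "dist": "triangular"
  },
  "p_medevac": {
   "value": 0.0003,
   "low": 0.0002,
   "high": 0.0004,
   "dist": "triangular"
  },
  "p_mh_treatment": {
   "value": 0.3,
   "low": 0.13,
   "high": 0.42,
   "dist": "triangular"
  },
  "p_suboptimal": {
   "value": 0.278,
   "low": 0.16,
   "high": 0.51,
   "dist": "triangular"
  },
  "p_optimal": {
   "value": 0.351,
   "low": 0.27,
   "high": 0.57,
   "dist": "triangular"
  },
  "p_bedrest": {
   "value": 0.371,
   "low": 0.13,
   "high": 0.47,
   "dist": "triangular"
  },
  "p_hospitalization": {
   "value": 0.009,
   "low": 0.003,
   "high": 0.024,
   "dist": "triangular"
  },
  "cost_medevac": {
   "value": 16938,
   "low": 13550,
   "high": 20326,
   "dist": "triangular"
  },
  "cost_hospital": {
   "value": 2907,
   "low": 2325,
   "high": 3488,
   "dist": "triangular"
  },
  "cost_bedrest": {
   "value": 104,
   "low": 84,
   "high": 125,
   "dist": "triangular"
  },
  "cost_suboptimal": {
   "value": 70,
   "low": 56,
   "high": 84,
   "dist": "triangular"
  },
  "cost_optimal": {
   "value": 82,
   "low": 65,
   "high": 98,
   "dist": "triangular"
  },
  "cost_self_failure": {
   "value": 27,
   "low": 22,
   "high": 32,
   "dist": "triangular"
  },
  "ddl_suboptimal": {
   "value": 0.7,
   "low": 0.4,
   "high": 1.0,
   "dist": "normal"
  },
  "ddl_optimal": {
   "value": 0.37,
   "low": 0.23,
   "high": 0.52,
   "dist": "normal"
  },
  "ddl_bedrest": {
   "value": 1.6,
   "low": 1.0,
   "high": 2.0,
   "dist": "triangular"
  },
  "ddl_hospital": {
   "value": 1.7,
   "low": 1.0,
   "high": 3.0,
   "dist": "triangular"
  },
  "ddl_medevac": {
   "value": 7,
   "low": 3,
   "high": 10,
   "dist": "triangular"
  },
  "ddl_run_course": {
   "value": 0.37,
   "low": 0.23,
   "high": 0.52,
   "dist": "normal"
  },
  "ddl_self_success": {
   "value": 0.18,
   "low": 0.11,
   "high": 0.25,
   "dist": "normal"
  },
  "ddl_self_failure": {
   "value": 0.48,
   "low": 0.29,
   "high": 0.67,
   "dist": "normal"
  }
 }
}
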