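# Default 21-member projection ensemble.
#
# The grid spans the structural axes the method varies: period structure
# (common index | Lee–Carter age-loaded | age-group-specific trends), age
# smoothing (independent | first-difference | second-difference penalty),
# birth-cohort effects (off | smoothed), recency weighting of observations
# (time_weight 1.0 equal, 0.95 / 0.90 favouring recent years), and the trend
# extrapolation (linear | random walk with drift).  Edit or replace this file
# to redefine the ensemble; ids must be unique.
members:
  - {id: com-lin-ind,      period_structure: common,       age_structure: independent, cohort_effect: none,     time_weight: 1.0,  trend: linear}
  - {id: com-lin-rw1,      period_structure: common,       age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: linear}
  - {id: com-rwd-ind,      period_structure: common,       age_structure: independent, cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: com-rwd-rw1,      period_structure: common,       age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: com-rwd-rw2,      period_structure: common,       age_structure: rw2,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: com-rwd-rw1-w95,  period_structure: common,       age_structure: rw1,         cohort_effect: none,     time_weight: 0.95, trend: rwd}
  - {id: com-rwd-rw1-coh,  period_structure: common,       age_structure: rw1,         cohort_effect: smoothed, time_weight: 1.0,  trend: rwd}
  - {id: lc-lin-ind,       period_structure: age_loaded,   age_structure: independent, cohort_effect: none,     time_weight: 1.0,  trend: linear}
  - {id: lc-lin-rw1,       period_structure: age_loaded,   age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: linear}
  - {id: lc-rwd-ind,       period_structure: age_loaded,   age_structure: independent, cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: lc-rwd-rw1,       period_structure: age_loaded,   age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: lc-rwd-rw2,       period_structure: age_loaded,   age_structure: rw2,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: lc-rwd-rw1-w95,   period_structure: age_loaded,   age_structure: rw1,         cohort_effect: none,     time_weight: 0.95, trend: rwd}
  - {id: lc-rwd-rw1-w90,   period_structure: age_loaded,   age_structure: rw1,         cohort_effect: none,     time_weight: 0.90, trend: rwd}
  - {id: lc-rwd-rw1-coh,   period_structure: age_loaded,   age_structure: rw1,         cohort_effect: smoothed, time_weight: 1.0,  trend: rwd}
  - {id: lc-lin-rw1-coh,   period_structure: age_loaded,   age_structure: rw1,         cohort_effect: smoothed, time_weight: 1.0,  trend: linear}
  - {id: as-lin-rw1,       period_structure: age_specific, age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: linear}
  - {id: as-rwd-rw1,       period_structure: age_specific, age_structure: rw1,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: as-rwd-rw2,       period_structure: age_specific, age_structure: rw2,         cohort_effect: none,     time_weight: 1.0,  trend: rwd}
  - {id: as-rwd-rw1-w95,   period_structure: age_specific, age_structure: rw1,         cohort_effect: none,     time_weight: 0.95, trend: rwd}
  - {id: as-rwd-rw1-coh,   period_structure: age_specific, age_structure: rw1,         cohort_effect: smoothed, time_weight: 1.0,  trend: rwd}
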