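# Demo pipeline configuration: three discovery cohorts at the published
# case/control splits, with repertoire sizes scaled down so the full
# pipeline runs in minutes on one CPU. See docs/methods.md for the
# parameter dictionary.
seed: 0

generator:
  cohorts:
    - {name: NationMS-Muenster, n_cases: 58, n_controls: 211,
       freq_a: 0.3086, freq_b: 0.4765, dprime: 0.31}
    - {name: ACP, n_cases: 75, n_controls: 234,
       freq_a: 0.3269, freq_b: 0.4401, dprime: 0.27}
    - {name: FinBB, n_cases: 71, n_controls: 978,
       freq_a: 0.4909, freq_b: 0.4662, dprime: 0.10}
  mean_unique: 300          # unique productive rearrangements per sample
  pool_size: 2000           # shared public clonotype pool
  n_planted_a: 65           # class-I-restricted treatment-associated clonotypes
  n_planted_b: 35           # class-II-restricted
  n_planted_other: 5        # exposure-associated, no HLA background
  n_feature_keys: 100       # allele-marker clonotypes per allele (imputation)
  background_presence: 0.02
  exposed_carrier_presence: 0.30
  synergy: 1.5

discovery:
  p_seq: 1.0e-3
  p_motif: 1.0e-4
  min_replicated_cohorts: 2

clinical:
  followup_years: 3.0
  baseline_hazard: 0.3
  hr_ga_x_a03: 0.66
  hr_gaifn_x_a03: 0.67

trial:
  recurrent:
    - [IFN, 168, 56]
    - [GA, 172, 60]
    - [GA+IFN, 353, 95]
  first_event:
    - [IFN, 239, 74]
    - [GA, 96, 32]
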