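# Simulation setting 2: 924 patients, 50% subgroup prevalence, benefit in
# both the subgroup and its complement (HR 0.7 for PFS and OS everywhere).
setting: 2
n_total: 924
subgroup_prevalence: 0.5
enroll_duration: 33.0
followup_duration: 24.0
control_median:
  PFS: {subgroup: 4.0, complement: 3.0}
  OS: {subgroup: 10.5, complement: 5.7}
hazard_ratio:
  PFS: {subgroup: 0.7, complement: 0.7}
  OS: {subgroup: 0.7, complement: 0.7}
annual_dropout: {PFS: 0.10, OS: 0.01}
futility:
  gamma: 0.05
  hr_alt: 0.7
  theta: {F: 0.83, S: 0.85}
alpha_total: 0.025
alpha_allocation:
  gsd_ad: {F_OS: 0.00025, F_PFS: 0.00017, S_OS: 0.01458, S_PFS: 0.01000}
  ggsd:   {F_OS: 0.01488, F_PFS: 0.01012, S_OS: 0.01480, S_PFS: 0.01020}
information_fractions:
  F: {PFS: [0.90, 1.0], OS: [0.69, 0.92, 1.0]}
  S: {PFS: [0.89, 1.0], OS: [0.66, 0.91, 1.0]}
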