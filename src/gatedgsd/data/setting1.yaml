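# Simulation setting 1: 554 patients, 75% subgroup prevalence, benefit in
# both the subgroup and its complement (HR 0.7 for PFS and OS everywhere).
setting: 1
n_total: 554
subgroup_prevalence: 0.75
enroll_duration: 28.0
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
  theta: {F: 0.85, S: 0.90}
alpha_total: 0.025
alpha_allocation:
  gsd_ad: {F_OS: 0.00220, F_PFS: 0.00165, S_OS: 0.01280, S_PFS: 0.00835}
  ggsd:   {F_OS: 0.01429, F_PFS: 0.01071, S_OS: 0.01513, S_PFS: 0.00987}
information_fractions:
  F: {PFS: [0.90, 1.0], OS: [0.69, 0.92, 1.0]}
  S: {PFS: [0.89, 1.0], OS: [0.66, 0.91, 1.0]}
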