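name: C2
constants:
  rnap_total: 75.0
  ribosome_total: 2000.0
  tx_elongation_rate: 108000.0
  tl_elongation_rate: 5400.0
  tx_saturation: 36.0
  tl_saturation: 253750.0
  polysome_gain: 10.0
  tx_initiation_time: 22.0
  tl_initiation_time: 1.5
  mrna_deg_default: 3.75
  protein_deg_default: 0.93
  temperature: 302.15
  capacity_halflife: 8.86
genes:
- name: sigma28
  gene_conc: 1.5
  gene_length: 811
  protein_length: 240
  mrna_deg_modifier: 0.7413338829518131
  protein_deg_modifier: 0.004059474667697105
  tx_time_constant: 0.0018
  tl_time_constant: 1.1
- name: cI_ssrA
  gene_conc: 1.0
  gene_length: 850
  protein_length: 248
  mrna_deg_modifier: 1.3691796159208798
  protein_deg_modifier: 0.0675108287127888
  tx_time_constant: 0.001
  tl_time_constant: 0.054
- name: deGFP_ssrA
  gene_conc: 8.0
  gene_length: 782
  protein_length: 237
  mrna_deg_modifier: 1.4328623887544087
  protein_deg_modifier: 0.6089212001545657
  tx_time_constant: 0.045
  tl_time_constant: 0.058
promoters:
  sigma28:
  - label: RNAP
    gibbs_energy: 46.67
    expressing: true
  - label: RNAP_sigma70
    gibbs_energy: -10.46
    expressing: true
    binding:
      regulator: sigma70
      dissociation_constant: 1350.0
      hill_coefficient: 1.1
      sense: activator
  - label: cI
    gibbs_energy: -12.89
    expressing: false
    binding:
      regulator: cI_ssrA
      dissociation_constant: 38.9
      hill_coefficient: 1.51
      sense: repressor
  deGFP_ssrA:
  - label: RNAP
    gibbs_energy: 41.94
    expressing: true
  - label: RNAP_sigma70
    gibbs_energy: -27.67
    expressing: true
    binding:
      regulator: sigma70
      dissociation_constant: 86870.0
      hill_coefficient: 1.53
      sense: activator
  - label: cI
    gibbs_energy: -7.21
    expressing: false
    binding:
      regulator: cI_ssrA
      dissociation_constant: 3830.0
      hill_coefficient: 0.698
      sense: repressor
  cI_ssrA:
  - label: RNAP
    gibbs_energy: 46.57
    expressing: true
  - label: RNAP_sigma28
    gibbs_energy: -0.0011
    expressing: true
    binding:
      regulator: sigma28
      dissociation_constant: 1090.0
      hill_coefficient: 1.88
      sense: activator
constitutive:
- name: sigma70
  initial_conc: 35.0
  protein_deg_modifier: 0.002089837227986733
initial_conditions: {}
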