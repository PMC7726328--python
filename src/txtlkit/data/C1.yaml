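name: C1
constants:
  rnap_total: 75.0
  ribosome_total: 2000.0
  tx_elongation_rate: 108000.0
  tl_elongation_rate: 5400.0
  tx_saturation: 36.0
  tl_saturation: 483130.0
  polysome_gain: 10.0
  tx_initiation_time: 22.0
  tl_initiation_time: 1.5
  mrna_deg_default: 3.75
  protein_deg_default: 0.93
  temperature: 302.15
  capacity_halflife: 4.03
genes:
- name: deGFP
  gene_conc: 5.0
  gene_length: 782
  protein_length: 237
  mrna_deg_modifier: 0.8215077695525277
  protein_deg_modifier: 0.0028595746968584582
  tx_time_constant: 0.61
  tl_time_constant: 0.16
promoters:
  deGFP:
  - label: RNAP
    gibbs_energy: 28.82
    expressing: true
  - label: RNAP_sigma70
    gibbs_energy: -20.38
    expressing: true
    binding:
      regulator: sigma70
      dissociation_constant: 24190.0
      hill_coefficient: 1.12
      sense: activator
constitutive:
- name: sigma70
  initial_conc: 35.0
  protein_deg_modifier: 0.008508214029556947
initial_conditions: {}
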