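# Study-like synthetic genome specification for `baculo simulate --spec ...`
# (all fields optional except length_bp and n_orfs; seed comes from --seed
# unless given here).  This is the generator's default configuration written
# out explicitly.

length_bp: 20000
n_orfs: 15
gc_percent: 37.18
orf_codon_range: [50, 300]
strand_fraction_plus: 0.7

promoter_plan:
  early_prob: 0.3
  early_tata_offset_range: [-118, -80]
  cakt_spacing_range: [25, 35]
  lef_prob: 0.3
  lef_offset_range: [-75, -40]
  late_prob: 0.6
  late_offset_range: [-110, -10]

hr_specs:
  - unit_length: 104
    n_units: 5
    n_reverse: 2
    core: GTAAACGTTTAC
    mutation_rate: 0.02
    gap_range: [20, 40]

dr_specs:
  - unit: AT
    copies: 30
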