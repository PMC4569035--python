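# Native stable/declining population: individual monitoring from 1972,
# census ~100 growing to ~220 by 1989 then declining to ~60; genetic
# sampling (the panel) covers the 20 yearly cross-sections 1988-2007.
# No immigration enters the analysed panel.
name: rm_like
n_chromosomes: 26
loci_per_chromosome: 8
mean_spacing_cM: 15.6
spacing_sd_cM: 10.0
alleles_min: 5
alleles_max: 15
missing_rate: 0.02
census:
  - [1972, 100]
  - [1989, 220]
  - [2007, 60]
sampled_years: [1988, 2007]
pulses: []
male_fraction: 0.25
sire_geometric_ratio: 0.7
generation_time: 3
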