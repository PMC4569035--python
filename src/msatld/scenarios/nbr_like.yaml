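# Bottleneck-then-rescue population: founded in 1922 by 12 translocated
# individuals, mean census ~48 until 1985, then four admixture pulses from
# a diverged source herd (15 migrants in total: the 1993/1994 introductions
# were 6 and 3 individuals; the 1985/1990 split is taken as 4 and 2, first
# pulse largest).  Census recovers to ~142 by 2007; the panel covers the
# 20 yearly cross-sections 1988-2007.
name: nbr_like
n_chromosomes: 26
loci_per_chromosome: 8
mean_spacing_cM: 15.6
spacing_sd_cM: 10.0
alleles_min: 5
alleles_max: 15
missing_rate: 0.02
census:
  - [1922, 12]
  - [1924, 48]
  - [1985, 48]
  - [1992, 70]
  - [2007, 142]
sampled_years: [1988, 2007]
pulses:
  - [1985, 4]
  - [1990, 2]
  - [1993, 6]
  - [1994, 3]
source_divergence_generations: 20
source_size: 50
male_fraction: 0.25
sire_geometric_ratio: 0.7
generation_time: 3
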