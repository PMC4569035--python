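# msatld

Multi-allelic linkage disequilibrium (LD) dynamics for microsatellite
panels from long-term individual-based studies.

Linkage disequilibrium — the nonrandom association of alleles at two loci
— sets the marker density needed for association mapping, heterozygosity–
fitness studies and outlier scans, and its extent varies between
populations and with the sample at hand.  `msatld` implements the full
analysis chain used to characterize LD and its temporal dynamics in wild
populations genotyped at mapped multi-allelic markers:

* **Haplotype frequencies** for each marker pair from unphased diploid
  genotypes by the gene-counting EM algorithm (double heterozygotes split
  between phases in proportion to current estimates).
* **Multi-allelic LD statistics** on the fitted table x with marginals
  p, q and D_ij = x_ij − p_i q_j:
  D′ = Σ p_i q_j |D_ij/D_max(i,j)|, and
  χ′² = [Σ D_ij²/(p_i q_j)]/(min(k,m)−1), which reduces to r² for
  biallelic loci.  Both range over [0, 1].
* **Background LD** (mean over nonsyntenic pairs) and the **half-length**
  of decay: LD(d) = (b − P3)·e^(−d·ln2/P2) + P3 fitted to syntenic pairs
  under 50 cM with P3 fixed at the background level, so that P2 is
  literally the distance at which LD above background halves.
* **Subsampling designs**: the sample-size curve (10–200 individuals,
  many replicates, without replacement) quantifying how small samples
  inflate background LD and depress half-lengths, and yearly
  cross-sections at fixed k = 20 making estimates comparable across years.
* **Relatedness**: the Queller–Goodnight moment estimator (ratio-of-sums,
  full-panel reference frequencies), the pedigree additive-relationship
  matrix (tabular method), and Pearson tests linking yearly relatedness to
  yearly LD.
* **Model selection**: 2-SD-standardized OLS of syntenic LD on log
  distance, mean heterozygosity and chromosome, all-subsets ranking by
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with Akaike weights.
* **A forward simulator** of two demographic templates — a stable/declining
  native population, and a 12-founder bottleneck population rescued by
  admixture pulses — producing GenePop panels, linkage maps, yearly
  cohorts and pedigrees with known truth for testing everything above.

Inputs are the files such studies actually hold: GenePop genotypes, a
marker/chromosome/position_cM map TSV, a cohort TSV (individual, year) and
optionally a pedigree TSV.

## Worked example

Estimate background LD and the half-length on a simulated stable
population of 220 (the `examples/` directory holds one short script per
capability):

```python
import msatld as m
from msatld.simulate import stable_small

sim = m.simulate_population(stable_small(), seed=5)
pairs = m.pairwise_ld(sim.gm, sim.lmap)
for metric in ("dprime", "chi2prime"):
    bg = m.background_ld(pairs, metric)
    fit = m.fit_decay(pairs, metric, p3=bg.mean)
    print(metric, bg.mean, fit.b, fit.p2)
```

prints (formatted):

```
1128 marker pairs (206 syntenic < 50 cM)
dprime   : background 0.269 +/- 0.103 (n = 864); intercept b = 0.786; half-length P2 = 12.27 +/- 1.17 cM
chi2prime: background 0.061 +/- 0.034 (n = 864); intercept b = 0.526; half-length P2 = 7.52 +/- 0.69 cM
```

Background is the LD level among markers on different chromosomes (the
decay asymptote); the intercept stays below 1 because completely linked
markers need not be in complete LD; and D′ above background halves every
12.3 cM while χ′² — the stricter statistic — runs lower and decays
faster.  Subsampling the same panel shows the sample-size bias
(`examples/04_sample_size_bias.py`):

```
n =  10: background D' 0.613 (SD 0.010); half-length  8.46 cM
n =  50: background D' 0.379 (SD 0.007); half-length 10.16 cM
n = 200: background D' 0.272 (SD 0.001); half-length 12.02 cM
```

so a pilot study with 10 individuals would overstate background LD
twofold and understate the extent of useful LD — the practical reason to
aim for ~100+ samples before choosing a marker density.

A thin CLI mirrors the library
(`msatld simulate|panel|ld|decay|sscurve|temporal|related|correlate|lm|run`);
`msatld run --config run.yaml` executes the whole pipeline and writes
checksummed TSV/JSON artifacts plus plots.

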