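# Methods

## The analysis

`poolscan` implements a pooled exome-wide association scan for an
insecticide-resistance phenotype. Females from a field population are
exposed to a discriminating dose; survivors ("knockdown resistant") and
knocked-down individuals ("susceptible") are pooled — 25 females per pool,
two replicate pools per phenotype — and each pool is sequenced as one
library. Allele frequencies are estimated from read counts, so the unit of
observation throughout is the per-site, per-library nucleotide count vector
(A, C, G, T).

The stages, in order:

1. **Depth window.** A site is kept only if every library's depth satisfies
   `min_depth <= depth <= max_depth` (defaults 25 and 1000). The ceiling is
   a proxy for collapsed repetitive DNA; the floor bounds the sampling error
   of a pool frequency estimated from reads. The window is applied per
   library, the stricter of the two readings of a per-library/per-group
   ambiguity, and the choice is recorded in the filter report.
2. **Replicate concordance.** Within each phenotype group, the two replicate
   libraries are compared with a Pearson chi-square on the 2 x n table of
   nucleotide counts, n being the number of bases observed in either
   replicate, with n − 1 degrees of freedom; monomorphic sites return
   (0, 0, 1) by convention. Sites with p below `heterogeneity_alpha` are
   discarded as replicate-discordant.
3. **Intersection and polymorphism call.** Only sites retained in both
   groups are analysed. A site is polymorphic when, in the counts pooled
   over all four libraries, the second-most-frequent base has count
   >= `min_minor_count` (2) and frequency >= `min_minor_freq` (0.01). Both
   thresholds are configurable and logged; they are repository definitions,
   chosen so that a single miscalled read can never create a SNP.
4. **Association.** Replicate counts are summed within group and the 2 x n
   group-by-allele table is tested with the Pearson chi-square (no
   continuity correction, no pseudocounts; all-zero allele columns are
   dropped and the degrees of freedom reduced accordingly). The score is
   −log10(p), capped at 320 when p underflows (the cap is flagged).
   Benjamini–Hochberg step-up control is applied per chromosome at
   alpha = 0.01; ties are handled by flagging every site with p at or below
   the step-up threshold.
5. **Sweep diagnostics.** At every FDR-passing SNP the expected
   heterozygosity H = 1 − Σ p_i² is computed per group from the
   replicate-summed counts, and the per-chromosome vector of differences
   Het(alive) − Het(dead) is tested against zero with a one-sample t test
   (two-sided p, 95% CI from the t distribution). A chromosome is flagged
   as swept when the mean difference is negative and p < 0.05 — a recent
   sweep in the survivors depresses their diversity around the selected
   locus. `region_profile` extracts the per-SNP profile around a focal gene
   with a default flank of 1.4 Mb.
6. **Annotation.** SNPs are classified against gene models
   (5'UTR / CDS / intron / 3'UTR / ncRNA / intergenic; introns are derived
   as gaps between exons of the canonical transcript, the one with the
   longest CDS). Coding effects use the standard genetic code on the most
   frequent alternate allele; residue numbering is local to the supplied
   CDS. Overlapping genes yield one annotation per gene with a warning.
7. **Category enrichment.** For a gene-category tag set (default the detox
   families CYP/CCE/GST/Redox), the per-chromosome 2 x 2 of polymorphic vs
   non-polymorphic analysed sites inside vs outside tagged genes is tested
   with Fisher's exact test (min-likelihood two-sided convention, exact for
   arbitrarily large margins). The denominators are all filter-passing
   sites, monomorphic ones included — inferred from the structure of the
   proportions this analysis reports.
8. **Pool-vs-genotype validation.** Individual genotypes (RR/RS/SS) at a
   focal locus give per-pool allele counts (2·RR + RS out of 2n); each
   pairwise comparison against the pooled read counts reports a Fisher
   exact p and a Pearson chi-square p, with concordance declared when both
   are >= 0.05. Library-side counts enter as raw read counts, which can
   exceed the 50 chromosomes actually pooled and therefore overstates the
   comparison's power; this caveat is deliberate, because read counts are
   what the data provide.

## The replicate-filter threshold

`heterogeneity_alpha` defaults to 1e-6, not 0.05. The filter's purpose is
to remove gross library artifacts (mapping errors, contamination, index
swaps), not to run a calibrated hypothesis test at every site: at a raw
per-site 0.05, five percent of perfectly concordant polymorphic sites are
discarded by construction, and because two replicate pools of 25 females
genuinely differ in allele frequency (sampling 50 chromosomes each), the
read-level chi-square is overdispersed by a factor of roughly
1 + 0.016·depth, so the filter would remove 15–50% of real polymorphic
signal — including the causal locus in a substantial fraction of
experiments. A genome-scale threshold keeps the artifact-removal intent
while leaving genuine polymorphism intact. The parameter remains exposed,
and the calibration of the underlying statistic is verified at alpha = 0.05
under a technical-replicate null.

## Error control and pool-sampling overdispersion

The association chi-square models read counts as independent draws from
the group allele frequency. Reads, however, sample the 100 chromosomes of
the two 25-female pools, which themselves sample the population: the
between-group frequency variance is p(1−p)(1/D_R + 1/D_S) from reads plus
roughly 2·p(1−p)/100 from pool composition. At the default depth the
statistic is therefore inflated about two-fold under the null, and the
per-chromosome BH procedure — whose guarantee assumes the nominal null
distribution and independent tests — does not control the realized false
discovery proportion in null simulations with distinct pools (measured
mean FDP ≈ 0.7 at alpha = 0.01). When the independence assumption is made
to hold exactly (both phenotype groups sequencing the same pools, so only
read noise separates them), the same machinery controls the FDR as
expected; both regimes are measured by the acceptance script
(`null_mean_fdp_distinct_pools`, `null_mean_fdp_technical_pools`). This is
a property of the published read-level method itself — which also assumes
significant SNPs are independently distributed despite linkage — and is
reproduced faithfully rather than corrected; variance-rescaling (effective
sample size) corrections exist in the pool-seq literature but are outside
this package's scope.

## The synthetic experiment

`SimulationConfig` defines a forward simulation of the whole design; the
defaults are the study conditions where those are stated and documented
choices where they are not.

* **Cohort and phenotyping.** 390 exposed females; survival under exposure
  is Bernoulli per individual given its causal genotype, with defaults
  {RR: 0.995, RS: 0.05, SS: 0.005} — strongly recessive knockdown
  protection at the discriminating dose. With a resistant-allele frequency
  of 0.6 this reproduces the observed design: a ~38/38/24 split of
  resistant/susceptible/recovered (the recovered fraction, 0.24, is drawn
  genotype-independently and excluded from pooling), survivor pools nearly
  fixed for the resistant allele (~0.95, matching individual genotyping of
  survivor pools in this kind of experiment) and knocked-down pools at
  intermediate frequency (~0.37).
* **Genome and sites.** Three 30-Mb chromosomes; 3000 sites each, 80%
  placed inside an exome-like layout of 60 single-CDS genes per chromosome
  carrying category tags (detox families, neuro, cuticle, other). 6.4% of
  sites are population-polymorphic (minor frequencies uniform on
  0.05–0.5), with a 1.5x polymorphism multiplier in detox-tagged genes.
  The causal site sits at the centre of a neuro-tagged gene in the middle
  of chromosome 3 (a neural target-site gene, by analogy with the
  voltage-gated sodium channel).
* **Sweep structure.** 95% of resistant haplotypes descend from one major
  founder lineage (`founder_fidelity`); within `linked_block_size` (4.2 Mb)
  of the causal site, lineage haplotypes carry the founder's alleles unless
  a per-site recombination event — probability d/L, proportional to
  distance — has switched them back to the population background. This
  yields group allele-frequency divergence that decays with distance and is
  strictly below the causal site's (the remaining 5% of resistant
  haplotypes carry no lineage markers), so the causal SNP is identifiable
  in principle. Markers are detectable to roughly half the block scale,
  i.e. ~2 Mb, comparable to the 1.4-Mb scale over which such sweeps have
  been profiled.
* **Sequencing.** Per site and library, depth is negative binomial
  (mean 60, dispersion 60, i.e. mild overdispersion); read alleles are
  binomial in the pool's chromosome frequency; each read is miscalled to a
  uniformly chosen different base with probability 0.002. Counts always
  sum to the drawn depth.
* **Reproducibility.** One seed drives named substreams (sites, haplotypes,
  phenotype, pools, sequencing), so identical config + seed give
  bit-identical output and stages are individually reproducible.

The generator's operating characteristics were calibrated forward against
the recovery targets the package is tested on (causal site top-ranked on
its chromosome in >= 95% of experiments; sweep flags correct in >= 90%)
and then validated on a disjoint seed range. Two structural constraints
drove the calibration: near-perfectly linked markers tie the causal site
in rank (hence founder fidelity < 1), and pool-sampling overdispersion
creates false FDR discoveries whose heterozygosity differences dilute and
occasionally flip the chromosome-level sweep test (hence a depth model
that keeps read noise comparable to pool genetic noise).

What the generator does **not** emulate: coalescent-accurate demography,
multi-generation selection, capture-probe GC bias, mapping artifacts,
overlapping genes, multi-isoform transcripts and indel/N read calls.
Passing recovery tests therefore show that the pipeline's statistics
recover signal under the model's assumptions, not that they would be
well-calibrated on arbitrary real data — the overdispersion section above
is the clearest instance of that distinction.

## Numerical choices

* Chi-square p-values come from the chi-square survival function; df = 0
  (monomorphic after column dropping) returns p = 1.
* −log10(p) is capped at 320 and flagged when p underflows double
  precision.
* BH with all p = 1 yields zero discoveries and an undefined threshold;
  an empty chromosome yields m = 0 without error.
* The sweep t test returns p = 0 for zero variance with nonzero mean, and
  (t = 0, p = 1) when all differences are exactly zero; chromosomes with
  fewer than two usable SNPs are reported with NaN statistics and no sweep
  flag.
* Heterozygosity frequencies must sum to 1 within 1e-9 (they are computed
  from integer counts, so this only rejects caller errors).
* Fisher's exact test is evaluated exactly for arbitrarily large margins
  (no chi-square fallback).
* All internal arithmetic uses 1-based inclusive coordinates; BED output is
  converted to 0-based half-open at the writer.

## Known limitations

* Read counts are treated as independent samples of the group frequency;
  no effective-sample-size correction is applied (see the error-control
  section).
* Multi-transcript genes are collapsed to the longest-CDS transcript;
  residue numbering is local to that CDS, not to any cross-species
  convention.
* The validation module compares allele counts, not genotype clusters; it
  does not model genotyping error.
* Sync-format N and deletion columns are read but ignored.
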