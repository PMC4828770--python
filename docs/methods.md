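# Methods

This note documents the statistical procedures `radmix` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and filtering

The pipeline's common currency is a loci × individuals matrix of unphased
diploid calls.  Allele "order" within a call is the storage order of the
input file (VCF GT order, TSV column order); it carries no phase
information but is deterministic for a fixed file, which the two-run test
scheme relies on.  MISSING is a first-class value and is never imputed.
Each SNP site is treated as an independent locus row (an optional
one-SNP-per-RAD-locus reduction keeps the first site per locus id);
multi-allelic records are retained on input, flagged, and removed by the
analysis filter.

All statistics run on the **complete biallelic matrix**: exactly those loci
with two observed alleles and no missing call in any individual.  This
mirrors standard practice for small-sample RAD datasets, where per-locus
sample-size variation would otherwise confound every comparison across
individuals.  The filter is idempotent and order-preserving.

## Individual-based ABBA/BABA tests

At a site with exactly two alleles among four single-allele sequences
(h1..h4 for P1, P2, P3, outgroup), the pattern is ABBA iff
h1 = h4 ≠ h2 = h3 and BABA iff h2 = h4 ≠ h1 = h3; D =
(nABBA − nBABA)/(nABBA + nBABA), undefined when no informative site exists
(such tests are excluded from averages, with the count logged).

Heterozygous sites are never discarded.  Each combination of reference
individuals is run twice under the default *paired* scheme: run 1 takes
the first-stored allele of all four individuals, run 2 the second.  The
pairing between runs is arbitrary (genotypes are unphased) but fixed, and
the per-individual mean over all tests is insensitive to it; an exhaustive
16-assignment scheme (`allele_scheme="all_haplotypes"`) is available for
checking that insensitivity.  Under the paired scheme each P2 individual
accumulates N1·N3·NO·2 tests.

Controls: every P1 member is also run as P2 (expected D ≈ 0; its own
leave-one-out removal keeps it out of the P1 pool) and every P3 member
likewise (maximal gene flow).  The admixture fraction of individual i is
f_i = S̄_i / S̄_max with S = nABBA − nBABA, where S̄_max pools all
maximal-control tests rather than matching reference combinations; the
pooled form is simpler, and because every control individual contributes
the same number of tests the control-taxon mean f is exactly 100 %.
Taxon summaries weight member individuals equally.

## Reference-sample bias

For each reference role (P1, P3, outgroup) the per-individual mean D over
all candidate tests is compared with the grand mean; test-count-weighted
deviations sum to zero by construction, and |deviation| > 0.1 flags an
outlier.  A one-way ANOVA (Kruskal–Wallis optional) tests for a global
effect of individual identity.  These p-values are **descriptive only**:
tests sharing loci and co-references are strongly dependent, and an
individual's realized genotype genuinely shifts D even when individuals
are exchangeable draws from one population, so small p-values appear even
in null simulations.  The deviation magnitudes are the robust readout: in
null simulations at study scale (2000 loci, samples 8/12/12/3), the
largest |deviation| stayed below the 0.1 threshold in every replicate,
while a P1 individual carrying a 30 % donor mosaic produces a deviation
several times larger than any other — negative, because donor material in
P1 inflates BABA in the tests it anchors.

## Population-frequency D and bootstrap

D is also computed from per-population derived-allele frequencies:
numerator Σ[(1−p̂1)p̂2p̂3(1−p̂4) − p̂1(1−p̂2)p̂3(1−p̂4)], denominator the
same with "+".  The derived allele is the least frequent allele among
outgroup gene copies; an exact 0.5 tie falls back to the global minor
allele, then lexicographic label order, so polarization is fully
deterministic.  When every group holds one haploid-like sequence this
reduces exactly to the individual-based D — a cross-check the test suite
exercises on random instances.

Significance uses 100 bootstrap replicates redrawing each locus ×
population derived-allele count from Binomial(n = gene copies sampled,
p = observed frequency); the replicate min–max range is reported and
"significant" means it excludes zero.  This resampling captures
genotype-sampling noise only, not the locus-level drift/ILS noise that
also moves the point estimate, so at zero gene flow individual ranges
cover zero only ~60 % of the time (both noise scales shrink as 1/√L, so
more loci do not change this).  The range should be read as a
reproducibility band for the given frequencies, not a confidence interval
against drift.

## Hybrid triangle

Diagnostic loci are those where each parental sample is monomorphic, for
different alleles ("fixed in the sample"; a `max_minor_freq` relaxation
exists but defaults to 0).  q is the fraction of the 2L panel gene copies
of donor (parent-B) type, Q12 the fraction of panel loci heterozygous
A-type/B-type.  Bounds: Q12 ≤ 2·min(q, 1−q) always (equality when one
parent of the individual is a pure parental), and Q12 = 2q(1−q) under
random mating.  Parental individuals may be profiled and land at the
triangle corners.

## Diversity and Fst

Per group: K = mean observed alleles per locus; AR = hypergeometric
rarefaction to a common number of gene copies (default 2 × smallest group
size, the natural depth when one group has very few samples); Priv =
(locus, allele) pairs observed in exactly one group; Ho = mean fraction of
heterozygous individuals; He = unbiased expected heterozygosity
2p(1−p)·2n/(2n−1).  Per-locus SDs accompany the means.

Fst is the Weir & Cockerham (1984) θ: per-locus variance components
a, b, c combined multilocus as Σa / Σ(a+b+c).  Undifferentiated groups
give small, typically slightly negative estimates (the estimator is
unbiased around zero); a monomorphic pair yields NaN with a warning.
Permutation p-values shuffle whole individuals between the two groups
(both alleles move together); p = fraction of permuted datasets with
θ ≥ observed, deterministic for a fixed seed (default 1000 permutations).
θ is the standard diploid single-level estimator; AMOVA-style variants
agree closely for this design but are not reproduced digit-for-digit.

## Synthetic data generator

Each locus starts from an ancestral derived frequency drawn from
Beta(0.5, 0.5) (U-shaped, mimicking a SNP ascertainment toward common
variants at the root).  Every branch of (((P1, H), P3), O) applies
Balding–Nichols drift, Beta(p(1−c)/c, (1−p)(1−c)/c), with per-branch
intensity c.  Defaults (c_p1 = c_hybrid = 0.2, c_split = 0.5, c_p3 = 0.65,
c_ingroup = 0.3, c_outgroup = 0.65; sample sizes 8/12/12/3; 977 loci) were calibrated once so the simulated
Weir–Cockerham Fst lands where the emulated study design sits — ~0.2
between the hybrid and its sister, 0.6–0.75 for anything involving the
donor or outgroup — making simulated D, f and Fst magnitudes directly
interpretable on that scale.  Loci monomorphic across all sampled
individuals are redrawn until exactly n_loci polymorphic, complete loci
exist, so generator output always passes the analysis filter unchanged.

*Frequency mode* applies the pulse to population frequencies
(p_H = (1−f)·p_sister + f·p_P3, optionally followed by binomial
Wright–Fisher generations at size `ne`) and draws genotypes binomially —
the right tool for population-level expectations such as the zero-flow
control.  *Mosaic mode* builds explicit hybrid individuals whose gene
copies are per-locus copies from the P1 or P3 **sample** haplotype pools:
a founder generation with exactly round(f·2N) donor haplotypes (paired so
f = 0.5 with no mating gives pure F1s), then `n_generations` rounds of
random mating with free recombination in a 100-individual breeding pool.
The truth object records every sampled gene copy's source, which makes
hybrid-index recovery exact at diagnostic loci and lets f-recovery tests
compare against the realized (not just nominal) admixture fraction — with
few sampled hybrids the realized fraction wobbles binomially around f.

What the generator does **not** emulate: linkage between sites of one RAD
locus (all sites independent), missing data and genotyping error (output
is complete by construction), allele dropout/paralogy, selection, and
continuous migration (admixture is a single pulse).  Passing tests
therefore validate the statistical machinery under ILS plus pulse
admixture, not robustness to those artefacts — on real data the
complete-matrix filter and upstream SNP-calling quality carry that weight.

## Numerical and reproducibility choices

- Every stochastic operation takes an explicit seed; the pipeline derives
  per-stage seeds from one master seed via numpy `SeedSequence` spawn keys
  and records them in the run metadata.  Fixed seeds give byte-identical
  outputs, including simulator files.
- NaN D tests (no informative sites) are excluded from means with a
  logged count; a zero bootstrap denominator or a monomorphic Fst pair
  yields NaN plus a warning rather than an error.
- Derived-allele ties and haplotype pairing are broken deterministically
  (see above); no operation depends on dict iteration order.
- Test-suite problem sizes: most module tests run at 300–1500 loci with
  the default or reduced sample sizes; the zero-control and f-recovery
  checks use 2000 loci × 5 seeds, the scale at which the estimator's
  ±0.05 recovery tolerance is comfortably met.

## Known limitations

- f is a ratio of means of site-count differences; with very few
  informative sites it is noisy and can be slightly negative at f = 0.
- The binomial bootstrap understates total uncertainty (see above).
- Bias-analysis p-values are descriptive, not calibrated.
- Exact reproduction of third-party implementations (Arlequin AMOVA Fst,
  FSTAT rarefaction depth) is not attempted; the estimators implemented
  are the standard literature forms stated here.
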