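# Methods

`adaptscan` re-implements, as a tested library, a family of analyses used
to study recent adaptation and fine-scale ancestry structure in human
population clusters: variant curation and polarization, haplotype-based
positive-selection scans (DIND, nSL), a composite-likelihood
balancing-selection scan, outgroup-f3 shared-drift contrasts with block
jackknife, Hudson Fst with permutation significance, and gene-subnetwork
enrichment of selection scores with cross-population filtering.  Because
the genomic datasets such studies rest on are not redistributable at desk
scale, every analysis is exercised against a built-in forward
Wright-Fisher simulator that produces fully ground-truthed phased panels.

## The simulator and its rescaling

The generator is a discrete-generation diploid Wright-Fisher model:
each offspring draws two parents (fitness-weighted under selection), each
transmitted gamete receives Poisson(r·L) crossovers at uniform positions
and Poisson(mu·L) new mutations under the infinite-sites model (integer
positions, collisions re-drawn).  Configurations are written in natural
units — mutation rate 1.25e-8 per bp per generation, human-like diploid
sizes of ~10,000, a recent two-way split (default 310 generations, ~9 ky at
29 y/generation) with an outer reference split several-fold older — plus an
explicit rescaling factor `scale` (default 100).  The engine runs with
N/scale individuals, mu·scale, r·scale, s·scale, m·scale and
generations/scale, preserving the compound parameters (4Nmu, 4Nr, 2Ns,
4Nm, T/N) the statistics respond to.  Burn-in is 10·N' generations before
the split clock starts.

Two features deserve emphasis:

* **Recent growth.** By default every population expands 10-fold from 300
  generations before present.  Without it a rescaled population of 100
  individuals genuinely contains many second- and third-degree relatives,
  which is demographically unrealistic and makes IBD-based sample exclusion
  meaningless.
* **Selection.** "sweep" events are additive (fitnesses 1, 1+s/2, 1+s)
  seeded as a single copy at their start generation, re-seeded up to a
  retry cap if lost (a fixed sweep counts as a success, not a loss).
  "balanced" events are overdominant with homozygote fitnesses calibrated
  so the deterministic equilibrium equals the configured frequency; they
  are seeded *at* that equilibrium frequency, modelling an established
  balanced polymorphism (a single copy would usually drift out before
  overdominance could hold it).  For balanced events `s·scale` must stay
  below 1/max(f, 1−f) so fitnesses remain positive; the calibration
  recorded in the tests uses s·scale = 1 at f = 0.5.

The emitted panel contains every site carrying a derived allele among the
sampled haplotypes, including sites fixed derived in the sample (a caller
reports those against an ancestral-like reference).  Ancestral alleles are
known by construction; a configurable fraction of sites can be emitted
unpolarized.  Nucleotides are assigned with a transition bias giving a
Ts/Tv ratio of ~2.07, and a configurable fraction of sites (default 25%)
has the reference carrying the derived allele, so polarization is
non-trivial.  The outgroup generator substitutes each ancestral allele with
probability 1−exp(−mu·t/g) on the outgroup lineage (6 My at 29 y per
generation by default, in natural units — the product mu·t/g is
scale-free) and emits additional monomorphic-in-panel substitution sites at
the same rate for the balancing scan's substitution class.

What the generator does *not* emulate: genotyping error, phasing
switch errors, background selection, gene conversion, mutation-rate
heterogeneity, realistic gene structure, or multiple chromosomes.  Passing
tests therefore demonstrate correctness of the statistics and their
implementation under a clean neutral-plus-selection coalescent-consistent
model, not robustness to real-data artefacts.

## Variant and sample curation

The QC stage mirrors standard WGS curation: sites with more than 5%
missing haplotypes are dropped (boundary retained), strand-ambiguous
A/T and C/G substitutions removed, and Hardy-Weinberg outliers removed at
a Bonferroni threshold of alpha divided by the number of polymorphic sites
actually tested.  The HWE test is the exact conditional test: all
heterozygote counts compatible with the observed allele counts are
enumerated with exact integer weights n!/(nAA!·nAa!·naa!)·2^nAa, and the
p-value is the summed probability of configurations no more probable than
the observed one ("prob" aggregation).  Integer arithmetic makes the
≤-comparison tie-exact.

Relatedness uses the method-of-moments IBD decomposition from
identity-by-state counts (PI-HAT = P(IBD=1)/2 + P(IBD=2)).  Two deliberate
choices: the IBS-class expectations conditional on IBD state are computed
with *without-replacement* (hypergeometric) draws from the sample allele
pool, and negative moment estimates are *not* clamped to zero — both
choices keep the estimator unbiased at desk-scale site counts (clamping
alone inflates PI-HAT by ~0.05 on a few hundred sites).  Relatedness is
estimated within populations on LD-pruned sites; pooling structured
populations would flag unrelated pairs.  On a single short chromosome the
estimator's sampling SD is ~0.2 (the chromosome is effectively one linked
genealogy), so the *pipeline* default threshold is 0.45 — a duplicate /
first-degree guard — while the library operation keeps the genome-wide
convention of 0.125 as its default.

LD pruning is greedy over sliding windows of 50 SNVs advancing by 5:
within a window, any pair of genotype-dosage vectors with r² > 0.2 loses
its later member; passes repeat until a brute-force window audit finds no
offending retained pair.

Polarization is conservative: a site's ancestral state is assigned only
when every outgroup allele agrees and matches ref or alt; any conflict,
gap or third allele leaves the site unpolarized and excluded from
derived-allele-frequency (DAF) machinery.  DAF filtering removes sites
strictly below 0.2 (so DAF = 0.2 is retained).

## Selection statistics

**DIND** at a focal polarized SNV is iπA/iπD: the mean pairwise count of
differences among ancestral-carrying versus derived-carrying haplotypes
over the nearest `window_snvs` polymorphic sites on each side (default 50
per side, the focal site excluded; the window size is a package choice).
Both classes must have at least two haplotypes.  A derived class with zero
diversity gives +infinity, capped at the largest finite score of the scan
(rank-preserving) and flagged; a zero ratio is floored symmetrically.

**nSL** is ln(SL_A/SL_D), where SL_C averages, over haplotype pairs within
allele class C, the length in consecutive polymorphic sites of the maximal
identity run containing the focal site, truncated at 4500 sites per side
("per side" is our reading of the truncation window; a flag exposes it).
Long shared derived haplotypes push nSL negative.  The scan implementation
accumulates per-pair run lengths into per-site class sums in one pass;
an O(n²·L) brute-force oracle pins both statistics exactly in the tests.

**Standardization.** Raw DIND (log-transformed) and nSL scores are
z-scored within DAF bins of width 0.025 (lower-closed), bins with fewer
than 20 sites merged with their nearest neighbour.  On a short synthetic
chromosome a sweep can *fill its own frequency bin* and normalize itself
away; for this regime the library also provides
`reference_standardize`, which takes bin means and SDs from a reference
score distribution (other populations, or neutral replicates).  The
pipeline's network stage uses the reference route, calibrating each
population's scores against the pooled raw scores of the other scanned
populations.

**Balancing selection.** Sites are classified against the outgroup:
polymorphic in the population, substitution (monomorphic and differing
from the outgroup), or excluded (monomorphic and matching — uninformative).
The composite-likelihood statistic contrasts, over the 100 nearest
informative sites on each side of the focal position, the model
P(polymorphic at genetic distance d) = w(d)·alpha + (1−w(d))·p0 with
w(d) = exp(−d/delta), maximized over alpha in {p0 + k(1−p0)/10, k=0..9}
and delta in {1e-5, 1e-4, 1e-3} Morgans, against the background P = p0.
T = 2(max ℓ1 − ℓ0) is non-negative by grid nesting.  The kernel form and
grids are this package's own explicit model of the
polymorphism/substitution contrast; the tests calibrate its null on
i.i.d. Bernoulli(p0) tables and verify grid maximization against a dense
independent implementation.

## f-statistics

Outgroup f3(O; A, B) averages (o−a)(o−b) − o(1−o)/(n_o−1) over sites; the
correction term removes the sampling bias of the population appearing
twice, so the statistic has expectation zero when O, A and B are samples
of one panmictic population (verified by simulation).  Standard errors
come from a weighted delete-one block jackknife over contiguous position
blocks (default 5 Mb; a block-count option serves short chromosomes).
The two-cluster residual contrast differences per-group f3 scores of the
two focal clusters and classifies each group against the empirical mean
and SD of the residuals at 1 and 2 SD (strictly greater; 2 SD counts as
significant).

Fst is the Hudson ratio-of-sums estimator; significance permutes
individuals' population labels (p = (1 + #{perm ≥ obs})/(n_perm + 1)),
which is exact under label exchangeability regardless of LD.

## Network enrichment

Each gene's representative score is the maximum standardized score among
sites within the gene body ± 50 kb (inclusive boundary; genes with no site
are unscored and removed from graphs, never zero-scored).  A connected
subnetwork of k genes scores sum(z)/sqrt(k).  The best subnetwork per
pathway is found by simulated annealing over connected sets of size 3-15
(add / remove non-articulation / swap moves, candidates rejection-sampled;
geometric cooling, several restarts); an exhaustive enumeration oracle on
small graphs anchors the search in the tests.

Significance has two routes.  `null_distribution` + `significance` follow
the descriptive construction — per-size scores of randomly grown connected
subgraphs under permuted gene scores — which is useful background but
anti-conservative when the observed value is a search *maximum*.  The
calibrated route, `pathway_significance`, applies the identical search to
n_perm permutations of the pathway's gene scores and ranks the observed
best among the permuted bests; under no signal the p-value is
exchangeable-uniform, which the tests verify.  The pipeline uses the
calibrated route, after a rank-inverse-normal transform of gene scores
(bounding any single outlier gene's leverage so the test responds to
connected groups of high scores rather than to lone extremes).  No
cross-pathway multiple-testing correction is applied by default, matching
the raw p < 0.05 reporting convention; a Benjamini-Hochberg helper is
available.

Cross-population filtering removes a significant target subnetwork when
any reference population has a significant subnetwork in the same pathway
with gene-set Jaccard ≥ 0.5 (boundary inclusive); granularity and
threshold are configurable.

## Pipeline

`run_pipeline` executes simulate → QC → scans → f-statistics → networks →
shared-signal filter from a single config.  All randomness derives from
the master seed via SHA-256 of "master:stage", so adding a stage never
perturbs earlier stages and a config+seed pair reproduces the bundle
exactly.  Desk-scale adaptations relative to genome-wide conventions
(kinship guard 0.45, gene flank 5 kb on a sub-megabase chromosome,
reference-calibrated network scores, 4-6-gene subnetwork sizes over
16-20-gene pathways) are defaults of the pipeline config only; each
library operation keeps the field-standard default and every value is a
flag.

## Problem sizes used by the test-suite and acceptance script

Simulated panels use L between 100 kb and 600 kb, scaled population sizes
of 50-100 diploids, and 15-20 sampled diploids per population; replicate
counts follow the property being tested (typically 20 per condition).
These sizes were chosen so the full statistical battery represents each
regime (neutral drift, hard sweep, overdominance, two-cluster contrast)
while each experiment stays at minutes of CPU.  Power properties at this
scale are genuinely harder than at genome scale — a single sweep's
footprint can cover a third of the chromosome, and frequency-bin nulls
carry hundreds rather than millions of sites — and the recorded power
numbers should be read with that in mind.

## Known limitations

* Single-chromosome panels make genome-wide conventions (kinship 0.125,
  ±50 kb gene windows, within-population DAF-bin standardization) behave
  poorly; the pipeline's desk-scale defaults compensate but are not the
  values one would use on real genome-wide data.
* The balancing-selection model is a deliberately explicit, simple kernel
  model; it is not a reconstruction of any published pipeline's internals.
* The subnetwork search's proposal distribution is not uniform over
  connected sets; correctness claims rest on the exhaustive oracle and the
  matched-permutation significance, not on sampler uniformity.
* Forward simulation with rescaling preserves compound parameters but not
  every observable (e.g. absolute allele ages); statistics that depend on
  the ratio of selection to recombination time-scales are compared only
  across matched rescaled conditions.
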