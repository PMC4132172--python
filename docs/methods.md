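# Methods

`ivypop` reimplements, as a tested pipeline, the multilocus population-genetic
analysis used to characterize North American *Ipomoea hederacea* — a weedy,
highly selfing annual vine with a single-locus leaf-shape polymorphism
(lobed `LL`, heterozygote `Ll`, entire `ll`) that clines with latitude. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data can and cannot establish.

## Input model

The pipeline consumes per-locus *phased* haplotype alignments (exactly two
rows per diploid, header convention `>IND|hapN`), a population table
(individual, population, latitude/longitude, leaf genotype), and a minimal
CDS annotation (BED-like intervals plus reading frame). Phasing is an input
contract; statistical phasing is out of scope. All coordinates are 0-based,
half-open.

Columns with gaps or IUPAC ambiguity codes are classified `excluded` and
enter no statistic; the source chromatographs were hand-edited to clean
calls and no gap model is described, so exclusion is a policy choice, not
an inference of intent. Multiallelic columns are likewise excluded
everywhere by default (a flag on the site summary admits them to the
segregating-site count) so that the SNP matrix and the diversity
denominators stay internally consistent.

**Silent sites.** Diversity is reported per *silent* site: noncoding
columns count 1 toward the denominator; CDS columns count their mean
fractional degeneracy across observed haplotype codons (Nei–Gojobori-style
counting: the fraction of the three possible point mutations at that codon
position that are synonymous). A segregating CDS column is labelled
synonymous only when every observed change preserves the amino acid in
every observed codon context. CDS columns falling in incomplete terminal
codons cannot be scored and are excluded.

## Diversity and neutrality statistics

* Watterson's estimator: `theta_W = S / (a1 * L_silent)`,
  `a1 = sum_{i<n} 1/i`.
* Pairwise diversity: mean silent differences over all C(n,2) haplotype
  pairs divided by `L_silent`; with missing data each column uses
  pairwise-complete denominators (the DnaSP-compatible choice).
* Multilocus "total" values pool sites and haplotypes across loci
  (equivalent to the silent-length-weighted average of per-locus values);
  per-population report rows use the same pooling within a population.
* Tajima's D uses the 1989 variance constants; D is *undefined* (NA, and
  excluded from averages) when S = 0 rather than set to 0.
* Fu's Fs evaluates `S' = P(K >= k_obs)` under the Ewens sampling formula
  with `theta-hat = pi_total` (the Fu 1997 / DnaSP convention), computed in
  log space from unsigned Stirling numbers of the first kind;
  `Fs = ln(S'/(1-S'))`, with an infinity sentinel when `k_obs = 1`.
* R2 contrasts per-sequence singleton counts with `pi/2`. All statistics
  are folded (no outgroup): a singleton is an allele seen exactly once.

**Null distributions.** Significance uses coalescent simulation conditioned
on the observed number of segregating sites: a neutral genealogy is drawn,
exactly S mutations are placed on branches with probability proportional to
branch length, and empirical tail probabilities use the add-one correction
`(r+1)/(reps+1)`, with ties counted toward both tails. Conditioning on
theta-hat instead is available but fixed-S is the default. Note that under
fixed-S conditioning E[D] is mildly negative (about −0.1 at n = 20,
S = 17; confirmed against an independent msprime-based oracle) — p-values
remain exactly uniform because observed data are compared against the same
conditional distribution.

**Multilocus D test.** The cross-locus mean of D is compared against means
of per-locus re-draws from each locus's own fixed-S null. A literal
shuffle of locus labels cannot change a cross-locus mean, so the coalescent
re-draw (the HKA program's randomization) is the operative null; this
interpretation is a documented decision, not an inference.

## Coalescent engine

Time is scaled in units of 2N generations and `theta = 4*N*mu`, so with k
lineages the within-deme coalescence rate is C(k,2)/size and E[S] =
`theta * a1(n)` at constant size. The engine supports: island and
stepping-stone migration (per-lineage total migration rate m/2 at scaled
rate 4Nm, split over destination demes), exponential growth by
time-rescaling of the coalescence intensity (`rate ∝ exp(alpha*t)`
backward in time), an arbitrary migration matrix (used by the
two-cluster scenario), and metapopulation extinction–recolonization (at
rate e per deme all resident lineages descend from at most `n_founders`
propagule founders drawn from one random source deme). The engine is
validated against closed forms (E[T2], E[L], E[S]) and against msprime as
an independent simulator on matching scales.

**Selfing.** Selfing enters at diploidization: with probability
`F = s/(2-s)` an individual is autozygous and carries one pool haplotype
duplicated; otherwise two distinct pool haplotypes. This reproduces the
heterozygosity structure (realized FIS → F) that every downstream analysis
consumes, without modelling selfing inside the genealogy; the
within-genealogy effective-size reduction 1/(1+F) is exposed as an optional
flag (`scale_by_selfing`) and off by default. Autozygosity is drawn
independently per locus — correct marginally for unlinked loci, though it
ignores the genome-wide identity correlation real selfers show.

## F-statistics, AMOVA, and distances

Per-SNP Weir & Cockerham (1984) variance components a (among populations),
b (among individuals within), c (within individuals) are summed across
SNPs: `FST = a/(a+b+c)`, `FIS = b/(b+c)`, `FIT = (a+b)/(a+b+c)` — the FIT
identity holds algebraically. One estimator family is used everywhere
(global, pairwise, per-SNP, leaf locus) for internal consistency, rather
than mixing GenAlEx/Arlequin variants. The AMOVA report truncates negative
summed components to zero before forming percentages (Excoffier
convention); F-statistics themselves are reported untruncated, so per-SNP
estimates may be slightly negative at no differentiation. Permutation
significance: individuals among populations for FST; allele copies
re-paired among individuals within populations for FIS (the permutation
unit is a documented choice — the original software does not specify its
unit).

Selfing rate from inbreeding: `SR = 2*FIS/(1+FIS) * 100`; negative FIS is
clamped to zero with a warning.

Distances: Nei (1972) standard distance over SNP allele frequencies
(mean J statistics across loci; +infinity when no alleles are shared);
pairwise multilocus W&C FST; linearized FST/(1−FST); great-circle
(haversine) geographic distance with Earth radius 6371 km on population
centroids (the range spans ~15 degrees of latitude, so a planar
approximation is not used). Isolation-by-distance uses Mantel tests —
Pearson correlation of lower triangles under joint row/column permutation,
one-tailed upper by default (9,999 permutations), cross-checked against
scikit-bio in the tests.

LD is the squared correlation of dosage vectors (composite r²), which
converges to gametic r² under strong inbreeding and needs no phase
assumption; significance uses `n*r² ~ chi2(1)`. The FST outlier contrast
removes SNPs in significant LD with *any* other SNP and recomputes the
distribution, leaving the original intact; the focal-locus percentile is
the fraction of background values strictly below it.

## Admixture clustering with inbreeding

A deliberately simplified relative of InStruct's model (by design):
per-individual admixture `q_i` (Dirichlet(1), alpha fixed rather than
inferred), per-individual inbreeding `f_i` (uniform prior), cluster allele
frequencies Beta(1,1). At each SNP, with probability `f_i` the two allele
copies are one draw from a single cluster sampled from `q_i` (autozygous —
heterozygosity impossible); otherwise two independent copies with
independent cluster origins. All updates are conjugate Gibbs draws; with
the autozygosity-indicator augmentation the `f_i` posterior is Beta, so no
Metropolis step is needed. With `f = 0` the likelihood reduces exactly to
the standard admixture model (asserted in tests). Multiple chains get a
Gelman–Rubin check on the log-likelihood trace (flagged > 1.2); the chain
with the best mean posterior log-likelihood is kept. Default chain
settings are desk-scale (20,000 iterations, 2,000 burn-in) rather than the
million-iteration production runs the original analysis used.

Model choice uses `DIC = D-bar + pD` with the posterior-mean plug-in
deviance, plus a parsimony report (smallest K within 2 DIC units of the
minimum). A known limitation, visible in our simulations and mirroring
the behavior reported for the original tool (DIC-optimal K of 14 while two
clusters carry the structure): plug-in DIC under-penalizes mixture
complexity, so on truly unstructured data it tends to prefer K = 2 over
K = 1. On genuinely structured data it selects the true K cleanly; the
parsimony report exists precisely because the argmin should not be read
literally. PCoA (Gower double-centering + eigendecomposition, via
scikit-bio) is the model-free cross-check.

## Leaf-shape genotype inference

Maternal genotypes are the maximum-likelihood call from selfed-progeny
multinomials — `LL → (1,0,0)`, `Ll → (1/4,1/2,1/4)`, `ll → (0,0,1)` over
(lobed, het, entire) — with ties broken toward `Ll`, the only genotype
consistent with mixed classes. The default assumes pure selfing; an
outcrossing-aware likelihood (pollen L frequency as a nuisance parameter)
is provided but off by default because no pollen-pool model is given for
the original arrays. Misclassification under pure selfing requires an
all-one-class array from an `Ll` mother (probability ≈ 2·(1/4)^10 per
array), so recovery exceeds 99% by construction; the all-heterozygote
array still calls `Ll` correctly.

## Synthetic data

The generator reproduces the sampling design as its defaults: 24
populations × 8 maternal lines (192 diploids), seven loci of 500–800 bp,
selfing rate 0.92, half the populations on each side of a configured
clinal boundary (36°N by default), longitude correlated with latitude
along the range axis, a leaf-shape locus whose lobed-allele frequency
follows a logistic cline (0.9 north, 0.1 south) with inbreeding-adjusted
genotype frequencies, and ten selfed progeny per line. Scenarios:
panmictic, island, stepping-stone (demes ordered by latitude),
two-cluster-patchy (two ancestral clusters assigned to populations
independently of geography), expansion, metapopulation. Mutations are
realized as single transitions from a random ancestral sequence (infinite
sites preserved; no recurrent mutation, indels, or sequencing error).

The *study-system preset* is an island-model configuration calibrated (runs
recorded in `scripts/calibrate_preset.py`) so that median pipeline outputs
land near the study's anchors: per-site theta 4e-5 and migration 4Nm = 5
give pooled silent theta-pi ≈ 1.2e-3, multilocus FST ≈ 0.15, FIS ≈ 0.85
(from s = 0.92 via F = s/(2−s)), and a leaf locus far out in the SNP FST
tail. Note the per-deme theta is much smaller than the pooled diversity
because pooled coalescence times under 24-deme structure are ~25× the
within-deme scale. The base `ScenarioConfig` default of theta = 1e-3 per
site is the panmictic-scale parameter; under multi-deme scenarios realized
pooled diversity exceeds it accordingly.

What passing on synthetic data does *not* show: robustness to sequencing
or phasing error, recurrent mutation and indels, within-locus
recombination (loci are simulated and analyzed as non-recombining
fragments), genome-wide identity correlation between loci, or realistic
geographic sampling noise.

## Problem sizes used in the test suite

Unit tests run Monte-Carlo checks at 2,000–10,000 replicates with
tolerances set from the corresponding standard errors. The acceptance
suite uses: 10,000 replicates for the engine calibration; 2,000 trials ×
1,000-replicate nulls (cached by S) for the type-I error of the D test; 30
replicate 7-locus expansion datasets; 1,000 panmictic datasets × 99
permutations for the FST type-I error; 16 preset seeds for the
leaf-locus outlier contrast; and 10,000 simulated progeny arrays. The
pipeline's own defaults remain at production scale (9,999 permutations,
10,000 coalescent replicates) with a `fast_profile` for exploratory runs.

## Known limitations

* The coalescent engine has no within-locus recombination and no selection.
* Fu's Fs at the full pooled sample size (n = 384) relies on log-space
  Stirling sums; values around ±30 are well within range but the statistic
  saturates to ±infinity sentinels when `S'` underflows.
* The admixture sampler does not correct for label switching within a
  chain; on weakly structured data posterior-mean admixture can blur
  across modes (the DIC caveat above).
* GenAlEx-specific estimator details (its AMOVA distance coding and FIS
  permutation unit) are not replicated bit-for-bit; Weir–Cockerham is used
  uniformly instead and the choice is logged in reports.
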