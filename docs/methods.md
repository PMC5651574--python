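# Methods

## Scope and data model

The package analyses biallelic SNP-array genotypes for a handful of closely
related populations (breeds). Genotypes are B-allele dosage codes 0/1/2 with
an explicit missing mask; when no chip manifest is available the
lexicographically later allele observed at a locus is defined as B, which
makes re-encoding deterministic. Coordinates are 1-based and inclusive
throughout, matching the convention of the caprine reference annotation the
gene tables follow.

## Quality control

Five locus filters run sequentially — GenTrain cluster score, pooled-sample
MAF, per-locus missingness, unmapped probes, multi-hit probes — and each
step's removal count refers to loci that survived all earlier steps, so the
counts always sum to `initial − surviving` (enforced by the report type).
Sequential counting is the only reading under which a published per-step
removal series can reconcile exactly with its survivor total. The MAF filter
uses the pooled frequency across breeds, so per-breed rare variants survive
into the MAF spectra. Hardy-Weinberg deviation is a pooled one-df chi-square
without continuity correction, computed on survivors and reported rather
than filtered by default (`hwe_alpha` turns filtering on); at a few dozen
deviating loci in ~50 K, removal changes nothing downstream. Sample QC is a
call-rate threshold (default 0.95); studies of this kind typically drop an
animal or two without stating a criterion, so the threshold is exposed
rather than hard-coded.

## Diversity

Per-locus H_O is the heterozygote share of non-missing calls; H_E is the
gene diversity 2p(1−p), by default with Nei's small-sample factor
2n/(2n−1) (at n≈24 the correction is below the second decimal). F_IS uses
the multilocus ratio-of-means form 1 − H̄_O/H̄_E rather than a mean of
per-locus ratios, which would be dominated by near-monomorphic loci. Its CI
is a bias-corrected (BC, no acceleration) percentile bootstrap resampling
loci with replacement, 1000 replicates by default; "significant" means the
95% CI excludes 0. MAF classes are rare [0, 0.05), intermediate
[0.05, 0.10), common [0.10, 0.30) and frequent [0.30, 0.50]; the class
boundaries are half-open upward so every MAF falls in exactly one class.
The per-breed summary's "percent polymorphic" is the share of called loci
with both alleles observed in that breed — on chip data this is the
practical polymorphic-information content surrogate printed in diversity
tables.

## Differentiation

FST is Weir & Cockerham's (1984) θ for diploid two-allele data with unequal
sample sizes: per-locus variance components a (among populations), b (among
individuals within populations), c (within individuals), combined as
θ = Σa/Σ(a+b+c) over usable loci — never a mean of per-locus ratios. Loci
where any population has zero calls, or with zero total variance, are
excluded from the sums. Small negative estimates are legitimate for this
estimator and are reported as-is. Note that with identical genotype counts
in two samples θ is slightly *negative*, not zero — the finite-sample
correction in a vanishes only in special cases such as an all-heterozygote
locus.

Significance comes from a percentile bootstrap over loci (1000 replicates)
at a Bonferroni-adjusted alpha of 0.005 for the six pairwise tests among
four breeds, with a suggestive tier at 0.01. Because loci resampling tests
whether the multilocus mean differs from zero, any genuinely drifted pair
becomes significant once enough loci are typed; workflows that resample
individuals instead report wider intervals for the same θ.

One-vs-rest contrasts pool the remaining breeds into a single "population".
The pooled rest is not random-mating (a Wahlund mixture), so the estimator's
value depends on that pooling and should be read through its per-locus θ
vector — the input to outlier validation — rather than as a pure coancestry
coefficient.

## Distances, clustering, AMOVA, kinship

Nei's (1972) standard distance D = −ln(J_XY/√(J_X·J_Y)) treats an individual
as an allele-frequency profile (0, 0.5, 1 per locus); the J terms are
averaged over each pair's pairwise-complete loci, so missingness is handled
pairwise instead of by global locus deletion. Zero shared identity gives
D = +∞, which is reported distinctly and capped (2× the largest finite
distance) only for clustering. The Reynolds coancestry distance between
breeds is the least-squares moment estimator of θ under pure drift: per
locus the numerator (p̃₁−p̃₂)² − p̃₁q̃₁/(2n₁−1) − p̃₂q̃₂/(2n₂−1) is unbiased
for 2θp̄q̄ and the denominator p̃₁q̃₂ + p̃₂q̃₁ for 2p̄q̄; negative ratios are
floored at 0 and a fixed difference gives exactly 1. Manhattan distance is
the mean per-locus |dosage difference| over pairwise-complete loci, so
missingness patterns do not scale it.

Clustering is scipy's agglomerative linkage, complete by default (the
default of R's `hclust`, which such studies typically use); trees are
exported as Newick with branch lengths equal to merge-height differences.

AMOVA is the two-level Excoffier (1992) decomposition of squared distances:
SS_total = Σ_{i<j}d²_ij/N, SS_within summed per group, σ²_within =
MS_within, σ²_among = (MS_among − MS_within)/n₀. The p-value is the
permutation tail probability (1 + #{Φ* ≥ Φ})/(1 + P) under random
reassignment of individuals to groups of fixed sizes, 10,000 permutations by
default (so the smallest reportable p is ~1e-4; raise the count to resolve
smaller). Two caveats established while validating: (i) on squared
Euclidean *dosage* distances between individuals, Φ_ST = 2θ/(1+θ)
analytically, not θ — the among component is 4·Var(p_k) against a within
variance of 2pq, because a distance matrix among diploid individuals cannot
expose the within-individual gene level; (ii) on squared Nei individual
distances Φ_ST is likewise several-fold larger than pairwise θ (our
study-shaped preset gives ~6% among breeds against θ ~0.01), which is the
regime such studies report.

IBS kinship is K_ij = 1 − Σ|g_i−g_j|/(2·L_ij) over pairwise-complete loci.
On common biallelic chip markers, unrelated individuals share alleles often
by chance, so the off-diagonal sits around 0.6–0.75 rather than 0.5.

## PCA and SNP selection

PCA mirrors R's `prcomp`: per-locus mean imputation of missing dosages,
column centering, no variance scaling (scaling is available behind a flag),
thin SVD, components ordered by variance; each component's sign is fixed so
its largest-magnitude loading is positive. A SNP's contribution to a
component follows the squared-correlation chain r = loading × component SD,
cos² = r², contribution% = 100·cos²/Σcos². Since the component SD cancels
in the ratio and loading columns are unit norm, contribution% ≡
100·loading²; the code asserts this identity to 1e-9, which also makes the
chain independent of scaling choices. With M loci the uniform expectation
is 100/M % (0.0021% at M = 48,505); SNPs at or above `factor` × that
expectation (default 10×, i.e. ≥0.02% at chip scale) are selected —
inclusive comparison, no tie-breaking needed. Individual contributions are
100·score²/Σscore² per component.

Validation asks whether the selected SNPs are differentiation outliers for
each breed: for every one-vs-rest contrast, the genome-wide mean and SD of
per-locus θ define a threshold mean + k·SD (default k = 2), and a selected
SNP counts when its θ is *strictly* above it (so a degenerate SD = 0 counts
nothing). Undefined per-locus θ is excluded from the moments and the
counts. In a design with one drifted breed, the expected signature is that
the drifted contrast's count is maximal — ideally the full selected set —
while other contrasts catch only a background fraction.

## Gene windows

A cis-window of total width 500 kb (±250 kb, clipped at position 1) is
placed around each selected SNP; "500 kb window around a SNP" is read as
total width, the convention of the SNP-proxy tooling this step follows, with
the half-width exposed for the alternative reading. A gene overlaps a
window when any base is shared (closed intervals); per-window lists keep
duplicates, the global list is deduplicated by gene id and ordered by
(chromosome, start).

## Synthetic data

The generator is Balding–Nichols: ancestral frequency p ~
Uniform(0.1, 0.5), population frequency p_k ~ Beta(p(1−F_k)/F_k,
(1−p)(1−F_k)/F_k), genotypes Binomial(2, p_k) — Hardy–Weinberg within
populations, so F_IS ≈ 0 by construction and pairwise θ between populations
i and j comes out near (F_i+F_j)/2. The uniform ancestral MAF band gives a
mean MAF of 0.30 ± 0.12 and expected heterozygosity ≈0.39, the regime of a
commercial chip after a 5% MAF filter. Outlier loci shift the target
population's frequency by δ = 0.35 (toward the farther boundary, clipped to
[0.01, 0.99]) — the simplest generator of a one-population high-θ
signature. Missingness is uniform at 1%, which reproduces the scale of
missingness-filter removals (a few per mille of loci) seen in chip studies
with ~95 animals. Loci are spread over 29 autosomes proportionally to
approximate chromosome lengths; the gene fixture plants two genes inside
and one decoy outside every outlier window plus random background genes, so
window extraction has known positives and negatives.

The study-shaped preset uses 23+24+24+24 animals and per-breed drift
F = (0.005, 0.006, 0.029, 0.0095) for NU/D/T/NI — a least-squares star-model
fit that places the six pairwise θ in the 0.005–0.023 band with the T
contrasts at the top (a star model cannot reproduce every published pair
exactly; it matches the mean of the T pairs) — with 49 planted outliers in
T at chip scale (48,505 loci).

What the generator does **not** emulate: linkage disequilibrium (loci are
independent, so PC structure is less concentrated than on a real chip and
the 10× contribution rule selects more loci than a real dataset of the same
size would — ~140 at full scale where a real study found ~49), ascertainment
bias of chip SNP panels, relatedness/pedigree structure, non-star breed
history (admixture, shared drift), and informative missingness. Passing
tests therefore demonstrate estimator correctness and the qualitative
drifted-breed signature, not the exact counts a specific real dataset
yields.

## Numerical and testing choices

Bootstrap and permutation counts default to 1000 and 10,000. Test suites
run the study-shaped preset at 6,000–10,000 loci and the full 48,505 only in
the acceptance script; at these sizes every stage is vectorized (indicator
matrix products for pairwise |Δdosage|, six matmuls for the Nei matrix,
thin SVD for PCA) and the whole acceptance run takes seconds. Estimator
implementations are cross-checked against independently coded scalar
oracles (WC 1984 components, Nei D, Reynolds moments, brute-force AMOVA SS,
naive complete-linkage agglomeration) and against scikit-learn's PCA.
Degenerate inputs are explicit: monomorphic loci are unusable for θ,
all-missing loci error in PCA and warn in MAF, zero-variance components
yield zero contributions with a warning, permutations = 0 reports the AMOVA
p as not computed.

## Known limitations

One-vs-rest θ depends on the Wahlund structure of the pooled rest and is
not a clean coancestry estimate (use the per-locus vector, as the outlier
validation does). Loci-bootstrap significance declares tiny but genuine
structure significant at large locus counts. The BC bootstrap lacks the
acceleration term. AMOVA is strictly two-level. Trees carry no support
values.
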