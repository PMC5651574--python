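# goatpop

Population-genetic analysis of dense SNP-array genotypes in closely related
livestock breeds, built around the study design of the four main Sudanese
goat breeds — Nubian (NU), Desert (D), Taggar (T) and Nilotic (NI) — typed on
the ~50 K caprine BeadChip (~24 females per breed). The package takes raw
genotype calls to a full diversity/differentiation report:

1. **Sequential locus QC** — GenTrain cluster score ≥ 0.6, pooled MAF ≥ 0.05,
   missingness ≤ 5%, uniquely mapped probes — with per-step removal
   bookkeeping that sums exactly to `initial − surviving`, plus per-sample
   call-rate screening and a Hardy-Weinberg deviation count (reported, not
   filtered).
2. **Within-breed diversity** — observed/expected heterozygosity, Wright's
   multilocus F_IS = 1 − H̄_O/H̄_E with a 1000-replicate bias-corrected
   percentile bootstrap over loci, percent polymorphic loci, and the MAF
   spectrum in rare/intermediate/common/frequent classes.
3. **Differentiation** — Weir–Cockerham (1984) θ per breed pair and
   one-vs-rest, combined across loci as a ratio of summed variance
   components Σa/Σ(a+b+c) (negative estimates preserved), with loci-bootstrap
   CIs at a Bonferroni-adjusted alpha of 0.005 and a suggestive tier at 0.01.
4. **Distances & structure** — Nei (1972) standard distance between
   individuals (pairwise-complete loci), Reynolds coancestry between breeds,
   normalized Manhattan distances; complete-linkage clustering with Newick
   export; two-level AMOVA (Excoffier 1992) with permutation p-values; and
   identity-by-state kinship.
5. **PCA-based SNP selection** — prcomp-style PCA (center, no scaling, mean
   imputation); each SNP's contribution to PC1 as the share of squared
   variable–component correlations (equal to 100·loading² for unit-norm
   loadings); selection of SNPs contributing ≥ 10× the uniform expectation
   100/M %; validation of the selected set against genome-wide one-vs-rest
   per-locus θ using a mean + 2·SD threshold; and extraction of genes inside
   500 kb cis-windows around the selected SNPs.
6. **Synthetic data** — a Balding–Nichols generator
   (p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), genotypes Binomial(2, p_k))
   shaped like the study: 23+24+24+24 animals, per-breed drift F fitted to
   pairwise FST in the 0.005–0.023 band with one strongly drifted breed, 49
   planted outlier loci, and a gene annotation with known placement — so
   every stage is testable against known truth.

All formats are plain text: PLINK `.ped`/`.map` or a TSV genotype matrix,
TSV metadata tables, square TSV distance matrices, Newick trees.

## Worked example

Numbered drivers under `analysis/` run the whole chain on simulated data
(here 12,000 loci for speed; drop `--loci` for the full chip scale):

```sh
cd analysis
python 01_simulate.py --loci 12000 --seed 42
python 02_quality_control.py
python 03_diversity.py
python 04_fst.py
python 05_clustering_amova.py
python 06_pca_selection.py
python 07_gene_windows.py
```

which prints, among other things:

```
12000 loci in; removed per step:
  gentrain   0
  maf        6
  missing    30
  unmapped   0
  multi_hit  0
11964 loci pass QC; 606 deviate from HWE at alpha 0.05 (reported, not removed)

breed  n   H_E   H_O   F_IS     pct_polymorphic  maf_mean±sd
D      24  0.39  0.39  -0.0001  99.9             0.29±0.12
NI     24  0.39  0.39   0.0011  99.9             0.29±0.12
NU     23  0.39  0.39  -0.0042  99.9             0.29±0.12
T      24  0.38  0.38   0.0011  99.6             0.28±0.13

pairwise Weir-Cockerham FST:
  D-T: 0.0194 [0.0180, 0.0212] **   NI-T: 0.0208   NU-T: 0.0185
  D-NI: 0.0075   D-NU: 0.0063   NI-NU: 0.0070

AMOVA: 5.94% among breeds, 94.06% within (Phi_ST 0.0594, p 0.0001)
IBS kinship off-diagonal: 0.68-0.71 (mean 0.69)
PC1 explains 2.3% of variance, PC2 1.5%
expected contribution 0.0084%; threshold 0.0836%; 54 SNPs selected
  T vs rest: 54/54 selected SNPs above mean+2SD (threshold 0.0977)
  D vs rest: 15/54 ...
48 unique genes overlap the windows
```

Reading the output: the drifted breed (T) shows elevated FST against every
other breed and against the pooled rest; most variance sits within breeds
(AMOVA); PC1 carries the T separation, and every SNP selected by the 10×
contribution rule exceeds the genome-wide mean + 2 SD of per-locus θ for the
T-vs-rest contrast — the planted differentiation signature — while only a
minority do for the other contrasts. Genes near those SNPs are collected in
500 kb windows.

The same chain is available as a library call (`goatpop.pipeline.run_all`)
driven by a flat YAML config in which every threshold (0.6, 0.05, 0.05,
1000 bootstraps, alpha 0.005, 10× selection, 2 SD validation, 500 kb
windows) is a named key.

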