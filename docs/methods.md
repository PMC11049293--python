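# Methods

This note records the models, conventions and numerical choices behind
`synaptomics`, in the order the pipeline runs, together with what the
synthetic-data generator does and does not emulate.

## Study design and data model

The design is a balanced 2×2 factorial: genotype (euploid vs trisomic) ×
treatment (water vs fluoxetine), four animals per cell, sixteen samples
quantified together in one TMTpro 16-plex run. The analysis object is a
protein × sample matrix of log₂ quantities with missing values; upstream
of it sits a spectrum × channel table of reporter-ion intensities, each
spectrum assigned to one or more proteins.

## Reporter-ion processing

**Impurity correction.** Isotope impurities make each label's signal leak
into neighbouring channels. With `P[i, j]` the fraction of label *j*'s
signal observed in channel *i* (expanded from a per-channel −2/−1/+1/+2
percentage table, diagonal = 100 minus the printed leakages, leakage off
the plex boundary treated as lost), the observed spectrum satisfies
`observed = P · true`; correction solves this linear system per spectrum.
`P` must be full rank; negative solutions — possible with noise — are
clamped to zero and counted. The forward model (`mix_impurities`) and the
correction are exact inverses, which the tests verify to 1e−10 relative
error.

**Iterative normalization.** Alternating removal of per-sample and
per-spectrum median offsets in log₂ space, iterated to a fixed point
(tolerance 1e−8 on the largest adjustment, cap 100 sweeps). The overall
intensity level is preserved by re-centering each offset vector on its
own median. The procedure is idempotent and leaves all sample medians
equal and all spectrum medians equal.

**Log transform, pruning, weighting.** Intensities are log₂-transformed
(non-positive values become missing and are counted); spectra matched to
more than one protein are removed before quantification. Each surviving
spectrum receives a weight `w = I/(I + c)` with `I` its total intensity
and `c` the 10th percentile of totals, down-weighting dim, noisy spectra
while bright spectra approach weight 1. This weighting is this package's
own adaptive-intensity rule (the weight function is pluggable); it is
monotone, positive and bounded by 1.

**Rollup.** Protein × sample quantities are weighted medians of the
protein's spectrum values per sample. The weighted median is the smallest
value whose cumulative weight reaches half the total — ties resolve to
the lower value, and equal weights reduce to the lower median for even
counts.

**Permutation differential expression.** The two-group statistic is the
difference of group means. With 4 vs 4 samples all 70 label splits are
enumerated, so p-values are even multiples of 1/70 (each split pairs with
its complement) with minimum 2/70; enumeration is used whenever the split
count is ≤ 20 000, otherwise 10 000 Monte-Carlo draws with the add-one
convention. BH q-values are computed across proteins.

## Protein-level modeling

Proteins quantified in fewer than 15 of 16 samples (more than one
missing) are removed before modeling. Each remaining protein is fitted to
the two-way fixed-effects model with interaction using type-II sums of
squares. Complete balanced data use closed-form contrast arithmetic
(SS_A = n·d_A², SS_B = n·d_B², SS_AB = n·i²/4 against the within-cell
residual), vectorized across proteins; this is algebraically identical to
the least-squares fit and is verified against an independent
normal-equations oracle to 1e−10. Proteins with one missing value are
fitted per protein by OLS with type-II ANOVA on the 15 available cells
rather than imputed. Proteins with an empty or singleton cell are flagged
inestimable; constant proteins get p = 1 with a zero-variance flag. BH
adjustment is applied within each effect family (genotype, treatment,
interaction) separately.

Interaction screening selects proteins with interaction p strictly below
0.05 (nominal, not BH-adjusted), matching the published decision rule.

**Contrasts from summary statistics.** For two groups with printed
mean ± SEM and n, the pooled two-sample t is `t = (m_b − m_a)/√(SEM_a² +
SEM_b²)` with df = 2n − 2 when group sizes are equal (this is exactly the
pooled test); unequal sizes fall back to Welch–Satterthwaite df. This
route reproduces the published AP2A1 (p = 0.001) and CLTA (p = 0.0002)
trisomic-water vs trisomic-fluoxetine values from their printed summary
statistics. The printed EXOC8 p = 0.0593 is *not* reproducible from its
summary statistics by a pooled or Welch t (both give ≈ 0.026); it is
therefore documented but not asserted.

**π score.** `π = log₂FC × (−log₁₀ p)` blends effect size and
significance for ranking; it is zero iff the fold change is zero or
p = 1, anti-symmetric in the fold-change sign, and undefined at p = 0
(callers must use add-one permutation p-values or a floor). Published π
values for FMR1 (−222.23) and UBE3A (−20.5864) are not reproducible from
this formula with any printed (p, FC) pair; the package implements the
formula as stated and leaves the discrepancy documented here.

## PCA and design association

PCA treats the 16 samples as observations and proteins as variables;
each protein is mean-centered with no unit-variance scaling (the common
default for log-scale omics PCA). Components are extracted by NIPALS
(tolerance 1e−9, cap 500 iterations per component, deterministic start
from the highest-variance protein, sign fixed so the largest loading is
positive), with every regression step restricted to observed cells so
missing values need no imputation. On complete data NIPALS agrees with
the SVD solution component by component (tested at |cosine| ≥ 0.9999).
Variance fractions are computed from the drop in residual sum of squares
per component; retention is by fixed component count (default 7) or by a
cumulative-variance target (default 0.76) — both exposed.

Each retained component's scores are fitted to the same 2×2 ANOVA as the
proteins, giving three p-values per component.

**Randomization FDR.** The null is formed by permuting the 16 sample
labels (matrix columns) uniformly and re-running PCA plus the score
ANOVAs; this preserves each protein's marginal distribution and the
protein-protein covariance. (For label permutation the re-fitted scores
are the observed scores re-ordered, so the procedure is equivalent to
permuting the design; the full re-fit is kept because the alternative
cell-wise shuffle, available via `scheme="cells"`, genuinely changes the
fit.) The estimate is the plug-in ratio: mean count of significant
component–effect pairs across randomizations divided by the observed
count, clamped to [0, 1], reported both per pair and per component.

The counting cutoff matters. Under label permutation any fixed score
vector — structured or not — clears a parametric cutoff `a` with
probability close to `a` (measured 0.05–0.07 at a = 0.05 across bimodal,
graded and one-cell score shapes; 20 000 permutations), so with discovery
counting at 0.05 the ratio can never fall meaningfully below ≈ 0.05–0.06
no matter how strong the signal. Discovery counting therefore uses a
stricter cutoff (`fdr_alpha`, default 0.01) than the per-component
significance flags (`alpha`, default 0.05): genuinely associated
components sit at p ≪ 0.01 and keep their discoveries, while the null
expectation per pair drops to ≈ 0.012, letting a real association show an
estimated FDR near 0.01. The fraction of randomizations with at least as
many discoveries as observed (`p_exceedance`) is reported alongside.
With no observed discoveries the FDR is reported as 0 with a
"no discoveries" flag.

## Preranked GSEA

Proteins are ranked descending by either a PC loading or a signed
significance score; ties break by protein identifier so the order is
reproducible. The enrichment score is the classic weighted KS running
sum: hits step up by `|metric|^w / Σ_hits |metric|^w` (weight default
w = 1), misses step down by `1/(N − N_hits)`; ES is the running sum's
most extreme value, taken at the earliest point within 1e−12 of the
maximum deviation so exact ties resolve deterministically. The null for
each set is 1000 random same-size gene sets (gene-label permutation —
appropriate because a loading-based metric has no per-sample replicates
to permute); NES divides ES by the mean |null ES| of the same sign, and
the p-value is the add-one fraction of same-sign null ES at least as
extreme. Sets intersecting the universe in fewer than 5 proteins are
skipped and reported. BH q is computed across tested sets and results
are ordered by NES.

Because the same-sign add-one p is floored near `2/n_perm`, the smallest
attainable BH q in a collection of m sets is ≈ `2m/n_perm`; with 1000
permutations a validation collection of 20 sets is the scale at which a
single strongly enriched set can still clear q < 0.05. The default
collection size of the generator and pipeline is chosen accordingly.

**Which ranking sees a rescue.** Under a full rescue the treated-trisomic
group returns to the euploid-water level, so a TF-vs-EW contrast is blind
to rescue proteins; the pipeline's enrichment ranking therefore uses the
π score of the rescue contrast (TF vs TW), where those proteins are
extreme. The TF-vs-EW contrast remains available for ranking when the
biology calls for it.

## Heatmap clustering

Selected proteins are standard-scaled per row to mean 0, variance 1
(population, divide-by-n, convention), with missing cells propagated and
zero-variance rows rejected by name. Distances are `1 − r` with Pearson r
over pairwise-complete observations (≥ 3 shared samples per pair);
agglomeration is Ward.D2 — the Lance–Williams update on squared
dissimilarities with heights reported on the unsquared scale. The scipy
"ward" linkage on a precomputed condensed distance matrix implements
exactly this recursion; the tests cross-check its merge heights against R's
`hclust(..., method="ward.D2")` on the same distances. The tree is cut at
the root into its two subtrees; "cut1" is oriented as the cluster whose
mean scaled TF value minus mean scaled TW value is negative (proteins
lower under fluoxetine in the trisomic background), "cut2" the mirror
image. Samples (columns) stay in design order — they are not clustered.

Plot exports: the heatmap matrix in dendrogram leaf order with cluster
labels; per-group 95% confidence ellipses for any pair of PC scores
(bivariate normal, χ² quantile with 2 df; degenerate point sets flagged);
and per-protein five-number boxplot summaries using linear-interpolation
quartiles and 1.5-IQR whiskers.

## Synthetic data: what it emulates, and what it does not

The generator plants, per protein: a baseline drawn uniformly from
[8, 14] log₂ units; optional genotype and treatment main effects
(default 0.5 log₂, random sign, 5% of proteins each); and, for a
configurable fraction (default 5%), a genotype × treatment "rescue"
interaction of 1.0 log₂ unit — trisomic-water shifted away from baseline
and trisomic-fluoxetine pulled back — split evenly between rescue-down
and rescue-up directions. Residual noise is additive Gaussian in log₂
space (σ = 0.25 by default), i.e. log-normal intensities, the standard
model for isobaric reporter data. Spectrum counts per protein are
1 + Poisson(mean − 1); spectra scatter around the protein's per-sample
value with an extra spectrum-level offset (σ = 0.3), so the per-protein
median tracks the matrix entry; a small fraction (2%) of spectra is
assigned to two proteins. Missingness is completely at random by default,
with an intensity-dependent mode (dimmer cells more likely missing)
behind a flag; the default rate is 0 at the generator level and set
explicitly by the caller. Defaults mirror the study scale: 2554 proteins,
16 channels, n = 4 per cell.

Planted gene sets draw 90% of their members from proteins carrying a
chosen truth flag; for interaction sets the members come from a single
rescue direction, modeling the empirical observation that pathway members
move coherently — a set straddling both tails of a signed ranking carries
no KS enrichment signal. A subset of simulated proteins is deterministically
renamed after the bundled marker panel and direction-expectation tables
(direction-matched), so the presence and concordance reports exercise
their fixtures on synthetic runs; this can be disabled.

Not emulated: chromatographic elution, isotope envelopes beyond the
purity matrix, peptide sequences, protein inference, batch structure, or
correlated (co-regulated) noise between proteins. Passing tests therefore
demonstrate statistical correctness of the pipeline under its stated
model, not robustness to every artifact of real LC-MS data.

## Problem sizes and published figures

The validation suite and the acceptance script run at desk scale: 2000
proteins for calibration and recovery (50 replicates), 360 proteins for
the PC-randomization checks (200 randomizations), 20-set collections with
1000 permutations for enrichment, 50 replicates of ~48 proteins for
cluster recovery, and one 2554-protein end-to-end run. Figures that are
bound to the deposited study data — 2554 quantified / 2066 retained / 106
interaction-selected proteins, ≈ 76% variance over 7 PCs, the PC 3
p-values, the < 0.003 randomization FDR, and named Reactome pathways with
their NES — are properties of that dataset and are documented here rather
than reproduced; the synthetic analogues check the corresponding
behaviours (filter arithmetic, interaction type-I error ≈ 5% under the
null, design-structured components flagged at small estimated FDR,
planted sets recovered at q < 0.05).

## Known limitations

- The adaptive intensity weighting stands in for an undisclosed
  commercial algorithm; results depending on fine weighting details may
  differ from Scaffold's.
- The plug-in randomization FDR is a ratio of expectations, not a proper
  FDR estimator with confidence bounds; `p_exceedance` is provided as a
  complementary summary.
- Pairwise-complete correlation distances can, in principle, produce a
  non-Euclidean distance matrix; with ≤ 1 missing value per protein this
  has not been observed to break Ward monotonicity, which the tests check.
- The GSEA null shares one permutation ensemble per distinct set size for
  speed; sets of equal size therefore share null draws within a run.
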