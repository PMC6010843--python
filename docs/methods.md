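# Methods

This note documents the models, the synthetic cohort that stands in for
field data, the numerical choices, and the places where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort

The generator (`synthetic_data`) emulates a field study of six tree
subpopulations in three ecoregions, ~30 trees each, profiled with
untargeted LC-MS and a reduced-representation SNP panel, and scored 1–5
for canopy disease.

**Genotypes.** Balding–Nichols structure: for each SNP with ancestral
frequency p ~ U(0.1, 0.9), subpopulation frequencies are drawn
Beta((1−F)/F·p, (1−F)/F·(1−p)) with F = `fst_target` (default 0.05, the
weak-differentiation regime typical of outcrossing trees). A second level
of the same form (`region_differentiation`, default 0.05) places extra
divergence between ecoregions; region centers sit far apart on an abstract
plane with subpopulation sites jittered nearby, so geographic distance
mirrors the genetic hierarchy. A plain single-level model carries no
geography signal at all, which is why the hierarchy exists. A fraction of
tags (default 15%) is drawn with boosted differentiation and labeled
"outlier", emulating loci under divergent selection; per-SNP
Weir–Cockerham estimates are filled into the SNP metadata because the
outlier-panel selection rule needs them. Genotype calls go missing
completely at random (default 3%).

**Metabolome.** Log abundance of metabolite m in sample i is

    baseline_m + Σ_k λ_mk f_ki  +  Σ planted SNP effects
               + env slopes · standardized covariates + N(0, σ)

with latent pathway factors f ~ N(0,1). Pathways have 3–4 members with
loadings |λ| ~ U(0.7, 1.0) (80% positive); the true conditional-dependence
graph is the union of within-pathway cliques, known by construction. The
size choice matters: in a single-factor clique of size m the pairwise
full-order partial correlation is ≈ λ²/(σ² + (m−1)λ²), which decays with m
and saturates near 0.24 at m = 5 regardless of loading strength — at the
study's sample size (~170) that is the boundary of detectability, while
3–4-member groups (matching the size of the candidate biomarker group the
analysis is designed around) are comfortably recoverable.

Each metabolite expands into 1 + Poisson(redundancy−1) redundant peaks
(default redundancy 7.4, so 377 metabolites yield ~2,785 aligned features)
sharing its retention time up to `rt_jitter` (0.5 s), with near-perfectly
correlated intensities (log-scale noise 0.05) and distinct m/z from a
fixed adduct/isotope offset table; the parent [M−H]⁻ peak is always the
most intense. Metabolite retention times sit on a shuffled uniform grid
over 90–1,170 s, so distinct metabolites stay separated beyond the
grouping tolerance at desk scale. Per-sample dropout (default 5%) zeroes
all peaks of an undetected metabolite — zeros mean "below detection", not
missing at random.

**Planted effects.** Two SNPs carry effects on log abundance (one on two
pathway-linked metabolites — so the integrated network has a
multi-associated SNP — and one on an isolated metabolite). The default
effect size, 0.8 log units per dosage unit, comes from an a-priori power
computation: with n = 180, residual trait SD ≈ 1.2, dosage SD ≈ 0.65 and a
Bonferroni threshold of 0.05/400, the noncentrality ≈ 0.8·0.65·√180/1.2 ≈
5.6 gives ≥ 90% power. A configurable fraction of metabolites (30%)
responds to Tcol (slope 0.5 per SD) and Bio14 (0.3 per SD), which are
site-level and therefore confounded with subpopulation — as in real
collection campaigns.

**Disease.** Binary health is Bernoulli with logit = intercept (1.2,
giving roughly 60–80% healthy) + slopes on z-scored log biomarker
abundances + (−1.0)·z(F) + (−0.5)·z(Tcol) + site intercepts ~ N(0, 0.5).
The biomarkers are the first pathway's members; the first one has its
baseline raised above the largest of its group so it is the dominant
member in essentially all samples. The default slopes (1.5, −0.5, −0.5)
make the *relative* dominance of that metabolite predictive of health.
This is deliberate: with a slope on the dominant member alone, the shared
pathway factor cancels out of within-group abundance ratios and dominance
indices carry almost no health signal — the modeled phenomenon is
precisely a dominance (unevenness) effect. The 1–5 score is derived by
quantile-binning the linear predictor within each binary class (diseased →
terciles 1/2/3, healthy → halves 4/5), so recoding {4,5} vs {1,2,3}
reproduces the generated state exactly.

**What the generator does not emulate.** Chromatographic drift and
batch effects, adduct-specific intensity physics, pathway structure beyond
one factor per group, linkage disequilibrium within tags beyond the
tag/SNP hierarchy, spatial autocorrelation of disease, and
missing-not-at-random genotyping. Passing tests therefore demonstrate
correct recovery under a clean version of the study design, not robustness
to those artifacts.

## Feature processing

Grouping links two features when |ΔRT| ≤ 5 s and Pearson intensity
correlation ≥ 0.75 (both config-exposed; the tolerance mirrors the
alignment bandwidth scale of common LC-MS preprocessing), and takes
connected components; the representative is the member with the largest
median intensity (median rather than a single maximal peak, for robustness
to outlier samples), ties broken by mean then id.

The DModX outlier statistic follows the PCA distance-to-model form:
autoscale features, fit A components, and compare each sample's normalized
orthogonal residual DModX² against an F critical value. Two practical
points surfaced during validation and are built into the pipeline stage
(the `dmodx_outliers` function itself is scale-agnostic):

- **Redundancy breaks the degrees of freedom.** Peaks of one metabolite
  repeat the same residual, so on the raw feature table the statistic
  behaves as if it had ~redundancy-fold fewer degrees of freedom than the
  F reference assumes, and clean cohorts get flagged en masse (18+/180 at
  a Bonferroni-level alpha in our experiments). The pipeline therefore
  groups first and screens on the collapsed metabolite matrix.
- **Below-detection zeros are leverage points.** ln(0 + 1) = 0 sits ~5σ
  from a typical log abundance. The screen log-transforms after
  half-minimum imputation and masks non-detected cells out of the residual
  sums (per-sample degrees of freedom K_i − A), via the function's
  `observed` argument.

With both corrections, clean synthetic cohorts produce zero false flags at
the Bonferroni-level drop alpha while a sample with heavy independent
noise in half its features is flagged uniquely.

Downstream correlation-based stages (distances, association, GGM, logistic
models) consume `impute_undetected` output — natural logs with
not-detected zeros replaced by half the metabolite's smallest detected
intensity. Diversity indices use raw intensities with zeros kept, since
richness is defined by detection. Annotation assumes deprotonated ions
([M−H]⁻ only); the 10 ppm window is inclusive with a 1e-9 relative slop
absorbing floating-point cancellation in the neutral-mass difference.

## Chemodiversity

Indices are computed on raw intensities (relative abundances are
compositional on the raw scale; the log matrix is reserved for
association/network work). Evenness is Pielou's H/ln S, undefined (NaN)
for S ≤ 1; the detection threshold defaults to 0 (any positive aligned
peak counts). Subset indices renormalize within the subset, so they are
invariant to everything outside it.

## Population genetics

The HWE exact test sums Levene–Haldane conditional probabilities ≤ the
observed configuration's (with a 1e-12 relative tolerance on the
comparison); it matches brute-force enumeration over allele placements for
every table with ≤ 6 individuals in the test suite. The SNP filter keeps a
locus when MAF ≥ 0.05, call rate ≥ 0.80, and HWE p ≥ 0.05 in strictly more
than half of subpopulations with ≥ 5 genotyped individuals (the per-test
alpha and the subpopulation floor are config-exposed since the field
conventions vary). Tag thinning keeps the cut-site-proximal SNP on neutral
tags and the highest-F_ST SNP on outlier tags; mixed-class tags count as
outlier, and outlier tags with no usable F_ST estimate fall back to the
position rule with a warning.

Expected heterozygosity uses the small-sample correction 2p(1−p)·2n/(2n−1)
everywhere. Nucleotide diversity divides summed unbiased 2pq by tag count
× tag length — the only sequence-length information reduced-representation
tags carry. Rarefied allelic richness is the exact hypergeometric form
Σ(1 − C(N−Nᵢ,g)/C(N,g)) with g defaulting to the smallest genotyped
gene-copy count across (locus, subpopulation). The inbreeding coefficient
is the method-of-moments (O_hom − E_hom)/(L − E_hom) with total-sample
allele frequencies. Missing dosages are excluded pairwise for IBS and F
but mean-imputed in the association module — a deliberate asymmetry
matching the respective conventions of the tools those modules emulate.

Weir & Cockerham θ uses the standard a/b/c variance components per locus
and ratio-of-sums across loci; it agrees with an independently coded
oracle to 1e-10 and recovers the generator's F_ST within Monte-Carlo
error. Linearization maps θ → θ/(1−θ) with negative multilocus estimates
truncated at 0 and θ = 1 capped (configurable) with a warning.

## Multivariate structure

ANOSIM uses mean ranks with the divisor m(m−1)/4 (m = samples), which
bounds R in [−1, 1] and equals 1 under complete separation; it matches
scikit-bio's implementation exactly in the cross-check tests. Negative
pairwise R values are shifted by the minimum before the matrix is used as
a distance analogue in Mantel tests.

Mantel tests correlate upper-triangle vectors; the partial form
residualizes both vectors on the conditioning vector and permutes the
first matrix's entities, recomputing its residualization each time. The
one-tailed p uses the (count+1)/(n_perm+1) estimator; CIs are percentile
bootstraps over entities (self-pairs excluded). Empirical type-I error of
all three permutation tests is verified to sit in [0.03, 0.07] at nominal
0.05 over 500 null replicates. With six sites a Mantel test has only 720
distinct permutations, of which ~48 block-symmetric ones nearly tie the
observed statistic under strong regional structure, flooring the p-value
near 0.05 — congruence analyses in the validation suite therefore use nine
sites (three per ecoregion) where resolution is needed; this is a property
of small site counts, not of the estimator.

DAPC autoscales, retains the smallest number of PCs explaining ≥ 90%
variance (capped at n/3 against overfitting), and fits an LDA on the
scores. Prior-free K selection scores k-means solutions with the BIC of a
hard-assignment spherical Gaussian mixture — including the
mixing-proportion term n_k ln(n_k/n) and a K·d + K parameter count. A
WSS-only criterion with a K·ln(n) penalty cannot work here: splitting a
single Gaussian cloud genuinely shrinks within-cluster variance by a
constant factor per split, so such a criterion prefers ever-larger K even
on unstructured data (verified directly during development); the mixture
BIC recovers both K = 1 on single clouds and the planted K on separated
clusters.

## Mixed-model association

EMMA REML: project out fixed effects, eigendecompose S K S once, and
maximize the profile restricted likelihood in δ = σ²_e/σ²_g by root-finding
on the derivative's sign changes over a 100-point ln δ ∈ [−10, 10] grid,
returning the best stationary point or boundary (flagged). Agreement with
a direct numerical REML maximization is verified to |Δh²| < 1e-4. The scan
reuses the null-model components per trait (EMMAX approximation),
whitens y, X and all dosages with V^{−1/2}, and t-tests the dosage
coefficient; with K = I it reproduces OLS p-values to 1e-8.

Bonferroni control is per trait across SNPs (0.05/n_SNPs), the convention
of the emulated tool; a global-denominator option exists. The Q–Q screen
passes a trait when the genomic-inflation factor λ_gc (median χ² quantile
/ 0.4549) lies within [0.8, 1.2] **widened by 3·SE(λ)** with SE ≈
2.33/√m for m SNPs, and a KS test of the sub-threshold p-values against
uniform is not rejected at 0.01. The widening matters at desk-scale
panels: a median-based λ on 300 SNPs has SE ≈ 0.13, so a fixed band would
reject well-calibrated traits ~15% of the time on sampling noise alone; at
a ~1,500-SNP panel the band converges to the fixed one. Whole traits (not
individual SNPs) are excluded when the screen fails.

## Gaussian graphical model

With hundreds of metabolites and fewer samples the sample correlation
matrix is singular, so the estimator shrinks it toward the identity with
the analytic Schäfer–Strimmer intensity λ* = Σ V̂ar(r_ij)/Σ r²_ij (clamped
to [0,1]) and reads partial correlations off the inverse. Edge
significance uses a zero-centered null on the z = atanh(pcor) scale whose
scale is the *smaller* of (a) a robust empirical estimate
median(|z|)/0.6745 — valid when most pairs are null, as in wide panels —
and (b) the classical Fisher SE 1/√(n−p−1), defined only when n > p and
binding when true edges dominate the empirical spread (small designed
panels). Benjamini–Hochberg q ≤ 0.05 selects edges. On the default
synthetic configuration (50 metabolites, ~170 samples) planted
within-pathway support is recovered with precision and recall ≥ 0.8; a
fixed-|pcor| threshold alternative is config-exposed.

The integrated network holds metabolites participating in retained GGM
edges plus SNPs significantly associated with them; association edges
carry the set of covariate configurations under which they were
significant, and SNPs with ≥ 2 metabolite partners are flagged
multi-associated.

## Health models

The random-intercept logistic model is fit by Laplace-approximate maximum
likelihood: an inner per-site Newton step finds the posterior mode of each
scalar intercept, the outer BFGS optimizes fixed effects and ln σ_site,
and Wald SEs come from a finite-difference Hessian. On a frozen fixture
the fit matches lme4's Laplace glmer to ~1e-3 in estimates, SEs, σ_site
and log-likelihood; with σ_site fixed at 0 it reproduces ordinary logistic
regression. Complete separation on the focal predictor and constant focal
predictors are detected and rejected. Interaction terms between the focal
predictor and the covariates are intentionally absent from the model.

Random-forest importance is OOB permutation importance (mean decrease in
accuracy) from an explicitly bagged ensemble of CART trees (default 1,000
trees in the module, √p features per split), since the library forest
exposes no public out-of-bag masks. Direction is the sign of the
healthy-minus-diseased mean log abundance; the top-12 set is the default
selection.

Subset chemodiversity models recompute the six indices within a candidate
metabolite group and substitute each as the focal predictor; indices that
are constant (richness with no dropout) or undefined in too many samples
are skipped with a reason. In the pipeline the candidate group is the
connected GGM component containing the top-ranked forest biomarker —
mirroring the analysis flow the package is built around.

## Problem sizes and determinism

All randomness flows from one integer seed through named per-stage
substreams, so stages can be regenerated independently and two runs with
the same config are byte-identical. The validation suite and
`scripts/acceptance.py` run simulations at desk scale — cohorts of 120–180
individuals, panels of 200–400 SNPs, 12–50 metabolites, permutation counts
of 99–999, and 3–100 replicates per property, sizes chosen so the whole
suite completes in a few minutes on one CPU while every recovery property
remains decisively testable. The one acceptance property that is *defined*
at full scale — 377 metabolites expanding to ~2,785 features — is checked
at that scale, which costs little because only the metabolome stage runs.

## Known limitations

- Only [M−H]⁻ ions are considered for annotation; other adducts and
  in-source fragments are grouped but not mass-annotated.
- The GGM edge null is empirical; it controls FDR well in the tested
  regimes but has no finite-sample guarantee under arbitrary dependence.
- The EMMAX approximation understates per-SNP variance-component
  uncertainty for traits with large single-SNP effects (exact per-SNP REML
  is available via `emma_reml` but not wired into the scan).
- The logistic fitter uses a scalar site intercept; crossed or nested
  random effects are out of scope.
- Pairwise-deletion IBS can be non-PSD under extreme missingness; the
  association module floors negative eigenvalues with a warning.
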