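# Methods

## Growth model

Rosette diameter is modeled per plant as a three-parameter logistic
d(t) = FS / (1 + exp(−slope·(t − t50))), with slope > 0 for an increasing
curve (some growth-curve packages parameterize the exponent with the
opposite sign; our slope is the positive rate constant, and the derivative
at inflection, slope·FS/4, is also exposed as `inflection_slope` for
readers who interpret "slope" as the steepest tangent). Fits use
Levenberg–Marquardt with an analytic Jacobian from a data-driven start
(FS₀ = max diameter; t50₀ = first day exceeding FS₀/2; slope₀ = 4·max
gradient/FS₀), with up to five deterministically jittered restarts. A fit
is flagged failed — and excluded downstream, never silently dropped — if
the optimizer does not converge or the solution is not a positive bounded
increasing curve (FS outside (0.5, 10)× the observed maximum, or a plant
that never emerged). Fitting requires ≥4 distinct time points.

Curves are fitted per plant; a genotype-pooled fit can be had by merging
replicate series, but per-plant fitting is primary because the block
design corrects plant-level environments afterwards.

## Genotypic means, plasticity, heritability

Genotypic means fit `parameter ~ genotype + block + tray + tray:row +
tray:col` by OLS and report estimated marginal means: the model prediction
for each genotype averaged over all observed design cells. This is
invariant to the contrast/reference choice and reduces to raw group means
in balanced designs without nuisance effects. Nuisance terms whose factor
is constant are dropped automatically so degenerate designs (one block,
one genotype) still work.

Plasticity (GxE) per genotype is the residual of its low-light mean
regressed (OLS) on its high-light mean — the deviation from the
population-average light response. Residuals sum to zero by construction.

Broad-sense H² uses REML (statsmodels MixedLM) on plant-level parameters
with block fixed and genotype random: H² = V_G/(V_G+V_E), clipped to
[0, 1]. The degenerate zero-residual case (identical replicates) returns
1 directly rather than relying on a boundary REML fit.

## Mixed-model association

Kinship is identity-by-state: K_ij = mean over pairwise-complete markers
of 1 − |g_i − g_j|/2 (for fully homozygous selfers this is plain allele
sharing; heterozygous calls get the natural intermediate value). Missing
genotypes are never imputed for kinship; they are mean-imputed per marker
only for testing.

The variance model y = Xβ + u + e, u ~ N(0, σ²_g K), e ~ N(0, σ²_e I) is
fit by restricted maximum likelihood profiled on δ = σ²_e/σ²_g: the
kinship is projected off the fixed-effect space, eigendecomposed once,
and the restricted likelihood maximized over log δ by a 100-point grid
plus bounded refinement (search range 10⁻⁵–10⁵). Pseudo-heritability is
σ²_g/(σ²_g+σ²_e). EMMAX fixes δ at the null value, whitens phenotype,
covariates and genotypes in the eigenbasis, and runs per-marker GLS via
Frisch–Waugh residualization (fully vectorized); p-values use the t
distribution with n − rank(X) − 1 df. Exact EMMA (per-marker δ
re-estimation) is available for small problems. The two routes agree
closely on the bulk of markers, but per-marker re-estimation at n ≤ 100
can move individual p-values by several tenths of a log10 unit (or
collapse to the σ²_e → 0 boundary under a strong marker effect) — an
intrinsic property of the approximation pair, covered explicitly in the
tests. MAF and missingness filters are boundary-inclusive (a marker at
exactly 5% MAF is retained, reading "below 5% removed" literally).

LOF association reuses the same machinery with 0/1 gene states (reported
effects are per state). Kinship-corrected trait correlations report plain
Pearson r with a Wald p from the mixed model y = α + βx + u + e, which
reduces exactly to the classical Pearson test when K = I.

## Differentiation

Per-SNP Fst is the Nei/Nei–Chesser gene-diversity estimator with
sample-size correction: Hs = ñ/(ñ−1)·(1 − mean(p²+q²) − Ho/2ñ) with ñ the
harmonic mean sample size, Ht = 1 − (p̄²+q̄²) + Hs/(ñ·k) − Ho/(2ñk), and
Fst = (Ht−Hs)/Ht with negatives set to zero. Lines are
haploid-equivalent (a heterozygous call counts 0.5). Genes aggregate SNPs
by ratio of sums Σ(Ht−Hs)/ΣHt — the standard multi-locus estimator — not
the mean of per-SNP ratios. A Weir–Cockerham variant is deliberately out
of scope; the Hs/Ht family is what the downstream percentile comparisons
assume.

The random-set test reports a two-sided KS p of the hit set against the
genome-wide distribution, and the add-one-corrected fraction of random
equal-size sets whose 95th percentile reaches the hit set's. Regional
contrasts use Tukey-HSD single-step adjustment with a compact letter
display (insert-and-absorb).

## Polygenic scores and Qx

LD clumping is greedy by ascending p (ties broken by position then id):
index SNPs need p < 10⁻⁴; markers with p < 0.01 within half of a 1 Mb
window and r² ≥ 0.5 (Pearson correlation of genotype codes,
pairwise-complete) join the clump. The r² default mirrors the 0.5 LD
cutoff used for candidate-gene windows; the source analyses do not state
the clumping r² explicitly.

Scores are Z = 2Σ αₗpₗ per unit; for one selfing genotype pₗ = dosage/2.
The Qx statistic centers Z across m units and computes
Z_cᵀ(2·V_A·F)⁻¹Z_c (pseudo-inverse on the centered covariance), with
V_A = 4Σ α²ε(1−ε) and χ²(m−1) reference. F is estimated from genome-wide
markers as half the standardized allele covariance,
F_ij = mean_l (p_il−ε_l)(p_jl−ε_l)/(ε_l(1−ε_l)) / 2, so a single inbred
line has F_ii = 1/2 and Cov(Z) = 2·V_A·F holds exactly for Bernoulli
alleles. Identity-by-state kinship must not be used here: its baseline
between unrelated lines is Σ(p²+q²)/m ≠ 0, which under-scales the
centered F and makes every marker set look over-dispersed. A `selfing`
flag doubles the drift scaling for users who treat units as selfing
families; the default follows the diploid formula. The empirical null
redraws marker sets matched on mean-frequency decile (an unmatched mode
exists) and carries the observed effects.

The pipeline runs Qx at two unit levels: each genotype as its own
population (df = m−1) and the regions (df = k−1). Between-region
divergence concentrates in the regional test; the genotype-level test
spreads it over many degrees of freedom.

Validation schemes: 80/20 holdout (GWAS on 80% of genotypes, score and
correlate the rest), replicate cross-validation (GWAS on two replicates'
means, correlate scores with the third), and random-set comparison
(associated-set rho against the empirical distribution of rho for
equal-size random marker sets; median, 95th percentile, max and
exceedance fraction reported). Correlations are Spearman.

## Qst

Qst = VarB/(VarB+VarW) from a one-way random-effects REML on genotypic
means (region random intercept; residual = genotype-within-region). The
REML is profiled on λ = VarB/VarW, for which VarW has the closed form
(Q+SSW)/(N−1); the 1-D search is cross-checked against statsmodels
MixedLM in the tests. For selfing lines these are broad-sense components,
which is the relevant quantity when whole-genotype variance can respond
to selection. A replicate-level variant with block fixed is available
through the heritability machinery.

The permutation null shuffles region labels and compares the statistic
qst − fst95 (not raw qst), with add-one correction. The MVN null draws
genotypic values from N(0, Vg·K) — Vg estimated as the within-region
genotypic variance of the observed means, with an optional ×2 additive
scaling flag — and re-estimates Qst per draw. Both nulls are discrete and
have an atom at qst = 0 (the REML boundary), so their p-values are
conservative near the null rather than exactly uniform; the tests check
validity (P(p ≤ α) ≤ α plus tolerance), not exact uniformity.
The Fst comparison reports the empirical percentile (weak ordering) of
the genome-wide SNP Fst distribution at the observed Qst.

## GO enrichment

Every universe gene gets exactly one score: minimum p over SNPs inside
the gene body, else the p of the closest SNP by gene-midpoint distance
(ties toward smaller p). Tandem duplicates — precomputed alignment pairs
with e-value < 10⁻³⁰ lying < 10 gene ranks apart on one chromosome — lose
their downstream member (order-independent, idempotent); the repository
consumes the pairwise table and does not run an aligner. Fisher
enrichment is the one-sided hypergeometric tail on the 2×2 table; terms
with ≤5 universe genes are suppressed. The rank test is a one-sided
two-sample KS of term-gene scores against the rest, sensitive to small-p
enrichment. The calibration threshold reruns the Fisher enrichment on
random candidate sets and takes the 0.01% quantile of the pooled p-value
distribution. DAG decorrelation (elim/weight) is out of scope: the
classic test is reproducible and oracle-checkable. Candidate windows
around a focal SNP take the contiguous run of markers with r² ≥ 0.5,
truncated at ±125 kb, and return overlapping genes (1-based inclusive
coordinates throughout).

## Synthetic studies

The generator emulates the study conditions: k regions of fully
homozygous selfing lines (defaults: 2 × 60 lines, scaled down from the
original panel of ~119 Spanish and ~84 Northern European accessions), 5000
SNPs on 5 chromosomes, ancestral frequencies Uniform(0.05, 0.95) to keep
the MAF filter exercised without degenerate markers, and regional
frequencies from a Balding–Nichols Beta model. The BN parameter is
calibrated as F = G·k/(k−1+G) so the realized multi-locus Nei Fst equals
`fst_target`; the default 0.06 reproduces the between-region divergence
of the real panel (mean ≈ 0.057, 95th percentile ≈ 0.21). Optional
uniform missingness exercises the missingness filter.

Traits are polygenic: standard-normal effects at `n_causal` random
markers, genotypic values standardized to unit SD, an optional additive
regional shift (genotypic-SD units), and replicate noise scaled so
single-replicate broad-sense heritability equals `h2` (default 0.6, in
the range of the heritable growth parameters of the real panel).
`selection_delta` additionally tilts causal allele frequencies between
regions along effect signs — divergence that is genuinely mediated by
the causal markers, which is what the Qx machinery is designed to
detect; the additive shift alone is invisible to a frequency-matched
marker-set null, by construction.

Growth experiments evaluate each line's logistic curve (FS carries the
polygenic signal at 1 cm per genotypic SD around a 7.5 cm mean; slope
0.25 ± 0.04/day and t50 14.5 ± 2 d vary between genotypes without marker
effects) at a bi-weekly high-light measurement schedule (days 11–46),
one replicate per genotype in each of 3 randomized blocks on 5×7-pot
trays, with additive block (SD 0.2 cm) and tray (SD 0.1 cm) offsets,
plant-level parameter deviations scaled to realize `h2`, and 0.2 cm
measurement noise. What the generator does not emulate: linkage
disequilibrium decay within chromosomes (markers are exchangeable given
their region frequencies), genotype-by-block interactions, non-logistic
growth phases, and shared environmental gradients within trays — so
passing tests demonstrate correctness of the estimators under the assumed
model, not robustness to those real-data features.

LOF matrices are Bernoulli gene × genotype states (default frequency
0.15) with one designated causal gene shifting the trait (default −3.5
units, the scale of the LOF association reported for the real panel).

## Reproducibility and problem sizes

A single global seed expands into per-stage seeds via
`SeedSequence([seed, stage_index])`; identical configuration and seed
give identical reports. The acceptance script and the end-to-end tests
use 2 × 80 lines with 3000 SNPs, 20 causal loci, h² = 0.8 and
selection_delta = 0.35 — a planted effect strong enough that its
recovery is informative about correctness — with 499 permutations, 1000
MVN simulations and 500 random marker sets; these are the package's
standard demonstration sizes and complete in well under a minute.
Sub-significant candidate SNPs use p < 10⁻³ at this sample size (the
genome-scale default of 10⁻⁴ is kept for full-size panels). Numerical
safeguards: kinship jittered by 10⁻⁶ on the diagonal when the smallest
eigenvalue is below 10⁻⁸; REML searches bounded as stated above;
permutation and resampling p-values add-one corrected so they are never
zero.

## Known limitations

No coalescent/LD-aware simulation; no multi-locus or multi-trait mixed
models; no Bayesian Qst–Fst; GO enrichment without DAG decorrelation;
flowering-time placeholder handling is input preparation only. The
external-data acceptance checks (published supplementary tables, public
genotype panel) require files that cannot ship with the repository.
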