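# Methods

This note records the statistical model behind `mrlink`, the defaults and
why they were chosen, the numerical decisions that are not visible from the
API, and what the synthetic-data studies do and do not demonstrate.

## Two-sample MR model

Exposure and outcome association estimates come from two independent GWAS
samples over a shared SNP panel. For instrument *j* the observed effects
are modelled as

    β̂_exp,j ~ N(γ_j, se_exp,j²),   β̂_out,j ~ N(Γ_j, se_out,j²),
    Γ_j = β·γ_j + α_j

with causal effect β and direct (pleiotropic) effect α_j. A valid
instrument has α_j = 0; the estimators differ in which violations of that
assumption they tolerate. All estimators consume a
`HarmonizedInstrumentSet` — both sides re-expressed on the exposure's
effect-allele frame — and return effects on the outcome scale (log-odds and
odds ratios for binary outcomes).

## Instrument selection

The cascade runs in a fixed order: exposure significance → LD clumping →
harmonization → outcome-association filter → Steiger filter → confounder
filter → radial-Q pruning. Stage thresholds default to p < 5×10⁻⁸
(exposure), r² = 0.001 within 1,000 kb (clumping), p < 5×10⁻⁵ (outcome
association, confounder association, and radial outliers), one-sided
α = 0.05 (Steiger), and a four-instrument minimum for a pair to be
evaluable. An audit dictionary counts survivors at every stage.

*Clumping* is greedy: the smallest-p unprocessed SNP becomes an index and
removes unprocessed same-chromosome SNPs within the window whose r² with it
exceeds the threshold. Ties on p break by genomic position, then SNP id, so
the result is deterministic. SNPs on different chromosomes never clump.

*Harmonization.* The exposure frame wins. Outcome records matching with
swapped alleles have their effect negated and frequency complemented;
records matching only after strand complement are complemented first.
Palindromic (A/T, C/G) variants cannot be oriented from labels: they are
dropped when the effect-allele frequency on either side lies in
[0.5 − b, 0.5 + b] (default b = 0.08) or is missing, and otherwise oriented
by frequency agreement — same side of 0.5 keeps the record, opposite sides
flip it. Indels are retained but never treated as palindromic.
Harmonization is idempotent, and randomized allele coding of either input
leaves every downstream estimate unchanged to 1×10⁻¹².

*Steiger filtering* computes r² = β²/(β² + se²·n) on each side and drops a
SNP when r²_out > r²_exp **and** the one-sided Fisher-z test of the
correlation difference, z = (atanh r_exp − atanh r_out) /
√(1/(n_exp−3) + 1/(n_out−3)), is significant. For binary outcomes n is the
total sample size; no effective-sample-size correction is applied.

*Radial pruning* fits first-order radial IVW (weights β_exp,j²/se_out,j²),
refers each SNP's Q contribution to χ²₁, removes outliers in a single pass
and refits once. An `iterate_radial` flag enables iteration to convergence;
single-pass is the default because repeated pruning on the same data
progressively overfits the heterogeneity statistic.

*Instrument strength*: R² is the sum of per-SNP r² on the exposure side and
F = R²(n−k−1)/((1−R²)k). F > 10 is the conventional weak-instrument bar.

## Estimators

* **IVW-MRE** — weighted regression through the origin, weights
  1/se_out,j². The fixed-effect SE is inflated by max(1, √(Q/(k−1))):
  heterogeneity widens but never narrows the interval. Its type-I error in
  the null simulations sits slightly below nominal (≈ 0.04 at α = 0.05)
  because the inflation factor is truncated at 1.
* **MR-Egger** — weighted regression with intercept after orienting all
  instruments to non-negative exposure effects; SEs inflated by
  max(1, √(Q′/(k−2))). Inference uses the t reference with k−2 df, the
  convention of the reference MR ecosystem, which keeps the intercept
  (pleiotropy) test close to nominal at moderate k.
* **Weighted median** — inverse-variance weights on the Wald ratios, the
  median located by linear interpolation of the centered cumulative weight
  at 0.5. SE by seeded parametric bootstrap (default 1,000 draws of both
  effect vectors from their sampling distributions).
* **Weighted mode** — mode of the weighted Gaussian kernel density of the
  ratios, bandwidth φ·0.9·min(SD, IQR/1.349)·k^(−1/5) (φ = 1 by default);
  degenerate spread returns the common ratio. SE by the same bootstrap.
* **MR-RAPS** — maximizes the profile likelihood of (β, τ²) under
  β̂_out,j ~ N(β·β̂_exp,j, se_out,j² + τ² + β²·se_exp,j²). Two choices
  matter. First, the log-normalization term carries se_out² + τ² only:
  profiling the latent γ_j puts β²se_exp² in the residual variance but not
  in the density normalization, and keeping it there would re-introduce the
  weak-instrument attenuation the method exists to remove (this is visible
  empirically: with the wrong normalization the RAPS bias equals IVW's).
  Second, with the default Huber loss (c = 1.345) the log-variance penalty
  is scaled by δ = E[ψ(Z)Z] = 2Φ(c)−1 so τ̂² stays Fisher-consistent.
  Optimization is L-BFGS-B with τ² ≥ 0 and a Nelder–Mead restart if the
  line search fails near the boundary; the SE is an empirical sandwich
  H⁻¹BH⁻¹ from per-SNP score contributions via central differences, so it
  is exact only to numerical-differentiation precision (~10⁻³ relative).
* **Contamination mixture** — each ratio is valid (N(β, se²)) or invalid
  (N(0, se² + ψ²)), each SNP assigned to its higher-likelihood component at
  every point of a 1,000-point grid spanning the ratio range ± 2·max(se).
  ψ defaults to 1.5 × SD of the ratios. The 95 % CI collects grid points
  within χ²₁(0.95)/2 log-likelihood of the maximum; a non-contiguous
  accepted region is reported as its hull with a multimodality flag, and
  the nominal SE is the hull half-width / 1.96 (this method is
  interval-first; the p-value is a likelihood-ratio test of β = 0 on the
  same profile).
* **Debiased IVW** — replaces IVW's denominator with
  Σ(β̂_exp,j² − se_exp,j²)/se_out,j², the unbiased estimate of Σγ²w. The
  variance is a sandwich derived from the estimating-equation influence
  function with the exact moments of the two-sample normal model,

      Var(score_j)/w_j² = se_x²se_y² + β²γ̂²se_x² + γ̂²se_y² + 2β²se_x⁴,
      γ̂² = max(β̂_exp² − se_exp², 0),

  which reduces exactly to the fixed-effect IVW variance when exposure SEs
  are zero. A non-positive denominator (instruments too weak on average)
  is an error rather than a sign-flipped estimate.

All stochastic routines (bootstraps, PRESSO simulations) require explicit
seeds in pipeline mode; an unseeded pipeline run is rejected.

## Sensitivity battery

Egger intercept (directional pleiotropy, α = 0.05), Cochran's Q on the IVW
fit (χ²_{k−1}), MR-PRESSO global test (default 1,000 simulated datasets;
observed statistic is the leave-one-out weighted residual sum of squares,
per-SNP outlier p-values Bonferroni-corrected across instruments), and
leave-one-out IVW. "Leave-one-out stable" means every reduced estimate
keeps the full estimate's sign and every reduced p-value stays on the same
side of the declared threshold — a deliberate, explicit operationalization
of the qualitative "no single instrument drives the result". The PRESSO
distortion test (effect shift after removing flagged outliers) is
implemented behind a flag but does not enter the verdict.

## Decision rule, thresholds, power

A pair is *significant* when IVW p < α/(n_phenotypes·n_directions)
(0.05/206/2 ≈ 1.2136×10⁻⁴ by default — note this computed value differs in
the third digit from some published roundings of the same expression; an
override field accepts any externally fixed threshold), *nominal* below
10⁻³, *null* otherwise, and *not evaluable* below four instruments.
Direction consistency requires all seven estimates to share IVW's sign; an
exact zero counts as inconsistent. Power uses the standard normal
approximation Φ(√(n·R²·K(1−K))·|β| − z_{1−α/2}) for binary outcomes (K the
case fraction) and Φ(√(n·R²)·|β| − z_{1−α/2}) for continuous ones, and is
computed post hoc for non-null tiers only.

## Synthetic data

The generator emulates summary statistics directly — no individual-level
genotypes — with per-SNP SE 1/√(2·maf(1−maf)·n), scaled by 1/√(K(1−K)) for
binary traits. Latent effects, sampling noise, and allele-label bookkeeping
draw from three separate seeded streams so label randomization can vary
while effects stay fixed. Pleiotropy regimes: balanced (zero-mean α),
directional (constant-sign α, independent of γ — InSIDE holds),
InSIDE-violating (α correlated with γ at 0.7 by default). Reverse-acting
SNPs get γ = 0 and an instrument-scale effect on the outcome; they are both
the Steiger filter's target and, in bidirectional runs, the outcome trait's
own instruments. LD blocks append proxy SNPs whose effects are the index
signal attenuated by r, together with a matching pairwise r² reference.

Preset defaults: 50 instruments, n = 100,000 per side, γ ~ N(0, 0.06) with
a 0.03 magnitude floor (per-SNP F in the hundreds, the regime of the
motivating study whose reported F statistics all exceed 30), causal effect
0.2 where present. The weak-instrument preset's γ scale (sd 0.015, floor
0.002, k = 100) was calibrated by simulation during development so the mean
per-SNP F is near 10. The directional-pleiotropy preset uses all-positive
exposure effects (mean 0.07, sd 0.02) so Egger's orientation step does not
symmetrize the direct effects, with α ~ N(0.02, 0.01) on every instrument.

What the simulations do **not** emulate: realistic human LD maps and MAF
spectra, polygenic architecture beyond the stated model, sample overlap
between the two GWAS, population stratification, or winner's-curse
selection of instruments. Passing tests therefore demonstrate correctness
of the procedures under the stated generative model, not robustness to
every failure mode of real GWAS data.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script (hundreds to a
thousand replicates; 50–100 SNP panels) are chosen so the full suite runs
in about a minute on one CPU while keeping Monte-Carlo error well inside
the asserted tolerances. Degenerate inputs are contracts, not crashes where
the pipeline can continue: a direction whose cascade yields too few
instruments is recorded as not evaluable; a zero exposure effect excludes
that SNP from ratio-based computation with an audit count; equal-allele or
non-positive-SE records are dropped at ingest with a logged count.
Duplicate SNP ids and unresolvable mandatory columns are hard errors.

## Known limitations

No LD-proxy lookup for outcome SNPs missing from the exposure panel; no
multivariable MR, correlated-instrument IVW, or Bayesian variants; no
liftover or VCF ingestion; the confounder filter consumes a user-supplied
SNP list rather than querying a live catalog, so its completeness is the
caller's responsibility.
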