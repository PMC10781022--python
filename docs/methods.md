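# Methods

## Model

`finemapvi` fine-maps a GWAS locus of G variants from summary statistics.
The generative model is a sum of K single-effect components ("effect
groups"): for individual-level data it would read

    y ~ N(X S β, τ_y⁻¹ I),   S = [s_1, …, s_K],
    s_k ~ Multinomial(1, π̃),   β_k ~ N(0, τ_β⁻¹),

where each one-hot indicator s_k selects the variant carrying the k-th
effect and π̃ is the prior inclusion-probability vector.  With genotypes
and trait standardized, the likelihood depends on the data only through
X ᵀX ≈ N·R (R the LD correlation matrix), X ᵀy ≈ z·√N (z the GWAS
z-scores) and y ᵀy ≈ N, so the model is fitted from summary statistics and
an LD panel alone.  K is an upper bound on the number of causal variants,
not an estimate: spare groups stay diffuse and are filtered before
reporting.  Nothing in the algorithm inverts a matrix, so rank-deficient
LD (duplicated variants, imputed panels) runs to completion.

### Variational inference

A paired mean-field family q(s_k, β_k) = q(s_k)·q(β_k | s_k) is optimized
by coordinate ascent on the evidence lower bound (ELBO).  Each group
update is closed-form: with residual score r_k = z√N − N·R·Σ_{k'≠k}
E[s_{k'}β_{k'}], posterior precision τ* = N·τ_y + τ_β,

    μ_k = τ_y r_k / τ*,   s²_k = 1/τ*,
    γ_k ∝ π̃ · exp(½ log(τ_β/τ*) + ½ μ_k² τ*)   (log-sum-exp normalized).

The ELBO is recomputed from the summary-statistic moments and is
non-decreasing at every coordinate update (asserted in the test suite);
iteration stops when the per-sweep ELBO gain falls below `tol` (default
0.01 nats) or the maximum absolute PIP change falls below `pip_tol`
(default 1e-4), with `max_iter` = 100 sweeps.  Residual scores are
maintained incrementally and refreshed from scratch every 10 sweeps to
cancel floating-point drift.  Inference is deterministic: uniform γ and
zero μ initialization, fixed group order.

### Hyperparameters from local heritability

Rather than estimating variances inside the loop, both precisions are
derived once from the locus' local heritability,

    ĥ² = (zᵀR⁺z − p) / (N − p),

with R⁺ the pseudo-inverse over eigenvalues ≥ `eig_threshold`·λ_max
(default 1e-3) and p the number retained.  The estimate is clipped to
[1e-6, 0.9]; negative estimates (common under the null) are floored and
logged rather than re-estimated.  For a unit-variance trait,
τ_y = 1/(1−ĥ²) and τ_β = K/ĥ² (each effect carries prior variance ĥ²/K;
`strategy="full"` selects τ_β = 1/ĥ² instead).  A simulation property
test confirms the estimator's Monte-Carlo mean tracks the true local
heritability within 3 standard errors at N = 50,000.

### Posterior summaries

Variant-level PIPs combine groups as PIP_g = 1 − Π_k (1 − γ_{k,g}).
Group-level reporting uses *attainable coverage*: the γ mass on variants
with r² ≥ `r2_min` (default 0.25) to the group's top variant.  A diffuse
group can never concentrate its mass on one LD-coherent signal, so groups
with attainable coverage below the credible-set level ρ (default 0.95)
are suppressed; the rest are summarized as the smallest γ-prefix reaching
ρ (ties broken by |z|, then index, for cross-platform determinism).  Two
groups converging on the same lead variant yield one set (the higher
attainable coverage wins); distinct leads in r² > 0.8 are reported
separately with a warning.

### Functional annotations

Priors are parameterized by a softmax over binary annotations,
π̃_g ∝ exp(A_g ᵀ w); exp(w_m) is annotation m's fold-enrichment among
causal variants.  Weights are estimated jointly for all M annotations by
maximizing the PIP-weighted cross-entropy Q(w) = Σ_g PIP_g log π̃_g(w), a
concave problem solved by L-BFGS plus Newton polishing to gradient norm
< 1e-6; standard errors come from the inverse observed information, and
a perfectly separating annotation is capped at |w| = 10 with infinite SE.
A per-annotation G-test on PIP-weighted soft counts
(G = 2·Σ O·log(O/E), χ²₁) screens annotations; only those with
p < `p_threshold` (default 1e-5) inform the second-pass prior.  The
workflow is two-stage: flat-prior fit → weight estimation and screening →
one re-fit with the informed prior (`em_rounds` can iterate further,
`mode="all"` skips the screen).

**Soft counts use signal PIPs.**  Enrichment is estimated from the
posterior mass of effect groups that pass the attainable-coverage filter,
not from raw variant PIPs.  With K groups and fewer true signals, each
spare group leaks ≈ 1/G selection mass uniformly across the locus; summed
over spare groups this leakage is of the same order as the causal mass
and would attenuate recovered log-odds several-fold.  Filtering by the
same rule that gates credible sets removes the leakage while keeping all
localized posterior mass; recovery tests (below) validate the choice.
Reported variant-level PIPs are unaffected.

Enrichment weights should be estimated from pooled evidence — a
genome-wide scan, or many loci/replicates — never from a single locus: a
locus contributes only a handful of causal variants, giving per-annotation
soft counts of order 1 and weight noise of order 1 on the log scale.

### Genome-wide scan

Chromosomes are tiled into 3-Mb windows sliding by 1 Mb; each window is
fine-mapped jointly and only its central 1-Mb core is retained (PIPs of
core variants, credible sets with core leads).  Cores partition the
chromosome, so every variant is reported exactly once with ≥ 1 Mb of
flanking LD context except at chromosome ends; the first/last windows
extend their cores to the ends.  Enrichment weights are estimated once
from the pooled core signal PIPs of the flat pass, then every window is
re-fitted with the shared informed prior.

## Synthetic data generator

The simulator emulates the biobank-scale single-locus design end to end:

- **Genotypes** — per haplotype, a latent Gaussian with AR(1) correlation
  `ld_decay`^|i−j| (optionally block-diagonal) thresholded at per-variant
  MAF quantiles (MAF ~ U(0.05, 0.5)); dosage = sum of two haplotypes.
  Thresholding attenuates correlation, so the returned theoretical LD is
  computed on the dosage scale from bivariate-normal orthant
  probabilities (Owen's T); the empirical LD of simulated dosages matches
  it within 0.05 at N = 10,000.
- **Annotations** — M = 10 binary columns with prevalence ~ U(0.10, 0.30)
  plus a shared 10% core set (each annotation includes a core member with
  probability ½) to induce the pairwise overlap seen in real annotation
  panels; 5 columns are enriched, 5 null by default.
- **Causal variants** — K distinct variants sampled with probability
  ∝ exp(A_g ᵀ w_sim), where w_sim carries the enrichment log-odds W at the
  enriched annotations; W = 0 reduces to uniform sampling.
- **Trait** — causal effects standard normal on standardized dosages, the
  genetic component rescaled to sample variance exactly h², independent
  Gaussian noise scaled to exactly 1 − h².  The noise is *not*
  orthogonalized against the genetic component: doing so suppresses noise
  along causal directions and biases the heritability estimator downward.
- **GWAS** — per-variant univariate regression t-statistics (simulated
  samples are unrelated, so no mixed model is needed) and in-sample LD.

Defaults are the full-scale design: N = 353,570 individuals, per-locus
h² = K × 1e-4, i.e. per-causal-variant noncentrality N·h²/K ≈ 35.4
(|z| ≈ 6).  `SimulationConfig.reduced(n, g)` produces desk-scale
configurations that preserve this noncentrality by raising h² as N
shrinks — the noncentrality, not N or h² separately, controls
fine-mapping difficulty, so reduced runs probe the same statistical
regime at a fraction of the cost.  Tests use n = 25,000 (or less) with
G = 150–300 variants per locus.

What the generator does **not** emulate: realistic MAF spectra and LD
blocks estimated from real panels, population structure and relatedness,
imputation error, mismatched (out-of-sample) LD references, binary
traits.  Passing tests therefore demonstrate correctness of the
algorithms under the model's assumptions plus thresholded-Gaussian LD;
they do not certify behavior under LD mismatch or confounding.

## Numerical choices

- Selection scores are normalized with max-subtracted exponentials; priors
  with zero mass propagate −∞ scores safely.
- Credible-set ties: γ descending, then |z| descending, then index.
- LD files are symmetrized as (R + Rᵀ)/2 when asymmetry ≤ 1e-8 and
  rejected beyond that; diagonals must be 1 within 1e-6.
- Strand-ambiguous variants (A/T, C/G) are dropped during allele
  harmonization rather than frequency-resolved, since summary statistics
  need not carry allele frequencies; allele swaps flip the z sign.
- Mixed per-variant N collapses to the median (one N per locus enters the
  precision updates).
- AUPRC uses tie-grouped thresholds and trapezoidal integration anchored
  at (recall 0, precision of the top tie group), under which a constant
  ranking scores exactly the prevalence.
- Coverage over zero reported credible sets is reported as missing, not
  1: an empty report makes no coverage claim.

## Known limitations

- **Mid-range PIP conservatism.**  On the reduced-scale locus design
  (K = 5 causals among 200 variants, N = 25,000), variants with PIP in
  0.2–0.8 are causal somewhat more often than their PIP states (observed
  minus expected precision ≈ +0.1, ranging 0.04–0.16 per bin over 800
  simulated loci), while the bottom and top bins are calibrated to within
  0.03 and credible-set coverage is 0.99+.  Controlled experiments
  attribute this to two compounding sources.  (i) Multi-effect inference:
  with model-matched Gaussian effects the bias persists at K = 5 but the
  single-effect fit (K = 1, provably equal to exact enumeration) reduces
  it, implicating the mean-field treatment of multiple effect groups.
  (ii) Effect-size-prior mismatch: the generator (like standard GWAS
  simulation pipelines) rescales effects so the realized heritability is
  exact, concentrating effect magnitudes relative to the model's Gaussian
  prior; even exact single-effect Bayes shows a residual ≈ +0.1 bias in
  the 0.6–0.8 bin under that design.  Conservative mid-range PIPs err on
  the safe side for variant prioritization but understate evidence for
  marginal signals; per-bin calibration error on this design should be
  expected near 0.1 rather than 0.
- Weight estimates from sparse causal mass attenuate toward zero when
  causal variants fall in mutual LD (one effect group absorbing two
  causal variants); genome-wide (sparse-causal) designs are unaffected.
- The G-test treats annotations marginally (1 df each); heavily
  overlapping annotations share credit only in the joint weight
  estimates, not in the screen.
- The local-heritability floor (1e-6) makes τ_β enormous on truly null
  loci; this is intentional (effects shrink to zero) but means ĥ² near
  the floor should not be interpreted as an estimate.
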