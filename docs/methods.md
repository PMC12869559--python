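# Methods

`cardiocc` analyses a pair of binary disorders whose common-variant
architectures sit at opposite ends of one genetic spectrum, modelled on
dilated (DCM-like) and hypertrophic (HCM-like) cardiomyopathy.  Everything is
built on summary statistics; individual-level data appear only in the
synthetic cohorts used for polygenic-score evaluation and as simulation
oracles.

## Liability-threshold model and effect scales

Each disorder is a latent standard-normal liability exceeding the threshold
τ = Φ⁻¹(1−K) at population prevalence K.  Per-standardized-genotype effects
move between three scales:

* **liability** β_l — effect on the latent liability;
* **case-control (log-odds)** d = β_l·φ(τ)/(K(1−K)) — the standardized mean
  genotype difference between cases and controls, equal to the per-SD
  log-odds ratio under the small-effect approximation;
* **delta** δ = β_l·φ(τ)/K = d·(1−K) — the standardized mean genotype
  deviation of *cases from the population*, the natural scale for case-case
  contrasts.

Heritabilities transform quadratically between scales
(`cardiocc.models`); the observed↔liability conversion uses the standard
K²(1−K)²/(φ(τ)²·P(1−P)) factor with P the sample case fraction.

## Synthetic data (the study conditions)

`SimulationConfig` defaults encode the target study: prevalences 0.4% and
0.2%; liability heritabilities 14.2% and 18%; 9,365 / 1,199,156 and 5,900 /
68,359 cases/controls; cross-disorder rg −0.58; three quantitative
endophenotypes (MRI-like, n = 36,083) whose causal effects correlate 0.793,
0.711 and −0.668 with the case-case axis; and 3,400 shared controls, chosen
so the induced sampling correlation of effect estimates is ≈0.012.  The
variant panel is scaled to desk size: 50,000 variants with 1,200 causal
(matching the study's ~1,223 effectively independent causal variants), chosen
so the full simulation plus estimation runs in seconds.

Causal liability effects are bivariate normal with per-trait variance
h2/m_causal and correlation rg.  Marginal z-scores are

    z = √(n_eff/4) · (R d) + ε,   ε ~ N(0, R),

with R block-compound-symmetric.  Block sizes cycle deterministically through
{0.2, 0.6, 1.0, 1.4, 1.8}× the mean size, interleaved with runs of
singleton (LD-free) variants: LD-score regression needs spread in l_j to
separate slope from intercept, and the singletons anchor the intercept (the
intercept SE drops ~8× versus uniform blocks).  LD scores are therefore known
in closed form, l_j = 1 + (block_size−1)ρ², and ship with the data — no
external reference panel is ever read.

Shared controls induce a per-variant cross-trait noise correlation
c = n_shared/√(n_ctrl_a·n_ctrl_b).  This closed form is the simulation's
definition of overlap (the quantity the bivariate intercept must recover);
it is intentionally simpler than overlap formulas for real designs, which
also involve case fractions.

What the generator does **not** emulate: realistic human LD (block CS only),
frequency-dependent architecture, X chromosome, imputation error,
population stratification in the summary statistics, or case/control
misclassification.  Passing tests therefore demonstrate internal consistency
of the estimators under the stated model, not robustness to real-data
pathologies.

Individual-level cohorts draw binomial dosages at the configured frequencies
(optionally with an ancestry gradient loaded on latent factors returned as
PC covariates), compute liabilities from the same truth effects, and
threshold at the disease prevalences.  Ascertained case-case cohorts are
produced by batched rejection sampling on liabilities computed from causal
genotypes only, with non-causal genotypes filled in afterwards — exact and
fast at prevalences of a few per mille.

## Heritability and genetic correlation

`estimate_h2` regresses χ² on N·l_j/M (N = n_eff/4 for binary traits, n for
quantitative ones); the slope is the heritability on the z-score calibration
scale, the intercept captures confounding/overlap.  Weights are the standard
heteroskedasticity form 1/(l_j(1+x_j·ĥ²)²) from a first-pass unweighted fit;
`weighted=False` gives the oracle-checkable unweighted fit.  SEs come from a
delete-one jackknife over ≤100 contiguous super-blocks of LD blocks, with
weights held fixed across replicates (the jackknife is over data, not
tuning).  `estimate_rg` runs the analogous cross-product regression; rg is
re-formed within each jackknife replicate so its SE propagates both
heritabilities.  rg(a, a) is exactly 1 because all three regressions share
the same weighting rule.

The regional scan is a deliberately simple method-of-moments stand-in for a
full local-correlation decomposition: per region, h² = M_r·Σ(χ²−1)/Σ(N·l)
with a null variance computed exactly from the known block correlation
(var 2 per variant, cov 2ρ² per within-block pair), and regional genetic
covariance analogously with the global bivariate intercept subtracted.  The
two-stage multiplicity scheme is Bonferroni over tested regions (both traits
must pass), then Bonferroni over retained regions, both two-sided — the
study's scheme (0.05/2,495 then 0.05/101 at its region counts).

## Case-case reconstruction

`to_delta_scale` converts per-allele log-odds effects to the delta scale:
δ = β·√(2p(1−p))·(1−K), var = se²·2p(1−p)·(1−K)².  The ordinary case-case
statistic is δ̂_A − δ̂_B with variance var_A + var_B − 2·c·√(var_A·var_B),
c the error covariance (bivariate intercept).  The exact statistic applies
weights w_i = √(s_A·s_B)/s_i with s_i = φ(τ_i)/K_i, so that a variant with
equal *liability-scale* effects in both disorders — a "stress" variant that
is shared risk, not subtype signal — has expectation exactly zero.  When the
prevalences coincide (s_A = s_B) the two paths are identical; when they
differ, the ordinary path acquires a bias proportional to β(s_A−s_B) that
inflates its type-I error at large n, which is precisely the calibration
property the stress-test simulations verify (ordinary path inflated, exact
path ≤1.5× nominal at α = 0.05 over ≥2,000 replicates).  Both paths are
emitted side by side with a `flag_stress` marker where their genome-wide
conclusions disagree; downstream stages consume the exact path.

F_ST,causal — the expected squared standardized case-group frequency
difference per causal variant — is (h2δ_A + h2δ_B − 2·rg·√(h2δ_A·h2δ_B))
/m_causal with h2δ = h2_l·(φ(τ)/K)², validated against a forward simulation
that realizes case-group genotype means through the liability model.  At the
study parameterization (K 0.004/0.002, h2 0.142/0.18, rg −0.56, m 1223) this
gives ≈3.9×10⁻³.

## Multi-trait update

Secondary traits are admitted at |rg| ≥ 0.65 with the target.  All traits
are reduced to standardized effects β̂ = z/√N with sampling covariance
Σ/√(N_iN_k); Σ has unit diagonal and the pairwise bivariate intercepts off
the diagonal (clipped into [−0.95, 0.95] and shrunk toward the identity if
needed — the intercepts are weakly identified at desk-scale M, and the clip
is logged).  Ω is method-of-moments from the LD-score slopes (gencov/M per
pair, h²/M on the diagonal), projected to the PSD cone by eigenvalue
clipping with the Frobenius distance recorded.  The per-variant update is
the GLS combination with weight vector ω_t/ω_tt; it reduces to the input for
a single trait or diagonal Ω and Σ, and to inverse-variance meta-analysis
when genetic effects are perfectly proportional.  The effective-sample-size
gain is reported as the mean-χ² ratio mapped through the standard N scaling
and labelled an approximation.  A maximum-FDR computation over latent
architectures is out of scope.

## Shared-effect meta-analysis

Stage 1: remove variants whose log SE-ratio deviates from the median by more
than k = 3 MAD-scaled robust SDs (a parameter-light, brute-force-checkable
stand-in for the original precision-outlier rule, which is not specified in
the main text; the rule is swappable), then fixed-effects inverse-variance
pooling.  Stage 2: for variants with p_FE < 1e-4, two-study
DerSimonian–Laird τ² and the random-effects p; p_final = max(p_FE, p_RE), so
the substitution is conservative by construction.

## Loci and genes

Fine-mapping is single-causal Wakefield ABF per LD block (prior SD 0.2 on
the log-odds scale, coverage 0.95, computed in log space): pips are
normalized ABFs, the credible set is the smallest pip-ranked set reaching
coverage, regions without a genome-wide-significant variant yield no set,
and numerical failure falls back to a flagged single-variant set.  This
replaces multi-signal fine-mapping deliberately — it is exact and
dependency-free, at the cost of one set per region.  Top-variant ties break
by pip, then p, then position (the last purely for determinism).

Loci are single-linkage merges of index variants within 1 Mb on a
chromosome; bounds come from member index-variant positions and ids are
`chrom:start-end` in genomic order.  Consolidation pools index variants
across studies, re-merges, carries the union of sources, and flags a locus
novel iff no reference study contributed.  Ids are deterministic per input
but not stable across different inputs.  Gene nominations (locus × study ×
method) are upstream inputs; each contributes 0.5 points, leads are the
top-scoring gene(s) per locus, and every gene within 1.0 point of the top is
retained as a joint candidate.

## Polygenic scores

The score builder is clump+threshold (best p first, suppress neighbours
within 250 kb, keep p < 5×10⁻⁸ by default) — a stand-in that exercises the
evaluation machinery, not a genome-wide Bayesian method.  Standardization
follows the ancestry-robust recipe: residualize on PCs, model log squared
residuals linearly on PCs (positivity by construction) to get a
PC-predicted SD, divide, then z-score.  Discrimination metrics per contrast:
OR per SD from a logistic model with covariates (PCs always; age/sex when
requested; Wald CI; perfect separation detected and flagged with an
unbounded CI), univariate AUC and AUPRC with seeded bootstrap CIs (2,000
resamples by default), Nagelkerke pseudo-R² gain over the covariate-only
model, and liability-scale R² gain from the observed-scale OLS R² gain via
the Lee factor K²(1−K)²/(φ(τ)²P(1−P)).  At K = P = 0.5 that factor is π/2
(the probit attenuation), which the property test asserts in closed form.
Score orientation is always recorded explicitly rather than sign-flipped.

## Replication

Binomial tails are exact (`scipy.stats.binom.sf`), matching exhaustive
enumeration to full precision for n ≤ 25.  One-sided replication p-values
orient the replication z by the discovery sign, p = 1 − Φ(z·sign_disc).
Allele-frequency enrichment uses one-sided Fisher exact tests on allele
counts (two per individual); effect agreement reports the Pearson r and the
regression slope, with the z-score variant as a sensitivity output.
Untestable variants are counted, never imputed.

## Numerical choices and limitations

* Problem sizes: 50k variants / 1,200 causal for correlation analyses, 40k
  independent variants for null calibration, 4,000 stress replicates, 3,000
  variants × ~1,200 individuals for the cohort experiment — chosen so each
  analysis completes in seconds while leaving Monte-Carlo error well inside
  the stated tolerances.
* z wins over p when both are present and inconsistent beyond 1e-3 relative;
  p is rebuilt from z.
* The regional scan's stage-2 null variance is an approximation (plug-in
  mean χ² scaling); at Bonferroni thresholds the occasional noise region can
  pass, which the drivers report rather than hide.
* Exact case-case weights guarantee the zero-expectation contract in the
  infinite-precision limit; finite-sample calibration is established by the
  stress simulations, not assumed.
* All randomness flows from explicit seeds; byte-identical regeneration with
  a fixed seed is tested.
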