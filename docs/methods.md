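# Methods

## Generative model

Each of *m* variants carries a raw non-HDL-C effect magnitude
*t<sub>v</sub>* = |N(μ₁, σ₁)| + |N(μ₂, σ₂)| (mg/dL per allele; defaults
σ₁ = 1.2 for the LDL component and σ₂ = 0.6 for the TRL component) and a
TRL share *s<sub>v</sub>* ~ Beta(0.5, 0.5), giving

  β<sub>TRL-C,v</sub> = s<sub>v</sub>·t<sub>v</sub>,
  β<sub>LDL-C,v</sub> = (1 − s<sub>v</sub>)·t<sub>v</sub>.

The U-shaped share spectrum produces many near-pure variants in either
pathway plus a mixed middle, so a 10-way ranking spans TRL:LDL effect
ratios from below 0.2 (set 1) to above 3 (set 10). The listed effect
allele is the raising allele for a random half of variants, as in real
GWAS output; orientation is part of the analysis, not the data.

ApoB tracks the two cholesterol pools through fixed conversion factors
a<sub>L</sub> = 0.77 and a<sub>T</sub> = 0.63 mg/dL apoB per mg/dL
particle-class cholesterol (an LDL particle pool of ~130 mg/dL
cholesterol carries ~100 mg/dL apoB; TRL remnants are slightly
cholesterol-enriched per particle). The AAA log-odds is linear in the
two pathway-specific apoB components:

  logit P(AAA) = β₀ + θ<sub>L</sub>·apoB<sub>L</sub>/10 +
  θ<sub>T</sub>·apoB<sub>T</sub>/10 + age/sex/PC terms,

with defaults θ<sub>L</sub> = ln 1.10 and θ<sub>T</sub> = ln 1.89 per
10 mg/dL pathway apoB — the study conditions all recovery runs use.
These defaults imply a per-particle (per-apoB) TRL:LDL ratio of 6.68 and
a per-cholesterol ratio of
(θ<sub>T</sub>a<sub>T</sub>)/(θ<sub>L</sub>a<sub>L</sub>) = 5.46.

Two further generator choices deserve note:

- **Intercept interpretation.** The outcome model uses
  allele-frequency-centred genetic components, so `baseline_logodds`
  (default −3.5) is the log-odds at the population-mean genetic apoB
  and controls prevalence (~5–7% with the default covariate effects,
  matching a veterans-cohort AAA case fraction). Lipid phenotypes
  themselves use the plain `effect x dosage` form; centring only moves
  the intercept and cannot change any per-unit effect.
- **Derived lipids.** TC is constructed as LDL-C + TRL-C + HDL-C, so
  non-HDL-C = TC − HDL-C and TRL-C = non-HDL-C − LDL-C hold exactly on
  every record. With Gaussian lipid noise a few percent of records
  derive a negative TRL-C; they are kept, flagged invalid, and excluded
  from GWAS fitting — deliberately mirroring the measurement-error
  reality of subtraction-derived remnant cholesterol rather than
  silently truncating.

Two-sample summary statistics report the true betas plus Normal noise at
`exposure_se_scale` (default 0.05 mg/dL; the exposure GWAS is treated as
very large) and an outcome beta equal to the causal combination plus
Normal noise at `outcome_se_scale` (default 0.05, also the reported SE).
Triglyceride betas are 5x the TRL-C betas (remnant cholesterol ≈ TG/5),
giving the significance filter a third lipid trait. Lipoprotein(a)
associations are emulated by planting 28 variants at the LPA locus with
near-zero Lp(a) p-values; background variants are Lp(a)-null.

LD is block-diagonal exchangeable: background blocks of 4 variants with
allele correlation ρ = 0.35 (r² ≈ 0.12, above the 0.1 pruning
threshold), cis-region blocks with ρ = 0.25 (below it, so gene regions
keep several instruments). Dosages realise this through a Gaussian
copula on the two allele draws; the pruning reference uses the nominal
block r². True betas are drawn independently of LD — LD exists to
exercise pruning, not to model tagging.

### EHR phenotyping

Latent cases receive two AAA codes (ICD-9 441.3/441.4, ICD-10
I71.3/I71.4) on separate dates, except a 5% minority who receive one
code only; 4% of non-cases receive some other vascular-disease code;
irrelevant codes are sprinkled on 30% of everyone. Classification is:
case = two or more AAA-code occurrences; comparator = no AAA code and
no code in ICD-9 440–448, ICD-10 I71–I75, I77–I79 or K55 (range
membership by prefix-numeric comparison on the category part);
everything else — including the single-AAA-code stratum, which the
case/comparator definitions leave unclassified — is excluded.

## Estimators

All summary-level estimators weight by 1/se<sub>out</sub>²:

- **IVW**: no-intercept WLS; one variant reduces exactly to the Wald
  ratio. The multiplicative random-effects SE multiplies the
  fixed-effect SE by √max(1, Q/(k−1)) — floored at 1 so CIs never
  become anti-conservative.
- **MR-Egger**: WLS with intercept after orienting each variant to a
  non-negative exposure beta; RE scaling on k−2 df; the intercept and
  its SE are the directional-pleiotropy diagnostic.
- **Weighted median**: Wald ratios ordered, weights ∝ inverse
  first-order ratio variance, linear interpolation of the midpoint
  cumulative weights at 0.5; SE from a seeded parametric bootstrap
  (default 1,000 draws) of the outcome (and exposure, when its SE is
  nonzero) betas.
- **MR-PRESSO**: observed residual sum of squares about closed-form
  leave-one-out IVW fits, compared with its parametric simulation
  distribution (default 1,000 draws, vectorised); per-variant outlier
  p-values Bonferroni-adjusted at 0.05; outliers removed and IVW
  re-run. The distortion field reports the relative difference between
  corrected and uncorrected estimates; no distortion p-value is
  computed. On outlier-free data the corrected estimate is bit-identical
  to plain IVW.
- **MVMR**: two-column no-intercept WLS with RE scaling on k−2 df; the
  full 2x2 coefficient covariance feeds the per-cholesterol ratio CI.

Ratios of log-odds ratios use the first-order delta method; the
set-10/set-1 ratio assumes independence (disjoint variant sets), the
MVMR ratio uses the joint covariance. A denominator within 2 SE of zero
flags the ratio unstable (CI still reported). The symmetric delta CI
tracks a 10⁶-draw Monte-Carlo ratio CI to within 5% relative width when
the denominator is at ≥10 SE from zero; at ~4.5 SE (the set-1 log-OR
under default conditions) the true ratio distribution is visibly
right-skewed and ~15–20% wider — the delta interval is the package's
documented, slightly narrow, convention. Mean-of-ratios across
replicates is biased upward by denominator noise, so recovery checks
compare ratios of mean log-ORs.

Instrument selection order is significance (p < 5x10⁻⁸ in any of TG,
TRL-C, LDL-C) → greedy LD pruning in descending combined magnitude
√(β²<sub>LDL</sub> + β²<sub>TRL</sub>) within a 20 Mb window at
r² ≥ 0.1 → MAF > 0.01 → Lp(a) exclusion at p < 0.05/m (m = candidates
tested). The ranking statistic is the bounded TRL share rather than the
raw TRL:LDL ratio, which explodes as β<sub>LDL</sub> → 0; the two agree
in ordering wherever both betas are positive. Zero-denominator variants
are excluded from ranking with a warning. Uneven k-splits give earlier
sets the extra variant; ties in share order by variant id. The cis
window is gene ± 200 kb (configurable); APOC3 and APOA5 overlap at this
flank and share instruments.

Individual-level analyses: scores are Σ dosage·β<sub>apoB</sub>/10
(one unit = 10 mg/dL apoB), with PLINK-style allele alignment when the
weight's effect allele is the cohort's other allele. Logistic models
adjust for age, sex and PC1–10; non-convergence (separation) is an
explicit failure. The interaction contrast is computed by
g-computation: predicted probabilities averaged over the empirical
covariate distribution at the 25th/75th percentile anchors of score A,
with score B moved one unit from its 25th-percentile anchor;
IC = [p(hiA, B+1) − p(hiA, B)] − [p(loA, B+1) − p(loA, B)]. The CI is a
percentile bootstrap over individuals (default 1,000 resamples,
anchors recomputed per resample).

## What the generator does and does not emulate

It emulates: a spectrum of pathway-mixed lipid variants with
allele-oriented summary statistics, LD structure sufficient for
pruning, planted cis regions and an Lp(a) locus, covariate-confounded
lipids, a rare binary outcome with logistic pathway effects, and noisy
EHR phenotyping. It does **not** emulate reference-panel LD or tagging
(true betas are LD-independent), population stratification (PCs carry
no signal by default), right-skewed lipid distributions, pleiotropy
beyond the two lipid pathways, or selection/survival bias. Passing
tests therefore demonstrate that the statistics recover what they claim
under the model's own assumptions — not that those assumptions hold in
any real cohort.

Two behaviours of the correctly-working pipeline are worth flagging.
First, the extreme variant sets are near- but not perfectly pure: set 1
retains a ~2% mean TRL share, which lifts its per-apoB estimand several
percent above the pure-pathway θ<sub>L</sub>, so recovery checks
compare against the generator-implied estimand rather than the pure
planted value. Second, because the generative outcome model is
multiplicative with no product term, the additive-scale interaction
contrast between two PRSs is genuinely (slightly) positive — risk
differences grow with baseline risk — so a small positive IC with a CI
excluding zero in a large cohort is correct behaviour, not a defect.
The multiplicative interaction p-value is uniform under this truth.

## Problem sizes and reproducibility

Recovery runs use 150 replicates of 1,360 independent candidate
variants (10 ranked sets of 136, mirroring a 1,357-variant instrument
set split ten ways), at which the Monte-Carlo SE of every recovered
mean is below 5% of its planted value; the individual-level statistics
use one 80,000-person cohort (~5% cases), with 200 bootstrap resamples
for the IC. The full selection cascade is exercised on a 4,000-variant
LD-structured pool in the analysis drivers and pipeline tests. All
randomness flows from a single seed through named substreams
(truth/cohort/summary draws are independent streams of the config
seed; pipeline stages hash the global seed with the stage name), so
every output — including the JSON results bundle — is byte-reproducible
under a fixed seed.

## Known limitations

- Delta-method ratio CIs are symmetric and mildly narrow for weak
  denominators (see above); Fieller intervals are not implemented.
- MR-PRESSO's distortion test is reported without a p-value.
- Logistic non-collapsibility means a per-set PRS coefficient is
  attenuated a few percent relative to the summary-level estimand when
  the omitted sets carry large independent effects; at the default
  sizes this is well inside Monte-Carlo noise.
- The weighted-median bootstrap and MR-PRESSO simulation counts are
  pragmatic defaults (1,000), exposed as flags, not derived quantities.
- VCF output stores dosages at 3 decimals; round-trips are exact to
  5x10⁻⁴.
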