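# Methods

## The pulse-chase renewal model

Rod outer segments renew by adding discs at the base and shedding them at
the tip. A heat-shock pulse marks the disc layer formed at induction; in
fixed tissue the stripe position yields two distances per rod, the
base-to-stripe growth distance D^G and the stripe-to-tip shedding distance
D^S. With rod birth at `birth_dpf`, induction at `heatshock_dpf` and
fixation at `fix_dpf` (defaults 3/6/10 dpf) and a pre-induction growth
rate `pre_rate` (default 1.6 µm/day, from untreated fish reared on the
same 14/10 light cycle), the forward model is

    D^G = g · T,        D^S = pre_rate · P − s · T,

with T the chase duration (4 days), P the pre-induction growth window
(3 days), and g, s the post-induction growth and shedding rates. The
model assumes both rates are constant over the chase and ignores
within-day (circadian) shedding structure — D^S is a *net* quantity, so
g and s are average rates, not event-level ones.

`expected_distances` floors D^S at 0 (a stripe cannot lie beyond the tip)
and flags the truncation; `infer_rates` inverts the model from mean
distances and reports a negative shedding rate with a flag instead of
clamping it, so simulation → inference round trips expose calibration
errors rather than hiding them. The `suppression_equivalent` helper
converts a percent increase of the D^S benchmark into shedding terms:
with the pooled control benchmark D^S = 3.40 µm, +20 % (4.08 µm) halves
the 1.4 µm shed during the chase (0.72 µm, 0.18 µm/day).

**Benchmark dispersion.** The pooled control benchmark reports its SD
across *fish-level* means, because the fish is the unit of replication in
this design; rod-level mean/SD are also exposed (`rod_mean`, `rod_sd`).
The published pooled dispersion does not state which level it refers to;
fish-level is this package's choice, and both are available. SD is
defined as 0 for a single fish (flagged `single_fish`).

**Percent-change reporting.** Calling uses full-precision model
estimates; only reporting rounds, to the nearest integer percent with
halves away from zero. Recomputing published per-compound percentages
from their (already rounded) printed group means reproduces almost all of
them exactly; two differ by one point, which is the expected artefact of
rounding the means first.

## The per-week mixed model

Each screening week is fitted separately: rods nested in fish, one fixed
effect per treatment group (cell-means coding, the shared vehicle control
first),

    y_lir = β_l + b_i + e_lir,   b_i ~ N(0, τ²),   e_lir ~ N(0, σ²).

Estimation is restricted maximum likelihood (REML), the standard default
of the mixed-model software family used for this design; REML rather
than ML because the fixed-effect count (up to 33 groups) is not small
relative to the number of fish. The implementation profiles the variance
ratio θ = τ²/σ²: at fixed θ the fixed effects are generalized least
squares — each group estimate is the precision-weighted combination of
its fish means with weights n_i/(1 + θ n_i) — and σ² has a closed-form
profile estimate, leaving a 1-D search over θ ∈ [0, 10⁶]. The search is
bounded golden-section/parabolic (`scipy minimize_scalar`, xatol 1e-10)
followed by a polish step that root-finds the *analytic* derivative of
the profiled restricted deviance (Brent, xtol 1e-14); the polish is what
lets the balanced-design fits agree with the ANOVA closed forms to ~1e-14
instead of the ~1e-8 a derivative-free search can reach. θ = 0 is checked
explicitly, so a negative between-fish moment truncates cleanly to τ̂² = 0
(flagged `tau_truncated`, standard practice). Constant data floor σ² at
1e-12 with a `degenerate_variance` flag. A fish appearing under two
treatments is a hard `LineageError`.

All likelihood quantities are accumulated per fish (Woodbury identities
for the compound-symmetric blocks), so a fit costs O(#fish) per
evaluation regardless of rod counts.

**Degrees of freedom.** Contrast df use the Satterthwaite approximation,
the convention of the lmerTest family: df = 2·Var(c'β̂)² / (∇'A∇), where
∇ is the gradient of the contrast variance in (τ², σ²) (central finite
differences, boundary-safe at τ² = 0) and A = 2H⁻¹ with H the
finite-difference Hessian of the restricted deviance. When τ̂² = 0 the df
collapses to the OLS residual df (rods − levels) exactly; a singular H
falls back to fish − levels, flagged. The df is clipped to
[1, rods − levels]. Finite differencing leaves ~1e-4-level noise in the
df, which is immaterial at the tail probabilities involved.

**Standard-error convention.** Fixed-effect covariance is the GLS form
σ̂²(X'V̂⁻¹X)⁻¹, matching lme4's `vcov()`. statsmodels' MixedLM reports
SEs from the joint observed-information Hessian instead, which differs
by O(1/#fish) (~0.5 % here); the test suite therefore checks estimates
and variance components against statsmodels but SEs against lme4.

## Dunnett many-to-one comparisons

For each week and metric, every compound is compared with the shared
control. Contrast correlations under cell-means coding have the
one-factor form ρ_ij = λ_i λ_j with λ_i = sqrt(W_i/(W_i+W_0)) (W the GLS
group weights; λ = sqrt(n/(n+n₀)) in the balanced case). The two-sided
adjusted p for contrast i is

    p_adj,i = 1 − Pr(max_j |T_j| ≤ |t_i|)

under the k-variate central t with that correlation and a common df —
the minimum Satterthwaite df across the week's contrasts, a conservative
tie-break so that one joint distribution serves all contrasts. The
multivariate *t* (not normal) is used because fish-level replication is
small; above df 500 the normal limit is taken.

The equicoordinate probability is evaluated by seeded scrambled-Sobol
quasi-Monte-Carlo (default 2×10⁵ points in 8 scramble replicates; the
reported `mc_error` is three standard errors across replicates, and
results are bitwise deterministic for a given seed). When the correlation
matrix is one-factor — always true for the shared-control design — the k
idiosyncratic coordinates are integrated analytically conditional on the
common factor and the chi scale, leaving a smooth 2-D integrand with
mc_error ~1e-6 at default settings; arbitrary PSD matrices fall back to
direct sampling of the coordinate maximum. A single contrast uses the
exact univariate t tail (p_adj = p_raw, mc_error 0). Comparisons are
two-sided throughout; no step-down refinement or FDR is applied, matching
the screen's single-step tier ladder (***(p<0.001), **(p<0.01),
*(p<0.05), boundaries exclusive).

## Hit calling

A **primary** call requires |percent change| ≥ 20 (non-strict, "at least
20 %") *and* p_adj < 0.001 (strict). Below primary, p_adj < 0.05 keeps a
signed **tiered** label. A non-primary result whose direction matches an
existing primary hit *for the same molecular target* anywhere in the
screen is promoted to **same-target-followup**, provided it clears at
least the weakest tier (p_adj < 0.05); this precedence (primary >
follow-up > tiered) is the package's interpretation of "other compounds
with the same target that similarly affected" the metric — the source
phrasing does not quantify "similarly", so the criterion is documented
here rather than hidden. Direction semantics for shedding are recorded on
the output: an *increased* D^S means shedding was *suppressed*, a
*decreased* D^S means it was *promoted*.

Qualitative content areas use the at-least-one-image rule (three central
retina images for phagosome accumulation and Rhodopsin mislocalization;
one image for the ciliary marginal zone). Pathway tallies count
non-lethal compounds whose call matches a content area, ordered by count
then label; unannotated compounds count under "unannotated". A compound
annotated for the screen but contributing no measurement rows (no
surviving fish) is marked lethal and excluded from every tally. A week
without exactly one control group is a hard error naming the week.

## The synthetic-screen generator

The generator emulates the screen's data structure with known truth:

- **week/clutch baseline**: each week draws its growth and shedding rates
  Normal around the control rates (1.25 and 0.35 µm/day) with `week_sd`
  applied on the distance scale (default 0.55 µm);
- **fish intercepts**: Normal(0, `fish_sd`²), default 0.35 µm, drawn
  independently per metric;
- **rod noise**: Normal(0, `rod_sd`²), default 1.0 µm, distances floored
  at 0 and stored to 4 decimals (the file format's resolution);
- **design**: 8–32 compounds per week plus one vehicle control, 3 fish
  per group, 33–149 D^G rods per fish; the shedding distance is observed
  for a uniformly drawn 24–105 subset of each fish's rods (capped at the
  fish's rod count), with the observed subset chosen uniformly at random —
  exchangeable across rods and independent of treatment. A per-rod
  dropout rate would reproduce the same marginal independence but cannot
  guarantee the observed count range, so the count-first construction was
  chosen;
- **effects**: multiplicative on rates, so a growth multiplier m is a
  true (m−1)·100 % D^G change regardless of week baseline. Note the
  asymmetry for shedding: D^S = 4.8 − 1.4·m µm at the nominal baseline,
  so a shedding-rate multiplier of 0.65 moves D^S only +14 % — shedding
  effects need to be strong (m near 0 or ≥ 2) to cross the 20 % distance
  threshold;
- **lethality**: Bernoulli(0.3) per compound, independent of effect size
  (whether lethality correlated with potency in reality is unknown);
  lethal compounds appear in truth/annotations but contribute no rows;
- **qualitative flags**: Bernoulli per image; controls and null compounds
  use a 2 % per-image rate (an occasional stray flag, so the at-least-one
  rule is exercised without making nulls hits systematically).

The variance split (0.55/0.35/1.0 µm) is a calibrated assumption: the
study-wide control dispersion is only published as a pooled value
(≈0.65 µm), and sqrt(0.55² + 0.35²) ≈ 0.652 µm reproduces it at the
fish level while keeping weekly control means in the published ~4–6.2 µm
range. Real data surely deviate (e.g. non-Gaussian rod noise, fish
effects correlated between metrics, measurement missingness tied to
stripe visibility at the tip); passing tests therefore demonstrate the
pipeline's correctness under this hierarchical Gaussian emulation, not
distributional claims about real retinas.

Randomness is a single seeded generator with child streams keyed on
(seed, week), so any week is reproducible in isolation and whole-screen
output is bitwise stable for a given seed.

## Simulation-study sizes and operating characteristics

Two studies characterize the full pipeline (`rodscreen.validation`);
their sizes are the package's own choices:

- **null screen**: 500 independent all-null weeks, 8 compounds/week,
  reduced rod counts (12–20 D^G, 9–15 D^S per fish). The measured
  primary-call rate is ~0 (the joint ≥20 % + family-wise p<0.001 rule is
  extremely conservative under the null); 8-compound families are the
  conservative end for a false-positive check since Dunnett's adjustment
  only tightens with family size.
- **effect recovery**: 200 weeks at the generator's default design —
  including the 8–32 weekly batch size, because the number of fish in a
  week drives the Satterthwaite df and hence power at p < 0.001 — with
  one +35 % and one −35 % growth-rate compound per week among nulls.
  Recovery of primary calls is ~85–94 % depending on seed. Recovery is
  defined on the growth metric; see the shedding asymmetry above for why
  ±35 % *rate* changes are not a meaningful shedding recovery target.

Both studies, and the Dunnett QMC inside them, run at reduced
quasi-Monte-Carlo sizes (2×10⁴ points) where integration error (~1e-5) is
negligible against the decision thresholds.

## Numerical choices

- Profiled-θ search bounds [0, 10⁶]; xatol 1e-10; derivative polish
  xtol 1e-14; τ² truncation at 0 flagged.
- Contrast SEs floored at 1e-12 (noise-free synthetic fixtures would
  otherwise divide by zero).
- QMC: Sobol with owner-seeded scrambling, 8 replicates, points rounded
  up to a power of two per replicate; chi-square quantile via inverse
  CDF; normal CDF/quantile via `ndtr`/`ndtri`. Correlation matrices are
  validated (symmetry, unit diagonal) and factored with escalating jitter
  (0 → 1e-8) before an eigenvalue-clipping PSD fallback; matrices with
  eigenvalues below −1e-8 are rejected.
- One-factor detection: least-squares fit of log λ on log |ρ_ij|,
  accepted when the reconstruction error is ≤ 1e-9 and all λ < 1 − 1e-9.
- Percent-change confidence intervals use the delta method on the ratio
  of independent group means with a t critical value at the contrast df.
- Config hashes are SHA-256 of the canonical (sorted-key) JSON dump,
  truncated to 12 hex digits — stable under key reordering.

## Known limitations

- One variance component only (fish); no random slopes, crossed effects
  or heteroscedastic residuals — the screen design is strictly nested.
- The Satterthwaite df uses finite differences of the deviance; extreme
  designs (2 fish total, near-degenerate variances) fall back to
  fish − levels.
- The same-target follow-up rule depends on annotation quality; compounds
  without target annotations can never be promoted.
- Percent-change CIs are delta-method approximations; they are used for
  simulation diagnostics, not for hit calling.
- The generator does not simulate images; qualitative flags are Bernoulli
  stand-ins for the visual assessment.
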