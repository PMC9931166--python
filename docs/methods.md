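# Methods

## The task being modeled

An adjusting-amount discounting session presents binary choices between a
smaller cheap reward and a larger reward of fixed amount A = 3,000
carrying a cost X. Three cost dimensions are supported, each with five
levels:

* **delay** — 2 weeks, 2 months, 6 months, 1 year, 3 years, encoded in
  days as 14, 60, 180, 365, 1095 (month = 30 d, year = 365 d,
  configurable). The calendar words have no unique day-count; any
  monotone encoding leaves ordinal analyses unchanged and perturbs the
  raw-axis AUC only slightly.
* **probability** — chances of 90, 75, 50, 25, 10 %, analyzed as odds
  against receipt, θ = (1 − p)/p = 1/9, 1/3, 1, 3, 9. Odds are held at
  full precision internally; 0.11 and 0.33 are display roundings.
* **effort** — walking durations of 10, 20, 60, 90, 120 minutes. Step
  counts shown to a participant are their calibrated steps-per-minute
  times the duration (`effort_costs`), but the analysis axis is the
  duration, which is common across participants.

### Titration

The staircase starts at A/2 and, after trial t, adjusts the offer by
A/2^(t+1) — up if the larger costly reward was chosen, down otherwise —
for six trials (adjustments 750, 375, 187.5, 93.75, 46.875 at A = 3,000).
Displayed/recorded offers are rounded half-up to whole units; internal
state is exact (a round-then-adjust variant exists behind a flag for
sensitivity checks). The **indifference point** is the rounded offer
presented on the sixth trial (`ip_rule="sixth_offer"`). The wording "the
amount on the sixth and final choice" admits a second reading — apply the
final halving adjustment after the sixth choice — so that rule is
available as `post_final_adjustment`; the default is documented rather
than guessed as the only possibility. For any deterministic agent with a
fixed subjective value v\* of the larger reward, the staircase guarantees
|IP − v\*| ≤ A/2⁶ + 0.5 (binary-search geometric series plus recording
rounding); the 2⁵ possible choice paths map bijectively onto 2⁵ distinct
final offers.

## Synthetic cohorts

The generator emulates a three-session repeated-measures design
(defaults: 23 participants × 3 time points × 3 tasks × 5 levels × 6
trials = 6,210 choices). Its statistical structure:

* **Trait layer.** Each participant's discounting rate b per task is
  lognormal: log b ~ Normal(log b₀(task), σ_trait). Default medians
  b₀ are 0.01/day (delay), 1.0 per unit odds-against (probability), and
  0.03/min (effort) — values that put typical ordinal AUCs mid-range for
  the default schedules, in line with commonly reported magnitudes for
  monetary rewards of this size.
* **State layer.** At each session the trait rate is perturbed
  multiplicatively, b_session = b_trait · exp(ε), ε ~ Normal(0, σ_state).
  The multiplicative-lognormal form keeps b positive; nothing stronger is
  claimed for it than being the simplest trait/state decomposition on a
  positive parameter.
* **Choice layer.** The probability of taking the larger reward is
  logistic in the subjective-value difference scaled by τ·A, so the
  temperature τ is currency-scale-free. τ = 0 is the deterministic argmax
  with ties broken toward the smaller/certain/easier option. Power-form
  agents floor subjective value at 0 during simulation (a negative value
  is behaviorally meaningless); model *fitting* always uses the raw
  formula.
* **Defaults** σ_trait = 0.8, σ_state = 0.4, τ = 0.1 are illustrative,
  not estimates: they produce moderate-to-good ICCs (≈ 0.55–0.8 across
  tasks and seeds) and moderate-to-strong retest correlations, i.e. the
  regime the analysis pipeline is meant to distinguish. No published
  effect sizes for the trait/state split exist to calibrate against.
* **Seeds.** A master seed spawns per-participant, per-session, and
  per-trial-block streams (`numpy.random.SeedSequence`), so the same
  master seed reproduces tables bit-for-bit and subsets are independent.

What the generator does **not** emulate: demographic covariates,
session-order or fatigue effects, inattentive/lexicographic responders,
and any drift in walking calibration. Passing recovery tests therefore
shows the pipeline is correct and well-conditioned under its own
assumptions, not that real cohorts satisfy them.

## AUC and ordinal AUC

IPs are divided by A; the cost axis is either raw costs divided by the
maximum cost or ranks 1..5 divided by 5 (**ordinal**); a zero-cost anchor
(x = 0, y = 1) is prepended so five IPs form five trapezoids and the
measure spans [0, 1]. Without the anchor five points cover at most 4/5 of
the axis; the documented 0–1 range of the ordinal measure is what forces
the anchor choice, and a flag (`anchor=False`, `anchor_y`) exists because
the effort task's cheap option is not literally zero-cost. The trapezoid
sum equals dense numeric integration of the piecewise-linear interpolant
to machine precision, and the ordinal variant is invariant under any
strictly monotone re-encoding of the costs. Only the ordinal AUC feeds
the stability statistics; the raw-axis AUC is computed and exported for
completeness.

## Model comparison

The three value functions are fitted to **per-level median IPs** (median
across participants; even counts take the central midpoint), not to
individuals. IPs are normalized by A before fitting, so RSS — and hence
AICc — is amount-invariant; absolute AICc values therefore depend on this
scale convention and only the differences Δᵢ are comparable across
conventions. The parameter count includes the error variance: k = 2
(hyperbolic), k = 3 (hyperboloid, power), a stated convention. Fitting is
bounded multi-start nonlinear least squares (trust-region reflective): b
starts on a 12-point log grid 10⁻⁶–10², s ∈ {0.25, 0.5, 1, 2, 4}, bounds
b ∈ (10⁻¹², 10⁶), s ∈ (0.01, 10], tolerances 10⁻¹⁴; no randomness, so
fits are reproducible. RSS = 0 yields AICc = −∞ with a warning. Support
bands for Δ: ≤ 2 substantial, (2, 7] considerably less, (7, 10] little,
> 10 essentially none — the published convention leaves (2, 4) and
(7, 10) unlabeled, and the merge above follows the usual reading of those
guidelines. Ties in the minimum AICc resolve toward the model with fewer
parameters.

## Stability statistics

**Bayes-factor correlations.** BF₁₀ for a nonzero population correlation
uses the exact sampling density of the sample correlation r given ρ and
n (hypergeometric form) under the stretched-beta prior on ρ with width
κ = 1 (uniform on (−1, 1)), the two-sided default of standard Bayesian
software; the factor depends on the data only through (r, n). The
implementation integrates by adaptive quadrature with a convergence
check; the test suite keeps an independent dense-grid trapezoid
integrator as an oracle (agreement to 10⁻⁶ relative) — the two routes are
never collapsed. The 95% interval reported is the central posterior
interval of ρ on a 20,001-point grid. The factor is symmetric in the sign
of r and increasing in |r| at fixed n.

**ICC.** The two-way mixed-effects absolute-agreement single-measure
coefficient is computed from the two-way ANOVA mean squares,
(MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n) — arithmetic shared
with the two-way random definition, which is why "mixed" and "random"
coincide computationally here. Confidence bounds use the F-based method
with a Satterthwaite denominator degrees-of-freedom approximation, the
standard choice when a CI is reported without a named method. On balanced
data the coefficient equals σ_b²/(σ_b² + σ_c² + σ_e²) with the ANOVA
component estimates, and it matches an independent reference
implementation (pingouin, ICC(A,1)) to 10⁻⁹.

**z-scoring scope.** AUC_ord values are standardized per task *pooled*
across all participant × timepoint observations, which preserves
between-session mean shifts so "absolute agreement" keeps its meaning;
per-timepoint standardization (available via `zscore_scope`) would erase
mean shifts and reduce absolute agreement to consistency. Published
descriptions rarely state which was used, so both are implemented and the
default documented rather than asserted as the original intent.

**Interpretation bands.** Correlations: |r| ≤ .35 weak, .36–.67 moderate,
.68–.9 strong, ≥ .9 very strong. Bayes factors: 0.3–3 weak, 3–10 moderate
H1, > 10 strong H1; values below 0.3 are mirrored (1/10–1/3 moderate H0,
< 1/10 strong H0) as an extension, since published bands cover only the
H1 side. ICC: < 0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good, > 0.90
excellent, with ICC × 100% read as the trait-like share of variance.

## Numerical and design notes

* Rounding of displayed offers is half-up (`floor(x + 0.5)`), matching
  how currency amounts are conventionally rounded, and avoiding the
  bankers'-rounding asymmetry at exact halves (e.g. 2812.5 → 2813).
* Degenerate inputs fail loudly: incomplete titration blocks are reported
  by key, constant vectors reject correlations and z-scores, missing ICC
  cells are never imputed, AICc with n − k − 1 < 1 is an error.
* Parameter-recovery checks use delay rates on a log grid spanning
  10⁻³·⁵–10⁻⁰·⁵ per day for *titrated* IPs — the range in which a
  six-trial staircase with A = 3,000 can resolve the implied values (the
  staircase quantizes IPs to a ±47 grid, so rates implying values below
  ~47 at every level are unidentifiable from titrated data by design) —
  and 10⁻³–10¹ per day for exact IPs, where recovery is to machine
  precision.
* Test problem sizes (cohorts of 5–23 participants, recovery grids of 12
  rates, 20-replicate Monte Carlo for variance components) are chosen so
  the full suite runs in well under a minute while keeping Monte-Carlo
  error far below the asserted tolerances.

## Known limitations

* The generator's choice noise is i.i.d. logistic across trials; real
  choice data show sequential dependencies the titration algorithm can
  amplify.
* Median-curve fitting (by design) says nothing about individual-level
  model identity; no per-participant fitting stage is provided.
* The effort task's nonzero-effort cheap option is approximated by the
  same zero-cost anchor as the other tasks; the `anchor_y` /
  `anchor=False` flags allow sensitivity analyses but no principled
  correction is attempted.
* Bayesian repeated-measures ANOVA of IPs is out of scope; absolute
  stability is addressed only through the ICC.
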