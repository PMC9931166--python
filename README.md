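# discountkit

Tools for simulating and analyzing **delay, probability, and effort
discounting** tasks of the adjusting-amount kind, aimed at behavioral
researchers studying how the subjective value of a reward falls as its
cost rises, and how stable those discounting patterns are across repeated
sessions.

The package covers the full path from raw binary choices to publication
statistics:

1. **Titration.** Each of five cost levels is probed with a six-trial
   staircase: the smaller, cheap offer starts at A/2 (A = 3,000 by
   default) and moves toward the point of subjective equality by halving
   adjustments (A/4, A/8, …, A/64). The offer presented on the sixth trial
   is the **indifference point** (IP).
2. **Synthetic cohorts.** Agents with trait-level discounting rates
   (lognormal across participants), session-level state perturbations,
   and logistic choice noise generate complete trial logs, so every
   downstream stage is testable without any external data.
3. **AUC.** The area under the IP-versus-cost curve, both with the raw
   normalized cost axis and the **ordinal** variant (costs replaced by
   ranks 1–5), computed by the trapezoid rule with a zero-cost anchor
   (x = 0, y = 1): `AUC = Σ (x₂ − x₁)·(y₁ + y₂)/2 ∈ [0, 1]`. Lower values
   mean steeper discounting.
4. **Model comparison.** Three candidate value functions fitted to
   per-level median IPs by bounded multi-start least squares —

   * hyperbolic  V = A / (1 + bX)
   * hyperboloid V = A / (1 + bXˢ)
   * power    V = A − bXˢ

   — and ranked by the small-sample Akaike criterion
   `AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` through the differences
   `Δᵢ = AICcᵢ − AICc_min` (Δ ≤ 2: substantial support; Δ > 10:
   essentially none).
5. **Stability.** *Relative* stability as between-session Pearson
   correlations with the default Jeffreys Bayes factor BF₁₀ for a nonzero
   population correlation (stretched-beta prior of width κ = 1, exact
   sampling density of r, adaptive quadrature), with 95% posterior
   intervals; *absolute* stability and a trait/state decomposition as the
   two-way absolute-agreement single-measure intraclass correlation
   `ICC = (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)` with
   F-based confidence bounds. ICC × 100% is read as the share of variance
   attributable to stable between-subject (trait-like) differences.

## Worked example

```python
from discountkit import (CohortSpec, simulate_cohort, extract_ips, auc_table,
                         DiscountingModel, StabilityAnalysis)

spec = CohortSpec(n_participants=23, n_timepoints=3, master_seed=42)
trials, truth = simulate_cohort(spec)     # 6,210 trial rows: 23 x 3 x 3 x 30
curves = extract_ips(trials)              # 207 five-point indifference curves

delay_t1 = [c for c in curves if c.task.value == "delay" and c.timepoint == 1]
print(DiscountingModel.from_curves(delay_t1, amount=3000).fit().summary())
```

```
Discounting model comparison (A = 3000, n = 5 levels)
model                   b        s          rss       AICc    dAICc  support
----------------------------------------------------------------------------
hyperbolic  *  0.00973508        1     0.026141     -16.27     0.00  substantial
hyperboloid     0.0342426   0.7436     0.014503       0.79    17.05  essentially none
power            0.140508   0.2682     0.024867       3.48    19.75  essentially none
* best model (smallest AICc)
```

The cohort was generated by hyperbolic agents with a median delay rate of
0.01/day, and the fit recovers that: the hyperbolic form wins (Δ = 0,
b̂ ≈ 0.0097/day); the hyperboloid halves the residual sum of squares but
pays a larger small-sample penalty, leaving it essentially unsupported.

```python
stability = StabilityAnalysis(auc_table(curves, 3000)).fit()
print(stability.summary())
```

```
Intraclass correlations (absolute agreement, single measures)
task             ICC  95% CI          band        % trait-like
delay           0.73  [0.54, 0.86]    moderate    73%
effort          0.81  [0.66, 0.91]    good        81%
probability     0.59  [0.35, 0.78]    moderate    59%
```

With the default trait spread (0.8 on the log scale) exceeding the state
spread (0.4), most ordinal-AUC variance is between subjects — the ICCs
land well above 0.5, i.e. trait-like differences dominate. The same
results object carries the pairwise test–retest correlations with their
Bayes factors (e.g. delay sessions 1 vs 2: r = 0.75, BF₁₀ ≈ 826, strong
evidence for a relationship).

A command-line pipeline wraps the same stages:

```sh
discountkit run-all --seed 42 --out results/
# -> trials.csv, truth.csv, ips.csv, auc.csv, fits.json, stability.json, report.md
```

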