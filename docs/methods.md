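# Methods

## Generative model

One simulated "study" is a balanced two-group between-subjects
experiment. The true effect of study *i* is θᵢ = θ + δᵢ with
δᵢ ~ N(0, τ²); given θᵢ, each participant contributes two outcome
measures (dv1, dv2) with within-group population SD 1, population
correlation ρ = 0.8, and a group-2 mean shift of θᵢ on both. Sex is
assigned by a fair coin, independently of everything else. The analysis
of a study is the standardized mean difference with the Hedges
small-sample correction,

```
d = (m₂ − m₁)/s_p,   g = J·d,   J = 1 − 3/(4·df − 1),   df = n₁+n₂−2
v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))
```

with a pooled-variance (Student) two-tailed t-test for the p-value.
Pooled-variance rather than Welch matches the large-sample v formula
above and the convention of SMD meta-analysis; groups are
variance-homogeneous by construction, so nothing hinges on it.

## Sample sizes

Total study sample sizes N (both groups, split equally) are drawn from
a calibrated stand-in for an empirical distribution of which only three
summaries are known: median 100, IQR 176, mean 123. The stand-in is a
log-normal with μ = ln 100 and σ = asinh(0.88)/z₀.₇₅ = 1.17708 — which
pins the median and IQR exactly — **winsorized** to [10, 247.6] and
rounded to the nearest even integer. The cap is the unique solution of
E[min(X, cap)] = 123; a conditionally truncated log-normal cannot match
all three summaries at once (matching median + IQR forces a truncated
mean ≥ 144 for any admissible cap). The winsorized model is exact on
all three summaries but puts ~22% of its mass at the cap and has no
studies above N = 248 — a caricature of the real distribution's tail.

Consequence worth knowing: for a fixed mean N, the expected
fixed-effect weight E[1/v] ≈ E[N]/4 is pinned, which bounds the
attainable I² at a given τ. With mean N = 123 the grid-average I² at
τ = 0.33 is ~71% no matter how the rest of the distribution is shaped
(even a degenerate all-N-equal model only reaches ~72%). Published
translations of the same τ grid that report ~78% imply an effective
mean N around 150+; we keep the printed mean and accept the lower I²
(the τ = 0.33 acceptance check documents this as an expected failure).
An `empirical-list` mode accepts a real N distribution (one even
integer per line) and removes the issue entirely.

## p-hacking

Researchers come in three archetypes: no hacking; optional DVs +
optional stopping; all four strategies. Environments mix them as
none = (1, 0, 0), medium = (0.30, 0.50, 0.20), high = (0.10, 0.40,
0.50). A hacking researcher enumerates every candidate analysis —
DV ∈ {dv1, dv2} × subset ∈ {all, females, males} × outliers
∈ {kept, removed} as licensed by the archetype (12 analyses for
all-four) — at each peek. Optional stopping adds 10% of the starting N
(rounded to the nearest even integer, minimum 2) per peek up to
max N = min(5·start, 200); when the start already exceeds the cap, no
extension is possible. Outlier removal drops values with |z| ≥ 2
within group, subset and DV, in a single pass (note the within-group z
is bounded by (n−1)/√n, so groups of ≤5 can never lose a point).

Selection uses a score: the plain p-value under a two-tailed regime; or
a "modified p" under a one-tailed regime, equal to p for
expected-direction results and 1 + (1 − p) otherwise, so a
wrong-direction result can never beat any expected-direction one.
Collection stops when the best score drops below .05 (wrong-direction
significance therefore does not stop collection under a one-tailed
regime) or the peeking schedule is exhausted; the analysis with the
smallest score — significant or not — is the single submitted result.
Ties (possible only at machine precision) resolve by a fixed
enumeration order. The reported sample size of a published study is the
number of participants in the *selected analysis* (what a meta-analyst
would code from the paper); a switch reports collected participants
instead.

## Publication bias

Two-tailed p < .05 in the expected direction always publishes. Under a
one-tailed regime, significant wrong-direction results are always
censored; under two-tailed they publish like any significant result.
Non-significant results publish with probability 1 − strength,
strength ∈ {0, .4, .8}, independently per study. Because a one-tailed
regime censors wrong-direction significance even at strength 0, the
package exposes a separate publish-everything regime for all
"absence of bias" analyses. Literatures are built by generating
researcher → study → censoring until exactly k studies survive; the
generated count is recorded for censoring-rate diagnostics.

## Estimators

All five τ² estimators are written from scratch and truncate negative
solutions at zero:

* **DL**: (Q − (k−1)) / (Σw − Σw²/Σw), w = 1/v (moment equation at
  fixed-effect weights).
* **HS**: (Q' − k)/Σw with Q' the weighted SS around the FE pooled mean.
* **PM**: τ² solving the generalized-Q equation Σ wᵢ(τ²)(gᵢ − θ̂(τ²))² =
  k − 1; the left side is strictly decreasing in τ², so Brent's method
  on an expanding bracket (tol 1e-10) always converges.
* **ML / REML**: the standard fixed-point iterations
  τ² ← Σw²[(g − θ̂)² − v]/Σw² (+ 1/Σw for REML), w = 1/(v + τ²), θ̂
  re-profiled each cycle; start at the DL value, tolerance 1e-8 on
  successive τ², max 100 iterations; non-convergence is reported, and
  the experiment engine regenerates such replicates (counting them).
  Note the minus sign on v in the numerator: only that form is a
  stationary point of the (restricted) log-likelihood, which the test
  suite verifies against brute-force grid maximization.

Inference on the pooled effect uses the Knapp-Hartung variance
Σw(g − θ̂)²/((k−1)Σw) with a t(k−1) reference, **without** the
truncate-at-1 modification of the adjustment factor (the default of the
standard reference implementation). The τ confidence interval is the
Q-profile interval: bounds where the generalized Q meets the
χ²(k−1) 0.025/0.975 quantiles, truncated at zero — the same interval
for every estimator, which is why per-estimator τ-coverage columns
coincide. I² is Q-based: max(0, (Q − (k−1))/Q)·100.

Frozen reference values from metafor 4.8-0 (`rma(..., test="knha")`,
`confint`) pin the whole fit to an independent implementation at 1e-6
or better.

## Experiment engine

The six factors (hacking, tail, strength, τ, θ, k) cross into 1,440
cells; each cell runs `reps` meta-analyses, fitting all five estimators
to the *same* literatures (paired comparison, so estimator contrasts
are not diluted by simulation noise). Per-cell summaries: mean T,
T_bias, T_sd, T_rmse, d_bias, θ/τ coverage, KH rejection rate,
Monte-Carlo error T_sd/√reps, mean published N, replicates replaced.
Seeding: a root seed plus the cell index feed a `SeedSequence`; each
replicate gets a spawned child stream, so any cell is bit-reproducible
in isolation and independent of scheduling.

The balanced-design ANOVA computes every term's SS by
inclusion-exclusion over marginal means on the dense factor grid;
orders ≥ 4 pool into Error. On a balanced grid the terms sum to the
corrected total exactly (a property test checks all 63 terms of a 2⁶
grid at 1e-9). The observation unit is the per-cell mean, matching the
corrected totals of the study being reproduced.

## Problem sizes

The original experiment (1,440 cells × 1,000 replicates with
participant-level hacking) is cluster-scale. The package's own default
analyses are sized for a single CPU: the unbiased recovery grid runs
400–500 replicates per τ × k condition; the factorial ANOVA run crosses
all levels of five factors with k ∈ {9, 36} at 15 replicates per cell
(720 cells), enough for the volatility ordering and the additivity of
hacking and censoring, which are driven by between-cell structure, not
replicate noise; the acceptance script uses ~2,000 meta-analyses per
I²/type-I quantity and 500 for the worst-case effect-inflation cell.
All sizes are flags, so any analysis scales up by argument.

## Known limitations

* The sample-size stand-in matches three summaries, not the real shape;
  I²-type quantities inherit its mean (see above), and stopping-rule
  headroom (how many studies can extend to 5× start or 200) inherits
  its body. Use the `empirical-list` mode when the real distribution is
  available.
* Only two-group balanced designs with continuous outcomes; no binary
  outcomes, unequal allocation, or cluster designs.
* The p-hacking menu is the four strategies above; no covariate
  hacking, researcher learning, or effect-size-contingent censoring.
* If nothing is significant when data collection ends, the smallest
  selection score is submitted — one of several defensible readings of
  "the smallest p-value is submitted", and the one that keeps the
  submitted-result distribution continuous across the significance
  boundary.
* Coverage of the τ interval is reported per estimator but is the same
  Q-profile interval for all; estimator-specific τ intervals (e.g.
  profile-likelihood for REML) are not implemented.
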