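# hetsim

Monte-Carlo evaluation of random-effects heterogeneity estimators for
meta-analyses of standardized mean differences, in research environments
distorted by **publication bias** and **p-hacking**.

## The problem

A meta-analysis pools study effects θ̂ᵢ under the random-effects model

```
θᵢ = θ + δᵢ,          δᵢ ~ N(0, τ²)     (between-study heterogeneity)
θ̂ᵢ = θᵢ + εᵢ,         εᵢ ~ N(0, σᵢ²)    (sampling error)
θ̂  = Σ wᵢ θ̂ᵢ / Σ wᵢ,  wᵢ = 1/(σᵢ² + τ̂²)
```

τ (the SD of true effects across studies) must be estimated, and many
τ² estimators exist: DerSimonian-Laird (DL), Hunter-Schmidt (HS),
maximum likelihood (ML), Paule-Mandel (PM) and restricted maximum
likelihood (REML). Their performance is usually benchmarked on
*unbiased* simulated literatures. Real literatures are not unbiased:
non-significant studies go unpublished, and researchers run many
analyses but report the one with the smallest p-value. This package
simulates that world from the participant level up — two-group
experiments, four p-hacking strategies (optional dependent variables,
optional stopping, optional moderators, optional outlier removal),
significance-contingent censoring (one- or two-tailed) — and measures
what each estimator then reports for τ and what the Knapp-Hartung test
of the pooled effect does to type-I error.

Who it is for: methodologists studying meta-analytic bias, and anyone
who wants a transparent, seedable sandbox in which "publication bias +
p-hacking → published literature → random-effects fit" is a one-liner.

## Worked example

Fit all machinery on a small literature (CSV with `effect,variance`
columns):

```bash
$ hetsim fit studies.csv --estimator REML
estimator      REML
k              6
tau2_hat       0.092984
tau_hat        0.304933
tau 95% CI     [0.000000, 0.984020]
theta_hat      0.312417
KH se          0.163873
KH t           1.9065
KH p           0.114906
KH 95% CI      [-0.108831, 0.733666]
Q              12.7242
I^2            60.70%
converged      True
```

τ̂ ≈ 0.30 says the true effects are estimated to spread with SD 0.30
around the pooled θ̂ = 0.31; I² ≈ 61% attributes most of the observed
spread to real heterogeneity rather than sampling error; the
Knapp-Hartung p of 0.11 does not reject θ = 0 with only 6 studies.
(These numbers agree with the metafor R package to ~1e-6.)

Simulate a biased literature and meta-analyse it in Python:

```python
import numpy as np
from hetsim import ENVIRONMENTS, BiasRegime, MetaSample, fit
from hetsim import sample_published_literature

rng = np.random.default_rng(7)
lit = sample_published_literature(
    k=18, theta=0.0, tau=0.22,
    environment=ENVIRONMENTS["high"],        # 50% of researchers use all
    regime=BiasRegime("one", 0.8), rng=rng)  # four p-hacking strategies;
                                             # 80% 1-tailed censoring
f = fit(MetaSample(lit.g, lit.v), "DL")
print(f.theta_hat, f.kh_p)   # a "significant" effect of ~0.3-0.4
                             # where the true effect is exactly zero
```

## Analysis scripts

Numbered drivers under `analysis/` rerun the study's analyses at desk
scale and write tidy tables under `results/`:

1. `01_sample_sizes.py` — the calibrated sample-size distribution
   (median 100, IQR 176, mean 123) actually used everywhere.
2. `02_unbiased_recovery.py` — estimator bias/RMSE, I² translation and
   τ-interval coverage with no bias of any kind.
3. `03_bias_grid.py` — the fully crossed six-factor experiment
   (scaled down) plus the balanced ANOVA that ranks estimator
   volatility (PM most volatile, DL most inert).
4. `04_inference.py` — published-N shifts, type-I error and effect
   inflation under censoring.

The full factorial grid is also available as `hetsim simulate
--config ... --filter "tau=0,0.33 k=9,18"`.

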