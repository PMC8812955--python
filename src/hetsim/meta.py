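"""Random-effects meta-analysis fitted from scratch.

Implements five heterogeneity-variance (tau^2) estimators --
DerSimonian-Laird (DL), Hunter-Schmidt (HS), maximum likelihood (ML),
Paule-Mandel (PM) and restricted maximum likelihood (REML) -- plus the
inverse-variance pooled effect, Knapp-Hartung inference on the pooled
effect, a Q-profile confidence interval for tau, and the Q-based I^2
statistic. All estimators truncate negative tau^2 solutions at zero.

The model: observed study effect g_i = theta + delta_i + eps_i with
delta_i ~ N(0, tau^2) (between-study heterogeneity) and
eps_i ~ N(0, v_i) (sampling error, v_i treated as known).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import stdtr

__all__ = [
    "ESTIMATORS", "MetaSample", "REFit",
    "tau2_dl", "tau2_hs", "tau2_pm", "tau2_ml", "tau2_reml",
    "pool_effect", "kh_inference", "tau_ci", "i_squared", "fit",
    "read_study_table", "write_study_table",
]

ESTIMATORS = ("DL", "HS", "ML", "PM", "REML")


@dataclass(frozen=True)
class MetaSample:
    """Study effects g_i with known sampling variances v_i."""

    g: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=np.float64)
        v = np.asarray(self.v, dtype=np.float64)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "v", v)
        if g.ndim != 1 or g.shape != v.shape:
            raise ValueError("g and v must be 1-d arrays of equal length")
        if g.shape[0] < 2:
            raise ValueError("need at least 2 studies")
        if np.any(v <= 0):
            raise ValueError("all sampling variances must be > 0")

    @property
    def k(self) -> int:
        return self.g.shape[0]


def _fe_stats(sample: MetaSample) -> Tuple[float, float, float, float]:
    """Fixed-effect weights summary: (Q, sum w, sum w^2, theta_FE)."""
    w = 1.0 / sample.v
    sw = w.sum()
    theta_fe = (w * sample.g).sum() / sw
    q = (w * (sample.g - theta_fe) ** 2).sum()
    return q, sw, (w * w).sum(), theta_fe


def tau2_dl(sample: MetaSample) -> float:
    """DerSimonian-Laird moment estimator (fixed-effect weights)."""
    q, sw, sw2, _ = _fe_stats(sample)
    denom = sw - sw2 / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (sample.k - 1)) / denom)


def tau2_hs(sample: MetaSample) -> float:
    """Hunter-Schmidt estimator: (Q - k) / sum(w) with w = 1/v."""
    q, sw, _, _ = _fe_stats(sample)
    return max(0.0, (q - sample.k) / sw)


def _gen_q(sample: MetaSample, tau2: float) -> float:
    """Generalized Q: weighted squared deviations at random-effects
    weights 1/(v + tau^2), with the pooled mean re-estimated."""
    w = 1.0 / (sample.v + tau2)
    theta = (w * sample.g).sum() / w.sum()
    return float((w * (sample.g - theta) ** 2).sum())


def tau2_pm(sample: MetaSample, tol: float = 1e-10,
            max_iter: int = 200) -> Tuple[float, bool]:
    """Paule-Mandel estimator: tau^2 solving Q_gen(tau^2) = k - 1.

    Q_gen is strictly decreasing in tau^2, so the root is found by
    monotone bracketing; returns 0 when Q_gen(0) <= k - 1.
    """
    target = sample.k - 1
    if _gen_q(sample, 0.0) <= target:
        return 0.0, True
    hi = 1.0
    while _gen_q(sample, hi) > target:
        hi *= 4.0
        if hi > 1e7:  # pragma: no cover - unreachable for finite data
            return hi, False
    root = optimize.brentq(lambda t2: _gen_q(sample, t2) - target,
                           0.0, hi, xtol=tol, maxiter=max_iter)
    return float(root), True


def _ml_like_fixed_point(sample: MetaSample, restricted: bool,
                         tol: float, max_iter: int) -> Tuple[float, bool, int]:
    g, v = sample.g, sample.v
    tau2 = max(tau2_dl(sample), 0.0)  # moment start
    for it in range(1, max_iter + 1):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        theta = (w * g).sum() / sw
        w2 = w * w
        new = (w2 * ((g - theta) ** 2 - v)).sum() / w2.sum()
        if restricted:
            new += 1.0 / sw
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new, True, it
        tau2 = new
    return tau2, False, max_iter


def tau2_ml(sample: MetaSample, tol: float = 1e-8,
            max_iter: int = 100) -> Tuple[float, bool]:
    """Maximum-likelihood estimator via the standard fixed-point
    iteration tau^2 <- sum w^2 [(g - theta)^2 - v] / sum w^2 with
    w = 1/(v + tau^2) and theta re-estimated each cycle."""
    tau2, converged, _ = _ml_like_fixed_point(sample, False, tol, max_iter)
    return tau2, converged


def tau2_reml(sample: MetaSample, tol: float = 1e-8,
              max_iter: int = 100) -> Tuple[float, bool]:
    """Restricted maximum-likelihood estimator; the fixed point adds the
    1/sum(w) term that removes the degrees-of-freedom loss from
    estimating the pooled effect."""
    tau2, converged, _ = _ml_like_fixed_point(sample, True, tol, max_iter)
    return tau2, converged


def pool_effect(sample: MetaSample, tau2: float
                ) -> Tuple[float, np.ndarray]:
    """Inverse-variance pooled effect under weights 1/(v_i + tau^2)."""
    w = 1.0 / (sample.v + tau2)
    theta = float((w * sample.g).sum() / w.sum())
    return theta, w


def kh_inference(sample: MetaSample, tau2: float, theta_hat: float,
                 alpha: float = 0.05
                 ) -> Tuple[float, float, float, Tuple[float, float]]:
    """Knapp-Hartung test/CI for the pooled effect.

    Var(theta_hat) = sum w_i (g_i - theta_hat)^2 / ((k-1) sum w_i) with
    random-effects weights; reference t distribution with k - 1 df. The
    small-sample adjustment factor is not truncated at 1.
    """
    w = 1.0 / (sample.v + tau2)
    df = sample.k - 1
    var = float((w * (sample.g - theta_hat) ** 2).sum() / (df * w.sum()))
    se = np.sqrt(var)
    if se == 0.0:
        return 0.0, 0.0, 1.0, (theta_hat, theta_hat)
    t = theta_hat / se
    p = float(2.0 * stdtr(df, -abs(t)))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return float(se), float(t), p, (theta_hat - tcrit * se,
                                    theta_hat + tcrit * se)


def tau_ci(sample: MetaSample, level: float = 0.95,
           tol: float = 1e-10) -> Tuple[float, float]:
    """Q-profile confidence interval for tau.

    Bounds are the tau^2 values at which the generalized Q statistic
    equals the chi-square(k-1) upper/lower tail quantiles, truncated at
    zero, then returned on the tau (SD) scale.
    """
    df = sample.k - 1
    alpha = 1.0 - level
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df)  # lower bound equation
    q_lo = stats.chi2.ppf(alpha / 2.0, df)        # upper bound equation

    def solve(target: float) -> float:
        if _gen_q(sample, 0.0) <= target:
            return 0.0
        hi = 1.0
        while _gen_q(sample, hi) > target:
            hi *= 4.0
        return float(optimize.brentq(
            lambda t2: _gen_q(sample, t2) - target, 0.0, hi, xtol=tol))

    lo2 = solve(q_hi)
    hi2 = solve(q_lo)
    return float(np.sqrt(lo2)), float(np.sqrt(hi2))


def i_squared(sample: MetaSample) -> float:
    """Q-based I^2 (%): share of between-study variability beyond
    sampling error, truncated to [0, 100]."""
    q, _, _, _ = _fe_stats(sample)
    if q <= 0.0:
        return 0.0
    return float(max(0.0, (q - (sample.k - 1)) / q) * 100.0)


@dataclass
class REFit:
    """One estimator's fitted random-effects model."""

    estimator: str
    tau2_hat: float
    theta_hat: float
    weights: np.ndarray
    kh_se: float
    kh_t: float
    kh_p: float
    kh_ci: Tuple[float, float]
    tau_ci: Optional[Tuple[float, float]]
    q_statistic: float
    i_squared: float
    converged: bool

    @property
    def tau_hat(self) -> float:
        return float(np.sqrt(self.tau2_hat))


_TAU2_FUNCS = {
    "DL": lambda s: (tau2_dl(s), True),
    "HS": lambda s: (tau2_hs(s), True),
    "ML": tau2_ml,
    "PM": tau2_pm,
    "REML": tau2_reml,
}


def fit(sample: MetaSample, estimator: str = "REML", alpha: float = 0.05,
        with_tau_ci: bool = True) -> REFit:
    """Fit the random-effects model with the chosen tau^2 estimator."""
    est = estimator.upper()
    if est not in _TAU2_FUNCS:
        raise ValueError(f"unknown estimator {estimator!r}; "
                         f"choose from {ESTIMATORS}")
    tau2, converged = _TAU2_FUNCS[est](sample)
    theta, w = pool_effect(sample, tau2)
    se, t, p, ci = kh_inference(sample, tau2, theta, alpha=alpha)
    q, _, _, _ = _fe_stats(sample)
    tci = tau_ci(sample) if with_tau_ci else None
    return REFit(estimator=est, tau2_hat=float(tau2), theta_hat=theta,
                 weights=w, kh_se=se, kh_t=t, kh_p=p, kh_ci=ci,
                 tau_ci=tci, q_statistic=float(q),
                 i_squared=i_squared(sample), converged=converged)


def read_study_table(path: str | Path | io.TextIOBase) -> MetaSample:
    """Read a study table CSV with columns effect,variance[,n1,n2]."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "effect" not in cols or "variance" not in cols:
        raise ValueError("study table needs 'effect' and 'variance' columns")
    return MetaSample(df[cols["effect"]].to_numpy(),
                      df[cols["variance"]].to_numpy())


def write_study_table(sample: MetaSample, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({"effect": sample.g, "variance": sample.v}).to_csv(
        path, index=False)
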