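"""Simulation of individual two-group experiments.

Generates participant-level data for between-subjects experiments under a
random-effects truth (true study effect ``theta_i ~ Normal(theta, tau^2)``)
and analyses them with the standardized mean difference (Hedges g) and a
pooled-variance two-sample t-test.

Study sample sizes come from a calibrated winsorized log-normal chosen to
match published summaries of sample sizes in psychology meta-analyses
(median total N = 100, IQR = 176, mean = 123), or from a user-supplied
empirical list of even integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import stdtr

__all__ = [
    "TrueWorld",
    "SampleSizeModel",
    "ParticipantTable",
    "StudyResult",
    "draw_sample_size",
    "draw_true_effect",
    "simulate_participants",
    "add_participants",
    "analyze_two_groups",
]

# Population correlation between the two dependent variables.
DV_CORRELATION = 0.8

# Calibrated sample-size family: log-normal with median 100 and IQR 176,
# winsorized to [10, cap] with the cap solving E[min(X, cap)] = 123.
# sigma = asinh(0.88) / Phi^{-1}(0.75); cap from a one-dimensional root solve.
_LOGN_MU = float(np.log(100.0))
_LOGN_SIGMA = 1.1770778568301313
_LOGN_CAP = 247.59426671979497
_MIN_N = 10


@dataclass(frozen=True)
class TrueWorld:
    """Generative truth of one simulated research field.

    theta is the average true standardized mean difference; tau the SD of
    true study effects around it (heterogeneity, in SMD units).
    """

    theta: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def draw_theta_i(self, rng: np.random.Generator) -> float:
        return draw_true_effect(self.theta, self.tau, rng)


class SampleSizeModel:
    """Distribution of total study sample sizes (both groups combined).

    Two modes:

    * ``calibrated`` (default): log-normal(mu=ln 100, sigma=1.17708)
      winsorized to [10, 247.6] and rounded to the nearest even integer.
      Matches median 100, IQR 176 and mean 123.
    * ``empirical``: draws uniformly from a supplied list of even integers
      (e.g. sample sizes coded from real meta-analyses).
    """

    def __init__(self, mode: str = "calibrated",
                 sizes: Optional[Sequence[int]] = None,
                 mu: float = _LOGN_MU, sigma: float = _LOGN_SIGMA,
                 cap: float = _LOGN_CAP, min_n: int = _MIN_N):
        if mode not in ("calibrated", "empirical"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.mu = mu
        self.sigma = sigma
        self.cap = cap
        self.min_n = min_n
        if mode == "empirical":
            if sizes is None or len(sizes) == 0:
                raise ValueError("empirical mode requires a non-empty size list")
            arr = np.asarray(sizes, dtype=np.int64)
            if np.any(arr < 4) or np.any(arr % 2 != 0):
                raise ValueError("empirical sizes must be even integers >= 4")
            self.sizes = arr
        else:
            self.sizes = None

    @classmethod
    def from_file(cls, path: str | Path) -> "SampleSizeModel":
        """Load an empirical list: one even integer per line, '#' comments."""
        sizes = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                sizes.append(int(line))
        return cls(mode="empirical", sizes=sizes)

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.sizes is not None:
            return self.sizes[rng.integers(0, len(self.sizes), size=size)]
        x = rng.lognormal(self.mu, self.sigma, size=size)
        x = np.clip(x, self.min_n, self.cap)
        n = 2 * np.round(x / 2)
        if size is None:
            return int(n)
        return n.astype(np.int64)


def draw_sample_size(model: SampleSizeModel, rng: np.random.Generator) -> int:
    """Draw one total sample size N (even; split N/2 per group)."""
    return int(model.draw(rng))


def draw_true_effect(theta: float, tau: float,
                     rng: np.random.Generator) -> float:
    """Draw theta_i ~ Normal(theta, tau^2); exactly theta when tau = 0."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if tau == 0:
        return float(theta)
    return float(theta + tau * rng.standard_normal())


@dataclass
class ParticipantTable:
    """Raw data of one experiment, in insertion order.

    group is 1 or 2; is_female a boolean; dv1/dv2 the two outcome
    measures (population SD 1 within group, correlation 0.8, group-2 means
    shifted by theta_i on both).
    """

    group: np.ndarray
    is_female: np.ndarray
    dv1: np.ndarray
    dv2: np.ndarray
    theta_i: float

    @property
    def n(self) -> int:
        return self.group.shape[0]


def _draw_rows(theta_i: float, n_per_group: int,
               rng: np.random.Generator):
    """Draw n_per_group rows for each of the two groups."""
    n = 2 * n_per_group
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = DV_CORRELATION
    dv1 = z1
    dv2 = rho * z1 + np.sqrt(1.0 - rho * rho) * z2
    group = np.empty(n, dtype=np.int8)
    group[:n_per_group] = 1
    group[n_per_group:] = 2
    shift = group == 2
    dv1 = dv1 + theta_i * shift
    dv2 = dv2 + theta_i * shift
    is_female = rng.random(n) < 0.5
    return group, is_female, dv1, dv2


def simulate_participants(theta_i: float, n_total: int,
                          rng: np.random.Generator) -> ParticipantTable:
    """Simulate a balanced two-group experiment with n_total participants."""
    if n_total % 2 != 0 or n_total < 4:
        raise ValueError(f"n_total must be even and >= 4, got {n_total}")
    group, is_female, dv1, dv2 = _draw_rows(theta_i, n_total // 2, rng)
    return ParticipantTable(group, is_female, dv1, dv2, float(theta_i))


def add_participants(table: ParticipantTable, increment: int,
                     rng: np.random.Generator) -> ParticipantTable:
    """Append `increment` new participants (split equally) from the same
    population; existing rows are unchanged."""
    if increment < 2 or increment % 2 != 0:
        raise ValueError(f"increment must be even and >= 2, got {increment}")
    group, is_female, dv1, dv2 = _draw_rows(table.theta_i, increment // 2, rng)
    return ParticipantTable(
        np.concatenate([table.group, group]),
        np.concatenate([table.is_female, is_female]),
        np.concatenate([table.dv1, dv1]),
        np.concatenate([table.dv2, dv2]),
        table.theta_i,
    )


@dataclass
class StudyResult:
    """One analysis outcome of one experiment.

    g is the bias-corrected SMD (Hedges g); v its estimated sampling
    variance; p the two-tailed pooled-variance t-test p-value; direction
    the sign of mean(group2) - mean(group1). descriptor records which of
    the candidate analyses produced the result:
    (dv, subset, outliers_removed, peek_index).
    """

    g: float
    v: float
    p: float
    direction: int
    n1: int
    n2: int
    descriptor: tuple = (1, "all", False, 0)
    valid: bool = True
    n_collected: int = 0

    @property
    def n_analyzed(self) -> int:
        return self.n1 + self.n2

    @property
    def significant(self) -> bool:
        return self.valid and self.p < 0.05


_INVALID = (np.nan, np.nan, np.nan, 0, False)


def _analyze(x1: np.ndarray, x2: np.ndarray):
    """Hedges g, its variance, two-tailed pooled t-test p, direction.

    Returns (g, v, p, direction, valid); hot path, no object creation.
    """
    n1 = x1.shape[0]
    n2 = x2.shape[0]
    if n1 < 2 or n2 < 2:
        return _INVALID
    m1 = x1.mean()
    m2 = x2.mean()
    ss1 = ((x1 - m1) ** 2).sum()
    ss2 = ((x2 - m2) ** 2).sum()
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    if sp2 <= 0.0:
        return _INVALID
    sp = np.sqrt(sp2)
    diff = m2 - m1
    d = diff / sp
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    ntot = n1 + n2
    v = ntot / (n1 * n2) + g * g / (2.0 * ntot)
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stdtr(df, -abs(t))
    direction = 1 if diff > 0 else (-1 if diff < 0 else 0)
    return float(g), float(v), float(p), direction, True


def analyze_two_groups(values_group1: Sequence[float],
                       values_group2: Sequence[float],
                       descriptor: tuple = (1, "all", False, 0)) -> StudyResult:
    """SMD analysis of two independent groups.

    Uses the Hedges small-sample correction J = 1 - 3/(4 df - 1) with
    df = n1 + n2 - 2, the large-sample SMD variance
    (n1+n2)/(n1 n2) + g^2 / (2 (n1+n2)), and a pooled-variance (Student)
    two-sample t-test, two-tailed. A zero pooled variance marks the
    analysis invalid.
    """
    x1 = np.asarray(values_group1, dtype=np.float64)
    x2 = np.asarray(values_group2, dtype=np.float64)
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("need at least 2 values per group")
    g, v, p, direction, valid = _analyze(x1, x2)
    return StudyResult(g=g, v=v, p=p, direction=direction,
                       n1=int(x1.shape[0]), n2=int(x2.shape[0]),
                       descriptor=descriptor, valid=valid,
                       n_collected=int(x1.shape[0] + x2.shape[0]))
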