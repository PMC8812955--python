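"""Questionable research practices: p-hacking strategies and result selection.

Four strategies are modelled, individually switchable per researcher:

* optional dependent variables -- two correlated outcomes, both analysed;
* optional stopping -- repeated peeks, adding 10% of the starting N each
  time, until significance or a maximum N (five times the starting N or
  200, whichever is lower);
* optional moderators -- analyses on all participants, females only and
  males only;
* optional outlier removal -- analyses with and without participants at
  |z| >= 2 within their group.

All candidate analyses of a study compete on a selection score: the plain
two-tailed p-value under a two-tailed publication regime, or a "modified
p" under a one-tailed regime that penalizes wrong-direction results as
1 + (1 - p). Only the analysis with the smallest score is submitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .studysim import (ParticipantTable, StudyResult, _analyze,
                       add_participants, simulate_participants)

__all__ = [
    "ResearcherProfile",
    "HackingEnvironment",
    "StoppingRule",
    "ENVIRONMENTS",
    "PROFILE_NONE",
    "PROFILE_DV_STOP",
    "PROFILE_ALL_FOUR",
    "enumerate_analyses",
    "remove_outliers",
    "modified_p",
    "run_hacked_study",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ResearcherProfile:
    uses_optional_dvs: bool = False
    uses_optional_stopping: bool = False
    uses_optional_moderators: bool = False
    uses_optional_outliers: bool = False

    @property
    def analyses_per_peek(self) -> int:
        return ((2 if self.uses_optional_dvs else 1)
                * (3 if self.uses_optional_moderators else 1)
                * (2 if self.uses_optional_outliers else 1))


PROFILE_NONE = ResearcherProfile()
PROFILE_DV_STOP = ResearcherProfile(uses_optional_dvs=True,
                                    uses_optional_stopping=True)
PROFILE_ALL_FOUR = ResearcherProfile(True, True, True, True)

_ARCHETYPES = (PROFILE_NONE, PROFILE_DV_STOP, PROFILE_ALL_FOUR)


@dataclass(frozen=True)
class HackingEnvironment:
    """Mixture of researcher archetypes in a simulated research field.

    Weights are over (no hacking, optional DVs + stopping, all four
    strategies).
    """

    label: str
    weights: tuple

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must be 3 probabilities summing to 1")

    def draw_profile(self, rng: np.random.Generator) -> ResearcherProfile:
        u = rng.random()
        w0, w1, _ = self.weights
        if u < w0:
            return PROFILE_NONE
        if u < w0 + w1:
            return PROFILE_DV_STOP
        return PROFILE_ALL_FOUR


ENVIRONMENTS = {
    "none": HackingEnvironment("none", (1.0, 0.0, 0.0)),
    "medium": HackingEnvironment("medium", (0.30, 0.50, 0.20)),
    "high": HackingEnvironment("high", (0.10, 0.40, 0.50)),
}


@dataclass(frozen=True)
class StoppingRule:
    """Peeking schedule for optional stopping.

    increment is 10% of the starting N rounded to the nearest even integer
    (minimum 2); max_n is min(5 * start_n, 200), but never below start_n.
    """

    start_n: int
    increment: int
    max_n: int

    @classmethod
    def for_start(cls, start_n: int) -> "StoppingRule":
        if start_n % 2 != 0 or start_n < 4:
            raise ValueError(f"start_n must be even and >= 4, got {start_n}")
        increment = max(2, 2 * round(start_n / 20))
        max_n = max(start_n, min(5 * start_n, 200))
        return cls(start_n=start_n, increment=increment, max_n=max_n)

    def peek_sizes(self) -> List[int]:
        sizes = [self.start_n]
        while sizes[-1] < self.max_n:
            sizes.append(min(sizes[-1] + self.increment, self.max_n))
        return sizes


def remove_outliers(values: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Drop values at or beyond `threshold` within-group SDs of the group
    mean (single pass; zero-SD groups define z = 0 and drop nothing)."""
    x = np.asarray(values, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return x
    z = np.abs(x - x.mean()) / sd
    return x[z < threshold]


def modified_p(p: float, direction: int, tail_mode: str) -> float:
    """Selection score of one analysis.

    Under a one-tailed regime, wrong-direction results score 1 + (1 - p),
    so no wrong-direction result can beat any expected-direction one.
    Under a two-tailed regime, the plain p-value is the score.
    """
    if tail_mode == "two":
        return p
    if tail_mode != "one":
        raise ValueError(f"tail_mode must be 'one' or 'two', got {tail_mode!r}")
    if direction > 0:
        return p
    return 1.0 + (1.0 - p)


# fixed descriptor order: dv1 < dv2, all < F < M, no-removal < removal
_SUBSET_ORDER = ("all", "F", "M")


def enumerate_analyses(table: ParticipantTable, profile: ResearcherProfile,
                       peek_index: int = 0) -> List[StudyResult]:
    """All candidate analyses of the current data under a profile.

    Cartesian product of DV choice x participant subset x outlier
    handling, in a fixed order (used for deterministic tie-breaking).
    Analyses that end up with fewer than 2 participants in either group
    are marked invalid.
    """
    dvs = (1, 2) if profile.uses_optional_dvs else (1,)
    subsets = _SUBSET_ORDER if profile.uses_optional_moderators else ("all",)
    outlier_opts = ((False, True) if profile.uses_optional_outliers
                    else (False,))

    g1 = table.group == 1
    n_collected = table.n
    results: List[StudyResult] = []
    for dv in dvs:
        values = table.dv1 if dv == 1 else table.dv2
        for subset in subsets:
            if subset == "all":
                m1, m2 = g1, ~g1
            elif subset == "F":
                m1 = g1 & table.is_female
                m2 = ~g1 & table.is_female
            else:
                m1 = g1 & ~table.is_female
                m2 = ~g1 & ~table.is_female
            x1 = values[m1]
            x2 = values[m2]
            for removed in outlier_opts:
                desc = (dv, subset, removed, peek_index)
                if x1.shape[0] < 2 or x2.shape[0] < 2:
                    results.append(StudyResult(
                        np.nan, np.nan, np.nan, 0, int(x1.shape[0]),
                        int(x2.shape[0]), desc, valid=False,
                        n_collected=n_collected))
                    continue
                y1, y2 = x1, x2
                if removed:
                    y1 = remove_outliers(x1)
                    y2 = remove_outliers(x2)
                    if y1.shape[0] < 2 or y2.shape[0] < 2:
                        results.append(StudyResult(
                            np.nan, np.nan, np.nan, 0, int(y1.shape[0]),
                            int(y2.shape[0]), desc, valid=False,
                            n_collected=n_collected))
                        continue
                g, v, p, direction, valid = _analyze(y1, y2)
                results.append(StudyResult(
                    g, v, p, direction, int(y1.shape[0]), int(y2.shape[0]),
                    desc, valid=valid, n_collected=n_collected))
    return results


def _best(results: List[StudyResult], tail_mode: str
          ) -> Optional[StudyResult]:
    """Valid analysis with the smallest selection score (first wins ties)."""
    best = None
    best_score = np.inf
    for r in results:
        if not r.valid:
            continue
        score = modified_p(r.p, r.direction, tail_mode)
        if score < best_score:
            best, best_score = r, score
    return best


def run_hacked_study(theta_i: float, start_n: int,
                     profile: ResearcherProfile, tail_mode: str,
                     rng: np.random.Generator,
                     max_regenerations: int = 100) -> StudyResult:
    """Run one experiment under a researcher profile and return the single
    result submitted for publication.

    Data are collected up to the stopping rule's peeking schedule (one
    single look for researchers without optional stopping).  At each peek
    every candidate analysis is run; the cycle stops as soon as the best
    selection score falls below 0.05 (under a one-tailed regime this
    requires an expected-direction result) or the maximum N is reached.
    The analysis with the smallest selection score at termination is
    submitted.
    """
    for _ in range(max_regenerations):
        result = _run_once(theta_i, start_n, profile, tail_mode, rng)
        if result is not None:
            return result
    raise RuntimeError("could not obtain a valid analysis after "
                       f"{max_regenerations} regenerations")


def _run_once(theta_i: float, start_n: int, profile: ResearcherProfile,
              tail_mode: str, rng: np.random.Generator
              ) -> Optional[StudyResult]:
    rule = StoppingRule.for_start(start_n)
    table = simulate_participants(theta_i, start_n, rng)
    peek = 0
    while True:
        analyses = enumerate_analyses(table, profile, peek)
        best = _best(analyses, tail_mode)
        stop_significant = (best is not None
                            and modified_p(best.p, best.direction,
                                           tail_mode) < ALPHA)
        if (stop_significant or not profile.uses_optional_stopping
                or table.n >= rule.max_n):
            return best
        increment = min(rule.increment, rule.max_n - table.n)
        table = add_participants(table, increment, rng)
        peek += 1
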