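"""Publication bias: significance-contingent censoring of submitted studies.

A regime is defined by its tail and strength. Statistically significant
results (two-tailed p < .05) in the expected direction always survive.
Under a one-tailed regime, significant wrong-direction results are always
censored; under a two-tailed regime they survive like expected-direction
ones. Non-significant results survive with probability 1 - strength.

A distinct publish-everything regime (``NO_BIAS``) represents the complete
absence of publication bias, used for all baseline (unbiased-world)
analyses: even a one-tailed regime at strength 0 still censors significant
wrong-direction results, so strength 0 is not bias-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .qrp import ALPHA, HackingEnvironment, run_hacked_study
from .studysim import SampleSizeModel, StudyResult, draw_true_effect

__all__ = ["BiasRegime", "NO_BIAS", "PublishedLiterature",
           "publish_decision", "sample_published_literature"]


@dataclass(frozen=True)
class BiasRegime:
    tail: str  # "one" | "two" | "none"
    strength: float = 0.0  # proportion of non-significant studies censored

    def __post_init__(self) -> None:
        if self.tail not in ("one", "two", "none"):
            raise ValueError(f"tail must be 'one', 'two' or 'none', "
                             f"got {self.tail!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")

    @property
    def selection_tail(self) -> str:
        """Tail mode governing within-study result selection."""
        return "one" if self.tail == "one" else "two"


NO_BIAS = BiasRegime(tail="none", strength=0.0)


def publish_probability(result: StudyResult, regime: BiasRegime) -> float:
    if regime.tail == "none":
        return 1.0
    significant = result.p < ALPHA
    if significant:
        if regime.tail == "two" or result.direction > 0:
            return 1.0
        return 0.0  # one-tailed: significant wrong-direction
    return 1.0 - regime.strength


def publish_decision(result: StudyResult, regime: BiasRegime,
                     rng: np.random.Generator) -> bool:
    """Bernoulli publication decision for one submitted study."""
    prob = publish_probability(result, regime)
    if prob >= 1.0:
        return True
    if prob <= 0.0:
        return False
    return rng.random() < prob


@dataclass
class PublishedLiterature:
    """The k studies surviving censoring, feeding one meta-analysis."""

    g: np.ndarray
    v: np.ndarray
    n_analyzed: np.ndarray
    n_collected: np.ndarray
    theta_i: np.ndarray
    n_generated: int  # studies generated to accumulate the k published

    @property
    def k(self) -> int:
        return self.g.shape[0]


def sample_published_literature(k: int, theta: float, tau: float,
                                environment: HackingEnvironment,
                                regime: BiasRegime,
                                rng: np.random.Generator,
                                sample_size_model: Optional[SampleSizeModel]
                                = None) -> PublishedLiterature:
    """Generate studies (researcher -> experiment -> submission ->
    censoring) until exactly k are published."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    model = sample_size_model or SampleSizeModel()
    tail = regime.selection_tail
    g = np.empty(k)
    v = np.empty(k)
    n_an = np.empty(k, dtype=np.int64)
    n_co = np.empty(k, dtype=np.int64)
    th = np.empty(k)
    published = 0
    generated = 0
    while published < k:
        theta_i = draw_true_effect(theta, tau, rng)
        start_n = int(model.draw(rng))
        profile = environment.draw_profile(rng)
        result = run_hacked_study(theta_i, start_n, profile, tail, rng)
        generated += 1
        if publish_decision(result, regime, rng):
            g[published] = result.g
            v[published] = result.v
            n_an[published] = result.n_analyzed
            n_co[published] = result.n_collected
            th[published] = theta_i
            published += 1
    return PublishedLiterature(g, v, n_an, n_co, th, generated)
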