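"""Independent oracles used by the estimator tests.

Everything here is deliberately naive (direct formula evaluation,
brute-force grid search) and shares no code with the implementation.
"""

import numpy as np

from hetsim.meta import MetaSample


def _profile_theta(g, v, tau2):
    w = 1.0 / (v + tau2)
    return (w * g).sum() / w.sum()


def ml_loglik(g, v, tau2):
    th = _profile_theta(g, v, tau2)
    s2 = v + tau2
    return -0.5 * (np.log(s2) + (g - th) ** 2 / s2).sum()


def reml_loglik(g, v, tau2):
    th = _profile_theta(g, v, tau2)
    s2 = v + tau2
    return (-0.5 * (np.log(s2) + (g - th) ** 2 / s2).sum()
            - 0.5 * np.log((1.0 / s2).sum()))


def grid_argmax(fun, g, v, hi=None):
    """Two-stage brute-force maximizer of fun over tau^2 in [0, hi]."""
    if hi is None:
        hi = max(2.0, 5.0 * float(np.var(g)))
    grid = np.linspace(0.0, hi, 4001)
    vals = [fun(g, v, t2) for t2 in grid]
    best = grid[int(np.argmax(vals))]
    lo = max(0.0, best - 2 * (grid[1] - grid[0]))
    fine = np.linspace(lo, best + 2 * (grid[1] - grid[0]), 4001)
    vals = [fun(g, v, t2) for t2 in fine]
    return fine[int(np.argmax(vals))]


def eq4_moment_form(g, v, w):
    """General method-of-moments form with arbitrary weights."""
    th = (w * g).sum() / w.sum()
    num = ((w * (g - th) ** 2).sum() - (w * v).sum()
           + (w * w * v).sum() / w.sum())
    den = w.sum() - (w * w).sum() / w.sum()
    return num / den


def random_samples(n, seed, k_range=(3, 10), equal_v=False):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(*k_range))
        v = (np.full(k, 0.05) if equal_v
             else rng.uniform(0.01, 0.2, size=k))
        tau = rng.uniform(0, 0.5)
        g = rng.normal(0.3, np.sqrt(tau ** 2 + v))
        out.append(MetaSample(g, v))
    return out
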