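"""Factorial Monte-Carlo experiment over the six design factors.

Crosses p-hacking environment, publication-bias tail and strength, true
heterogeneity tau, true average effect theta, and number of studies k;
runs many simulated meta-analyses per design cell, fits all five
heterogeneity estimators to the same literatures (paired comparison), and
summarizes estimator performance per cell. A classical balanced-design
ANOVA decomposes the variance of any cell-level response into main
effects and interactions.

Every input is generated: the module is also the synthetic-data
orchestrator, with one root seed giving bit-reproducible output.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import meta
from .meta import ESTIMATORS, MetaSample
from .pubbias import NO_BIAS, BiasRegime, sample_published_literature
from .qrp import ENVIRONMENTS
from .studysim import SampleSizeModel

__all__ = [
    "FULL_GRID", "DesignCell", "build_grid", "run_cell", "mc_error",
    "factorial_ss", "bias_label", "run_experiment", "default_config",
]

log = logging.getLogger("hetsim")

# the fully crossed factor levels of the main experiment (1,440 cells)
FULL_GRID: Dict[str, tuple] = {
    "hacking": ("none", "medium", "high"),
    "tail": ("one", "two"),
    "pb_strength": (0.0, 0.4, 0.8),
    "tau": (0.0, 0.11, 0.22, 0.33, 0.44),
    "theta": (0.0, 0.2, 0.5, 0.8),
    "k": (9, 18, 36, 72),
}

FACTORS = tuple(FULL_GRID)


@dataclass(frozen=True)
class DesignCell:
    hacking: str
    tail: str
    pb_strength: float
    tau: float
    theta: float
    k: int
    index: int = 0

    @property
    def regime(self) -> BiasRegime:
        if self.tail == "none":
            return NO_BIAS
        return BiasRegime(tail=self.tail, strength=self.pb_strength)

    def label(self) -> str:
        return (f"hack={self.hacking} tail={self.tail} "
                f"pb={self.pb_strength} tau={self.tau} "
                f"theta={self.theta} k={self.k}")


def build_grid(levels: Optional[Dict[str, Sequence]] = None,
               filter: Optional[Dict[str, Sequence]] = None
               ) -> List[DesignCell]:
    """Deterministically ordered full crossing of the factor levels,
    optionally restricted to a subset of levels per factor."""
    lv = {f: tuple(FULL_GRID[f]) for f in FACTORS}
    if levels:
        for f, vals in levels.items():
            if f not in lv:
                raise ValueError(f"unknown factor {f!r}")
            lv[f] = tuple(vals)
    if filter:
        for f, vals in filter.items():
            if f not in lv:
                raise ValueError(f"unknown factor {f!r}")
            vals = tuple(vals)
            unknown = set(vals) - set(lv[f])
            if unknown:
                raise ValueError(f"unknown level(s) {unknown} for {f!r}")
            lv[f] = tuple(v for v in lv[f] if v in vals)
    for f, vals in lv.items():
        if not vals:
            raise ValueError(f"factor {f!r} has no levels")
    cells = []
    for i, combo in enumerate(itertools.product(*(lv[f] for f in FACTORS))):
        cells.append(DesignCell(**dict(zip(FACTORS, combo)), index=i))
    return cells


def mc_error(t_sd: float, reps: int) -> float:
    """Monte-Carlo standard error of a cell's mean heterogeneity
    estimate: SD of the replicate estimates divided by sqrt(reps)."""
    return t_sd / math.sqrt(reps)


def bias_label(value: float) -> str:
    """Verbal label for unsigned bias in T (SMD units)."""
    a = abs(value)
    if a >= 0.20:
        return "large"
    if a >= 0.10:
        return "medium"
    if a >= 0.05:
        return "small"
    return "negligible"


def run_cell(cell: DesignCell, reps: int, seed: int,
             estimators: Sequence[str] = ESTIMATORS,
             sample_size_model: Optional[SampleSizeModel] = None,
             with_tau_ci: bool = True,
             reported: str = "analyzed") -> pd.DataFrame:
    """Monte-Carlo evaluation of one design cell.

    Runs `reps` meta-analyses; each replicate assembles one published
    literature and fits every requested estimator to it. Replicates in
    which ML or REML fails to converge are regenerated (and counted)
    until `reps` converged meta-analyses are completed. Returns one row
    per estimator with bias/RMSE/coverage/type-I summaries.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if reported not in ("analyzed", "collected"):
        raise ValueError("reported must be 'analyzed' or 'collected'")
    estimators = tuple(e.upper() for e in estimators)
    env = ENVIRONMENTS[cell.hacking]
    regime = cell.regime
    model = sample_size_model or SampleSizeModel()
    ss = np.random.SeedSequence([seed, cell.index])

    t_hat = {e: np.empty(reps) for e in estimators}
    d_hat = {e: np.empty(reps) for e in estimators}
    cover_theta = {e: np.zeros(reps, dtype=bool) for e in estimators}
    cover_tau = {e: np.zeros(reps, dtype=bool) for e in estimators}
    reject = {e: np.zeros(reps, dtype=bool) for e in estimators}
    i2 = np.empty(reps)
    n_reported = np.empty(reps)
    n_generated = np.empty(reps)

    replaced = 0
    done = 0
    max_attempts = 10 * reps
    attempts = 0
    while done < reps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"cell {cell.label()}: exceeded {max_attempts} replicate "
                "attempts (persistent non-convergence)")
        rng = np.random.default_rng(ss.spawn(1)[0])
        lit = sample_published_literature(
            cell.k, cell.theta, cell.tau, env, regime, rng,
            sample_size_model=model)
        sample = MetaSample(lit.g, lit.v)
        fits = {}
        converged = True
        for e in estimators:
            f = meta.fit(sample, e, with_tau_ci=with_tau_ci)
            fits[e] = f
            converged &= f.converged
        if not converged:
            replaced += 1
            continue
        for e in estimators:
            f = fits[e]
            t_hat[e][done] = f.tau_hat
            d_hat[e][done] = f.theta_hat
            cover_theta[e][done] = f.kh_ci[0] <= cell.theta <= f.kh_ci[1]
            if with_tau_ci:
                cover_tau[e][done] = f.tau_ci[0] <= cell.tau <= f.tau_ci[1]
            reject[e][done] = f.kh_p < 0.05
        i2[done] = meta.i_squared(sample)
        n_rep = lit.n_analyzed if reported == "analyzed" else lit.n_collected
        n_reported[done] = n_rep.mean()
        n_generated[done] = lit.n_generated
        done += 1

    rows = []
    for e in estimators:
        t = t_hat[e]
        t_sd = float(t.std(ddof=1))
        t_bias = float(t.mean() - cell.tau)
        rows.append({
            **{f: getattr(cell, f) for f in FACTORS},
            "cell_index": cell.index,
            "estimator": e,
            "reps": reps,
            "T_mean": float(t.mean()),
            "T_bias": t_bias,
            "T_sd": t_sd,
            "T_rmse": float(np.sqrt(((t - cell.tau) ** 2).mean())),
            "d_mean": float(d_hat[e].mean()),
            "d_bias": float(d_hat[e].mean() - cell.theta),
            "coverage_theta": float(cover_theta[e].mean()),
            "coverage_tau": (float(cover_tau[e].mean())
                             if with_tau_ci else np.nan),
            "rejection_rate": float(reject[e].mean()),
            "mc_error": mc_error(t_sd, reps),
            "i2_mean": float(i2.mean()),
            "i2_median": float(np.median(i2)),
            "n_mean": float(n_reported.mean()),
            "n_generated_mean": float(n_generated.mean()),
            "replicates_replaced": replaced,
        })
    return pd.DataFrame(rows)


def factorial_ss(cell_table: pd.DataFrame, response: str,
                 factors: Sequence[str] = FACTORS,
                 max_order: int = 3) -> pd.DataFrame:
    """Classical balanced-design ANOVA sums of squares.

    `cell_table` must hold exactly one response value for every cell of
    the full crossing of `factors`. Each term's SS comes from
    inclusion-exclusion over marginal means; interaction orders above
    `max_order` are pooled into an Error term. Term SS sum exactly to the
    corrected total on a balanced grid.
    """
    factors = [f for f in factors if cell_table[f].nunique() > 1]
    if not factors:
        raise ValueError("no varying factors in the table")
    levels = {f: sorted(cell_table[f].unique()) for f in factors}
    n_cells = int(np.prod([len(levels[f]) for f in factors]))
    if len(cell_table) != n_cells:
        raise ValueError(
            f"grid incomplete or duplicated: {len(cell_table)} rows for "
            f"{n_cells} cells")
    if cell_table.duplicated(subset=factors).any():
        raise ValueError("duplicate cells in table")

    # response as a dense ndarray with one axis per factor
    idx = [pd.Categorical(cell_table[f], categories=levels[f]).codes
           for f in factors]
    shape = tuple(len(levels[f]) for f in factors)
    y = np.full(shape, np.nan)
    y[tuple(idx)] = cell_table[response].to_numpy(dtype=np.float64)
    if np.isnan(y).any():
        raise ValueError("grid incomplete")

    nf = len(factors)
    all_axes = set(range(nf))
    # marginal means for every subset of factors
    marg: Dict[frozenset, np.ndarray] = {}
    for r in range(nf + 1):
        for sub in itertools.combinations(range(nf), r):
            s = frozenset(sub)
            marg[s] = y.mean(axis=tuple(all_axes - s), keepdims=True)

    grand = float(marg[frozenset()].squeeze())
    corrected_total = float(((y - grand) ** 2).sum())

    rows = []
    error_ss = 0.0
    for r in range(1, nf + 1):
        for sub in itertools.combinations(range(nf), r):
            s = frozenset(sub)
            eff = np.zeros_like(marg[s])
            for rr in range(r + 1):
                for tt in itertools.combinations(sub, rr):
                    sign = (-1.0) ** (r - rr)
                    eff = eff + sign * marg[frozenset(tt)]
            mult = n_cells / np.prod([shape[i] for i in sub])
            ss_term = float(mult * (eff ** 2).sum())
            if r <= max_order:
                rows.append({
                    "term": ":".join(factors[i] for i in sub),
                    "order": r,
                    "ss": ss_term,
                })
            else:
                error_ss += ss_term
    rows.append({"term": "Error", "order": 0, "ss": error_ss})
    rows.append({"term": "Corrected total", "order": 0,
                 "ss": corrected_total})
    out = pd.DataFrame(rows)
    return out


def default_config() -> dict:
    return {
        "levels": {},          # factor -> levels (defaults: full grid)
        "filter": {},          # factor -> subset of levels
        "reps": 1000,
        "seed": 1,
        "estimators": list(ESTIMATORS),
        "sample_size": {"mode": "calibrated"},
        "tau_ci": True,
        "reported": "analyzed",
        "out": "results",
    }


def _make_model(cfg: dict) -> SampleSizeModel:
    sscfg = cfg.get("sample_size", {}) or {}
    mode = sscfg.get("mode", "calibrated")
    if mode == "empirical":
        if "file" in sscfg:
            return SampleSizeModel.from_file(sscfg["file"])
        return SampleSizeModel(mode="empirical", sizes=sscfg["sizes"])
    return SampleSizeModel()


def run_experiment(config: Optional[dict] = None,
                   resume: bool = True) -> pd.DataFrame:
    """Run the factorial experiment described by `config`.

    Writes one row per cell x estimator to ``<out>/cells.csv``, ANOVA
    decompositions for T_bias, T_rmse (per estimator) and d_bias (first
    estimator) to ``<out>/anova_<response>.csv`` when the grid is
    balanced with more than one cell, plus a ``run.log``. Per-cell files
    under ``<out>/cells/`` allow interrupted runs to resume.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    out = Path(cfg["out"])
    cell_dir = out / "cells"
    cell_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        model = _make_model(cfg)
        cells = build_grid(cfg.get("levels") or None,
                           cfg.get("filter") or None)
        log.info("running %d cells x %d reps (seed=%s)",
                 len(cells), cfg["reps"], cfg["seed"])
        frames = []
        for cell in cells:
            path = cell_dir / f"cell_{cell.index:05d}.csv"
            if resume and path.exists():
                frames.append(pd.read_csv(path))
                continue
            df = run_cell(cell, cfg["reps"], cfg["seed"],
                          estimators=cfg["estimators"],
                          sample_size_model=model,
                          with_tau_ci=cfg["tau_ci"],
                          reported=cfg["reported"])
            df.to_csv(path, index=False)
            replaced = int(df["replicates_replaced"].iloc[0])
            if replaced:
                log.info("cell %s: %d replicates replaced "
                         "(ML/REML non-convergence)", cell.label(), replaced)
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(out / "cells.csv", index=False)

        n_cells = table["cell_index"].nunique()
        varying = [f for f in FACTORS if table[f].nunique() > 1]
        if n_cells > 1 and varying:
            for resp in ("T_bias", "T_rmse"):
                parts = []
                for e in cfg["estimators"]:
                    sub = table[table["estimator"] == e.upper()]
                    an = factorial_ss(sub, resp, factors=varying)
                    an.insert(0, "estimator", e.upper())
                    parts.append(an)
                pd.concat(parts, ignore_index=True).to_csv(
                    out / f"anova_{resp}.csv", index=False)
            e0 = cfg["estimators"][0].upper()
            sub = table[table["estimator"] == e0]
            an = factorial_ss(sub, "d_bias", factors=varying)
            an.insert(0, "estimator", e0)
            an.to_csv(out / "anova_d_bias.csv", index=False)
        log.info("done: %d cells", n_cells)
        return table
    finally:
        log.removeHandler(handler)
        handler.close()
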