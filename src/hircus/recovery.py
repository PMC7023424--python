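"""Simulation-based parameter-recovery experiments.

Simulate a herd from known variance components, refit it with the samplers,
and score whether each posterior HPD interval covers the truth.  This is the
package's calibration harness: with the generative and inferential models
identical, empirical HPD coverage across replicate seeds should sit near the
nominal level, and that is what the experiment tables report.

Scaled-down defaults (a few hundred kids, 20,000-iteration chains) keep one
replicate in the tens of seconds on a single core; the study-scale protocol
is available through the same functions by passing larger configs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .growth_model import ModelSpec, build_design, gibbs_chain
from .pedigree import relationship_matrix
from .simulate import SimulationConfig, simulate_dataset
from .summaries import genetic_correlation, hpd_interval
from .survival_model import aft_gibbs_chain, censor_records, survival_heritability

__all__ = [
    "growth_recovery_config",
    "survival_recovery_config",
    "run_growth_recovery",
    "run_survival_recovery",
    "coverage_table",
]


def growth_recovery_config(**overrides) -> SimulationConfig:
    """Scaled-down cohort for growth recovery: 400 kids, 150 dams, 30 sires."""
    base = dict(n_kids=400, n_dams=150, n_sires=30, n_herds=8)
    base.update(overrides)
    return SimulationConfig(**base)


def survival_recovery_config(**overrides) -> SimulationConfig:
    """Scaled-down cohort for survival recovery: 1000 kids, 420 dams, 30 sires."""
    base = dict(n_kids=1000, n_dams=420, n_sires=30, n_herds=8)
    base.update(overrides)
    return SimulationConfig(**base)


def run_growth_recovery(
    n_replicates: int = 20,
    config: SimulationConfig | None = None,
    trait_pair: tuple[str, str] = ("bw", "cg"),
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    thin: int = 10,
    prob: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate simulate -> fit -> HPD-coverage for the growth model.

    Returns one row per replicate x parameter with the truth, the posterior
    mean/median and HPD limits, and a coverage flag.  Parameters scored are
    the five variance components of each trait and the genetic correlation.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = config or growth_recovery_config()
    t2 = trait_pair[1]
    truth = {f"{c}_1": cfg.growth_variances["bw"][c] for c in ("a", "m", "p", "c", "e")}
    truth.update({f"{c}_2": cfg.growth_variances[t2][c] for c in ("a", "m", "p", "c", "e")})
    truth["r_g"] = cfg.genetic_correlations[t2]

    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + 7919 * rep
        cfg_r = dataclasses.replace(cfg, seed=rep_seed)
        ped, rec = simulate_dataset(cfg_r)
        design = build_design(rec, ped, ModelSpec(trait_pair=trait_pair))
        A = relationship_matrix(ped)
        chain = gibbs_chain(
            design, A, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=rep_seed + 1,
        )
        s = chain.samples
        per_param = {}
        for tix in (1, 2):
            for comp in ("a", "m", "p", "c", "e"):
                per_param[f"{comp}_{tix}"] = s[f"{comp}{tix}{tix}"].to_numpy()
        per_param["r_g"] = genetic_correlation(
            s["a11"].to_numpy(), s["a12"].to_numpy(), s["a22"].to_numpy()
        )
        for name, draws in per_param.items():
            lo, hi = hpd_interval(draws, prob)
            tv = truth[name]
            rows.append(
                {
                    "replicate": rep,
                    "seed": rep_seed,
                    "parameter": name,
                    "truth": tv,
                    "post_mean": float(np.mean(draws)),
                    "post_median": float(np.median(draws)),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "covered": bool(lo <= tv <= hi),
                }
            )
    return pd.DataFrame(rows)


def run_survival_recovery(
    n_replicates: int = 20,
    config: SimulationConfig | None = None,
    n_iter: int = 6_000,
    burn_in: int = 1_000,
    thin: int = 5,
    prob: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate simulate -> fit for the survival model; scores h2 as well."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = config or survival_recovery_config()
    sp = cfg.survival
    truth = {
        "s2_a": sp.var_a, "s2_m": sp.var_m, "s2_c": sp.var_c, "s2_e": sp.var_e,
        "b1": sp.bw_slope,
        "h2": sp.var_a / (sp.var_a + sp.var_m + sp.var_c + sp.var_e),
    }
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + 104729 * rep
        cfg_r = dataclasses.replace(cfg, seed=rep_seed)
        ped, rec = simulate_dataset(cfg_r)
        design = censor_records(rec, ped, horizon=sp.censoring_horizon)
        A = relationship_matrix(ped)
        chain = aft_gibbs_chain(
            design, A, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=rep_seed + 1,
        )
        s = chain.samples
        draws = {k: s[k].to_numpy() for k in ("b1", "s2_a", "s2_m", "s2_c", "s2_e")}
        draws["h2"] = survival_heritability(
            [draws["s2_a"], draws["s2_m"], draws["s2_c"], draws["s2_e"]]
        )
        for name, d in draws.items():
            lo, hi = hpd_interval(d, prob)
            tv = truth[name]
            rows.append(
                {
                    "replicate": rep,
                    "seed": rep_seed,
                    "parameter": name,
                    "truth": tv,
                    "post_mean": float(np.mean(d)),
                    "post_median": float(np.median(d)),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "covered": bool(lo <= tv <= hi),
                }
            )
    return pd.DataFrame(rows)


def coverage_table(recovery: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter empirical coverage fraction from a recovery table."""
    out = (
        recovery.groupby("parameter")
        .agg(
            truth=("truth", "first"),
            coverage=("covered", "mean"),
            n_replicates=("replicate", "nunique"),
            mean_post_mean=("post_mean", "mean"),
            mean_post_median=("post_median", "mean"),
        )
        .reset_index()
    )
    return out
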