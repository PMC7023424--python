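"""Accelerated-failure-time animal model for kid survival to one year.

log(ST) = X b + Z_a a + Z_m m + Z_c c + e

where ST is survival time in days (right-censored at the horizon, 360 days by
default), X carries an intercept and the kid's birth weight, a is the
pedigree-correlated additive genetic effect, m the i.i.d. maternal effect and
c the herd-year-season common environmental effect.  The default residual
family is Gaussian on the log scale (log-normal AFT), which is what gives
the variance-ratio heritability

    h2 = s2_a / (s2_a + s2_m + s2_c + s2_e)

its meaning; an exponential residual family is available behind a flag, in
which case location effects are updated by random-walk Metropolis steps and
no residual variance is reported.

Censored records are handled by data augmentation: at every Gibbs scan each
censored log-time is redrawn from its truncated-normal full conditional above
log(horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .growth_model import MCMCChain, _csr_lists, _incidence
from .pedigree import Pedigree, RelationshipMatrix
from .simulate import KidRecords

__all__ = [
    "SurvivalPriorSpec",
    "SurvivalDesign",
    "censor_records",
    "aft_gibbs_chain",
    "survival_heritability",
]

SURVIVAL_PARAM_NAMES = ["b0", "b1", "s2_a", "s2_m", "s2_c", "s2_e"]

#: deaths recorded on day 0 are floored to half a day before taking logs
ZERO_DAY_FLOOR = 0.5


@dataclass
class SurvivalPriorSpec:
    """Scalar inverse-chi-square priors per term; flat by default.

    The flat prior is encoded as df = -2 with zero scale (see
    :class:`hircus.growth_model.PriorSpec` for why zero-attracting proper
    defaults are avoided).  Proper priors need df > 0 and scale > 0.
    """

    df: dict = field(default_factory=lambda: {"a": -2.0, "m": -2.0, "c": -2.0, "e": -2.0})
    scale: dict = field(default_factory=lambda: {"a": 0.0, "m": 0.0, "c": 0.0, "e": 0.0})

    def __post_init__(self) -> None:
        for term, v in self.scale.items():
            if v < 0:
                raise ValueError(f"prior scale for {term!r} must be nonnegative")
            if v > 0 and self.df[term] <= 0:
                raise ValueError(f"proper prior for {term!r} needs df > 0")

    def arrays(self, order=("a", "m", "c", "e")) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([float(self.df[t]) for t in order]),
            np.array([float(self.scale[t]) for t in order]),
        )


@dataclass
class SurvivalDesign:
    """Observation vectors and incidence structures for the AFT model."""

    log_time: np.ndarray
    time_days: np.ndarray
    censored: np.ndarray
    birth_weight: np.ndarray
    X: sp.csr_matrix
    Z_a: sp.csr_matrix
    Z_m: sp.csr_matrix
    Z_c: sp.csr_matrix
    anim_codes: np.ndarray
    dam_codes: np.ndarray
    grp_codes: np.ndarray
    animal_ids: list
    dam_labels: list
    grp_labels: list
    kid_ids: list
    horizon: int

    @property
    def n_records(self) -> int:
        return len(self.log_time)


def _season_of(birth_date: pd.Series, season: pd.Series | None) -> pd.Series:
    if season is not None and not season.isna().any():
        return season.astype(str)
    months = pd.to_datetime(birth_date).dt.month
    return pd.Series(np.where(months.isin([6, 7, 8, 9]), "dry", "wet"),
                     index=birth_date.index)


def censor_records(
    records: KidRecords, ped: Pedigree | None = None, horizon: int = 360
) -> SurvivalDesign:
    """Apply the right-censoring rule and assemble the survival design.

    Kids alive at the horizon are flagged censored with time set to the
    horizon; deaths keep their observed day (a zero-day death is floored to
    half a day before the log).  The common-environment grouping is the
    herd x birth-year x season cross-classification.  Kids without a birth
    body-weight record are dropped with a warning (the model adjusts for
    birth weight).
    """
    kids = records.kids.copy()
    if kids["survival_days"].isna().any():
        raise ValueError("survival_days missing for some kids")
    if (kids["survival_days"] < 0).any():
        raise ValueError("negative survival days")

    birth = records.records_at("birth")[["kid", "bw"]].dropna()
    kids = kids.merge(birth, on="kid", how="left")
    n_missing = int(kids["bw"].isna().sum())
    if n_missing:
        import warnings

        warnings.warn(f"dropping {n_missing} kid(s) without a birth weight record")
        kids = kids.dropna(subset=["bw"])
    if len(kids) == 0:
        raise ValueError("no kids with survival outcome and birth weight")

    censored = (kids["censored"].astype(bool) | (kids["survival_days"] >= horizon)
                ).to_numpy()
    days = np.where(censored, horizon, kids["survival_days"].to_numpy()).astype(float)
    days = np.maximum(days, ZERO_DAY_FLOOR)
    if censored.all():
        raise ValueError("all records censored; survival model unidentifiable")

    year = pd.to_datetime(kids["birth_date"]).dt.year.astype(str)
    season = _season_of(kids["birth_date"], kids.get("season"))
    grp_key = kids["herd"].astype(str) + ":" + year + ":" + season.to_numpy()
    grp_labels = sorted(grp_key.unique())
    grp_codes = grp_key.map({g: i for i, g in enumerate(grp_labels)}).to_numpy()

    dam_labels = sorted(kids["dam"].unique())
    dam_codes = kids["dam"].map({d: i for i, d in enumerate(dam_labels)}).to_numpy()
    if ped is not None:
        absent = [k for k in kids["kid"] if k not in ped.index]
        if absent:
            raise ValueError(f"kids absent from pedigree: {absent[:5]}")
        anim_codes = kids["kid"].map(ped.index).to_numpy(dtype=np.int64)
        animal_ids = ped.ids
    else:
        animal_ids = list(kids["kid"])
        anim_codes = np.arange(len(kids), dtype=np.int64)

    n = len(kids)
    X = sp.csr_matrix(np.column_stack([np.ones(n), kids["bw"].to_numpy()]))
    return SurvivalDesign(
        log_time=np.log(days),
        time_days=days,
        censored=censored,
        birth_weight=kids["bw"].to_numpy(dtype=float),
        X=X,
        Z_a=_incidence(anim_codes, len(animal_ids)),
        Z_m=_incidence(dam_codes.astype(np.int64), len(dam_labels)),
        Z_c=_incidence(grp_codes.astype(np.int64), len(grp_labels)),
        anim_codes=anim_codes,
        dam_codes=dam_codes.astype(np.int64),
        grp_codes=grp_codes.astype(np.int64),
        animal_ids=animal_ids,
        dam_labels=dam_labels,
        grp_labels=grp_labels,
        kid_ids=list(kids["kid"]),
        horizon=horizon,
    )


def aft_gibbs_chain(
    design: SurvivalDesign,
    A: RelationshipMatrix | None,
    priors: SurvivalPriorSpec | None = None,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed: int = 0,
    include_additive: bool = True,
    include_maternal: bool = True,
    include_common_env: bool = True,
    error_family: str = "lognormal",
    mh_step: float = 0.15,
    mh_steps: int = 8,
    mh_scale: float | None = None,
) -> MCMCChain:
    """Gibbs (or Metropolis-within-Gibbs) chain for the survival model.

    With ``error_family="lognormal"`` all full conditionals are exact and
    censored log-times are data-augmented; with ``"exponential"`` location
    effects move by random-walk Metropolis and s2_e is absent.  Retains the
    regression coefficients (intercept, birth-weight slope) and all variance
    components.  Deterministic given the seed.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if error_family not in ("lognormal", "exponential"):
        raise ValueError("error_family must be 'lognormal' or 'exponential'")
    priors = priors or SurvivalPriorSpec()

    q = len(design.animal_ids)
    if include_additive:
        if A is None:
            raise ValueError("relationship matrix required for the additive term")
        if A.order != design.animal_ids:
            raise ValueError("relationship matrix order does not match the design")
        lam, Q = np.linalg.eigh(A.values)
        lam = np.clip(lam, 0.0, None)
        Q = np.ascontiguousarray(Q)
        Ainv = np.ascontiguousarray(A.inverse())
    else:
        lam = np.ones(q)
        Q = np.eye(q)
        Ainv = np.eye(q)
    if mh_scale is None:
        mh_scale = max(0.05, 2.0 / np.sqrt(q))

    anim_ptr, anim_idx = _csr_lists(design.anim_codes, q)
    dam_ptr, dam_idx = _csr_lists(design.dam_codes, len(design.dam_labels))
    grp_ptr, grp_idx = _csr_lists(design.grp_codes, len(design.grp_labels))

    meta = {
        "kind": "survival",
        "error_family": error_family,
        "n_iter": int(n_iter), "burn_in": int(burn_in), "thin": int(thin),
        "seed": int(seed), "n_records": design.n_records,
        "n_animals": q, "n_dams": len(design.dam_labels),
        "n_groups": len(design.grp_labels),
        "horizon": design.horizon,
        "n_censored": int(design.censored.sum()),
        "include_additive": include_additive,
        "include_maternal": include_maternal,
        "include_common_env": include_common_env,
        "prior_df": {k: float(v) for k, v in priors.df.items()},
        "prior_scale": {k: float(v) for k, v in priors.scale.items()},
    }

    if error_family == "lognormal":
        from ._samplers import survival_gibbs_kernel

        pdf, ps = priors.arrays()
        raw, min_aug = survival_gibbs_kernel(
            np.ascontiguousarray(design.log_time, dtype=np.float64),
            np.ascontiguousarray(design.censored),
            np.ascontiguousarray(design.birth_weight, dtype=np.float64),
            design.anim_codes, design.dam_codes, design.grp_codes,
            anim_ptr, anim_idx, dam_ptr, dam_idx, grp_ptr, grp_idx,
            Q, lam,
            include_additive, include_maternal, include_common_env,
            pdf, ps,
            float(np.log(design.horizon)),
            int(n_iter), int(burn_in), int(thin), int(seed),
            int(mh_steps), float(mh_scale),
        )
        samples = pd.DataFrame(raw, columns=SURVIVAL_PARAM_NAMES)
        meta["min_augmented_log_time"] = float(min_aug)
    else:
        from ._samplers import survival_exponential_kernel

        pdf, ps = priors.arrays(order=("a", "m", "c"))
        raw, acc = survival_exponential_kernel(
            np.ascontiguousarray(design.time_days, dtype=np.float64),
            np.ascontiguousarray(design.censored),
            np.ascontiguousarray(design.birth_weight, dtype=np.float64),
            design.anim_codes, design.dam_codes, design.grp_codes,
            anim_ptr, anim_idx, dam_ptr, dam_idx, grp_ptr, grp_idx,
            Ainv,
            include_additive, include_maternal, include_common_env,
            pdf, ps,
            int(n_iter), int(burn_in), int(thin), int(seed), float(mh_step),
        )
        samples = pd.DataFrame(raw, columns=SURVIVAL_PARAM_NAMES[:5])
        meta["mh_acceptance"] = float(acc)
    return MCMCChain(samples, meta)


def survival_heritability(components) -> np.ndarray | float:
    """h2 = s2_a / (s2_a + s2_m + s2_c + s2_e), element-wise over samples.

    *components* is a 4-sequence (s2_a, s2_m, s2_c, s2_e) of scalars or
    aligned sample vectors.
    """
    a, m, c, e = (np.asarray(v, dtype=float) for v in components)
    total = a + m + c + e
    if np.any(total <= 0):
        raise ValueError("total variance must be positive")
    if np.any(a < 0) or np.any(m < 0) or np.any(c < 0) or np.any(e < 0):
        raise ValueError("variance components must be nonnegative")
    out = a / total
    return float(out) if out.ndim == 0 else out
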