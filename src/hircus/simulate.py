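"""Synthetic smallholder goat-herd generator.

Generates pedigrees and kid records with exactly the statistical structure the
inference modules assume, so that every estimation stage of the package can be
tested end to end without field data.  The generative model is the analysis
model run forwards:

* growth traits (BW kg; CG, BL, HW cm) follow the bivariate (here jointly
  four-trait) repeatability-maternal animal model: fixed age/sex/parity/birth
  type cell mean + additive genetic (pedigree-correlated) + maternal (i.i.d.
  per dam) + permanent environmental (per kid) + common environmental (per
  herd) + residual (per record);
* log survival time follows the accelerated-failure-time animal model with a
  birth-weight slope, a twin penalty, additive + maternal + herd-year-season
  random effects and a Gaussian residual, right-censored at the horizon.

Default parameter values are the published reference estimates for Burundian
indigenous goat kids (:mod:`hircus.reference`): 1538 kids from 645 dams and
106 sires in 8 village herds, records at birth/3/6/9/12 months with attrition,
twin fraction 0.4 (mean litter size 1.4), overall one-year mortality
calibrated at 31.6% with twins dying more than singles, censoring at 360
days.  See docs/methods.md for the calibration arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .pedigree import Pedigree, PedigreeRecord

__all__ = [
    "AGE_CLASSES",
    "AGE_DAYS",
    "TRAITS",
    "SimulationConfig",
    "SurvivalParams",
    "KidRecord",
    "KidRecords",
    "SimulatedHerd",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "simulate_dataset",
]

AGE_CLASSES = ("birth", "3mo", "6mo", "9mo", "12mo")
AGE_DAYS = {"birth": 0, "3mo": 90, "6mo": 180, "9mo": 270, "12mo": 360}
TRAITS = ("bw", "cg", "bl", "hw")

#: months of the dry season (used to assign the season label of a birth date)
DRY_SEASON_MONTHS = (6, 7, 8, 9)


@dataclass
class SurvivalParams:
    """Generative parameters of log survival time (days, natural log scale).

    The intercept and twin effect are calibrated so that, at the default
    growth parameters, expected one-year mortality is 31.6% overall with
    twin and single strata straddling it (twins die more).
    """

    intercept: float = 6.7301
    bw_slope: float = 0.1          # log-days per kg of birth weight
    twin_effect: float = -0.6269   # log-days, twins relative to singles
    var_a: float = 0.05
    var_m: float = 0.05
    var_c: float = 1.78            # herd-year-season, the dominant component
    var_e: float = 0.05
    censoring_horizon: int = 360   # days


def _default_growth_variances() -> dict:
    return {t: dict(reference.GROWTH_COMPONENTS[t]["mean"]) for t in TRAITS}


def _default_age_means() -> dict:
    return {
        "bw": dict(reference.DESCRIPTIVES["bw_age_means"]),
        "cg": {"birth": 25.0, "3mo": 38.0, "6mo": 45.0, "9mo": 50.0, "12mo": 54.0},
        "bl": {"birth": 22.0, "3mo": 32.0, "6mo": 38.0, "9mo": 42.0, "12mo": 45.0},
        "hw": {"birth": 25.0, "3mo": 35.0, "6mo": 40.0, "9mo": 44.0, "12mo": 47.0},
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic herd; defaults emulate the study cohort."""

    n_sires: int = 106
    n_dams: int = 645
    n_kids: int = 1538
    n_herds: int = 8
    years: tuple[int, int] = (2016, 2019)
    twin_fraction: float = 0.4
    # true variance components per trait (keys a, m, p, c, e)
    growth_variances: dict = _field(default_factory=_default_growth_variances)
    # additive genetic correlation of BW with each conformation trait
    genetic_correlations: dict = _field(
        default_factory=lambda: {"cg": 0.79, "bl": 0.65, "hw": 0.74}
    )
    # correlation of BW with each conformation trait in every non-additive term
    env_correlations: dict = _field(
        default_factory=lambda: {"cg": 0.90, "bl": 0.88, "hw": 0.84}
    )
    age_means: dict = _field(default_factory=_default_age_means)
    sex_contrast: float = 0.58        # male minus female, kg (BW only)
    birth_type_contrast: float = -1.0  # twin minus single, kg (BW only)
    parity_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    survival: SurvivalParams = _field(default_factory=SurvivalParams)
    # probability a live kid is actually measured at each age class
    attrition: dict = _field(
        default_factory=lambda: {
            "birth": 1.0, "3mo": 0.8927, "6mo": 0.7759, "9mo": 0.6810, "12mo": 0.6698
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sires", "n_dams", "n_kids", "n_herds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must be in [0, 1]")
        for t, comps in self.growth_variances.items():
            for k, v in comps.items():
                if v < 0:
                    raise ValueError(f"negative variance {t}.{k}")
        for v in (self.survival.var_a, self.survival.var_m,
                  self.survival.var_c, self.survival.var_e):
            if v < 0:
                raise ValueError("negative survival variance")
        for a, p in self.attrition.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"attrition[{a}] not a probability")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "survival" in raw and isinstance(raw["survival"], dict):
            raw["survival"] = SurvivalParams(**raw["survival"])
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        if "parity_effects" in raw:
            raw["parity_effects"] = tuple(raw["parity_effects"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["years"] = list(self.years)
        raw["parity_effects"] = list(self.parity_effects)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class KidRecord:
    """One kid: identity, covariates, repeated measurements, survival outcome."""

    kid_id: str
    sire_id: str
    dam_id: str
    sex: str                 # "male" / "female"
    birth_type: str          # "single" / "twin"
    parity: int              # 1..3
    herd: str
    village: str
    province: str
    birth_date: str          # ISO date
    measurements: dict       # age class -> (bw, cg, bl, hw) or absent
    survival_days: int
    censored: bool


class KidRecords:
    """Collection of kid records as two aligned DataFrames.

    ``kids`` has one row per kid (identity, covariates, survival outcome);
    ``measures`` has one row per kid x measured age class with the four trait
    values.  This tabular layout is the canonical in-memory container; the
    :class:`KidRecord` dataclass view is available via :meth:`to_kid_records`.
    """

    KID_COLUMNS = [
        "kid", "sire", "dam", "sex", "birth_type", "parity", "herd",
        "village", "province", "birth_date", "season",
        "survival_days", "censored",
    ]
    MEASURE_COLUMNS = ["kid", "age_class", "bw", "cg", "bl", "hw"]

    def __init__(self, kids: pd.DataFrame, measures: pd.DataFrame):
        self.kids = kids.reset_index(drop=True)
        self.measures = measures.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.kids)

    @property
    def n_measurements(self) -> int:
        return len(self.measures)

    def records_at(self, age_class: str) -> pd.DataFrame:
        return self.measures[self.measures["age_class"] == age_class]

    def to_frame(self) -> pd.DataFrame:
        """Single long table: one row per measurement plus one survival row."""
        meas = self.measures.merge(
            self.kids.drop(columns=["survival_days", "censored"]), on="kid"
        )
        meas.insert(0, "row_type", "measure")
        surv = self.kids.copy()
        surv.insert(0, "row_type", "survival")
        long = pd.concat([meas, surv], ignore_index=True, sort=False)
        order = ["row_type"] + [c for c in self.KID_COLUMNS if c not in
                                ("survival_days", "censored")] + \
                ["age_class", "bw", "cg", "bl", "hw", "survival_days", "censored"]
        return long[order].sort_values(
            ["kid", "row_type"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, long: pd.DataFrame) -> "KidRecords":
        surv = long[long["row_type"] == "survival"]
        kids = surv[cls.KID_COLUMNS].copy()
        kids["censored"] = kids["censored"].astype(bool)
        kids["survival_days"] = kids["survival_days"].astype(int)
        kids["parity"] = kids["parity"].astype(int)
        meas = long[long["row_type"] == "measure"][cls.MEASURE_COLUMNS].copy()
        return cls(kids, meas)

    def write(self, path: str | Path, *, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, *, sep: str | None = None) -> "KidRecords":
        long = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_frame(long)

    def to_kid_records(self) -> list[KidRecord]:
        meas_by_kid: dict[str, dict] = {}
        for row in self.measures.itertuples(index=False):
            meas_by_kid.setdefault(row.kid, {})[row.age_class] = (
                row.bw, row.cg, row.bl, row.hw
            )
        out = []
        for row in self.kids.itertuples(index=False):
            out.append(
                KidRecord(
                    kid_id=row.kid, sire_id=row.sire, dam_id=row.dam,
                    sex=row.sex, birth_type=row.birth_type, parity=int(row.parity),
                    herd=row.herd, village=row.village, province=row.province,
                    birth_date=row.birth_date,
                    measurements=meas_by_kid.get(row.kid, {}),
                    survival_days=int(row.survival_days),
                    censored=bool(row.censored),
                )
            )
        return out


@dataclass
class SimulatedHerd:
    """A simulated pedigree plus the herd structure needed to attach records."""

    pedigree: Pedigree
    litters: pd.DataFrame     # kid, sire, dam, herd, year, month, day, twin, parity
    dam_herd: dict
    sire_herd: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig, seed: int | None = None) -> SimulatedHerd:
    """Simulate the mating structure: founder sires/dams in herds, litters.

    Litters are allocated to unique (dam, year) slots; every dam gets one
    guaranteed litter (so the configured dam count is realised exactly when
    the kid count allows it) and remaining litters are assigned to random free
    slots.  The number of twin litters is fixed at ``n_kids - n_litters`` so
    the kid count is exact and mean litter size is ~(1 + twin_fraction).
    Sires serve within their own herd.  Deterministic given the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_years = cfg.n_years
    if cfg.n_kids > cfg.n_dams * n_years * 2:
        raise ValueError(
            f"infeasible: {cfg.n_kids} kids exceed {cfg.n_dams} dams x "
            f"{n_years} years x 2"
        )
    n_litters = int(round(cfg.n_kids / (1.0 + cfg.twin_fraction)))
    n_litters = max(min(n_litters, cfg.n_dams * n_years), cfg.n_kids - cfg.n_dams * n_years)
    if n_litters > cfg.n_dams * n_years:
        raise ValueError("infeasible litter count for the dam x year grid")

    herds = [f"H{h+1}" for h in range(cfg.n_herds)]
    sires = [f"S{i+1:04d}" for i in range(cfg.n_sires)]
    dams = [f"D{i+1:04d}" for i in range(cfg.n_dams)]
    sire_herd = {s: herds[i % cfg.n_herds] for i, s in enumerate(sires)}
    dam_herd = {d: herds[i % cfg.n_herds] for i, d in enumerate(dams)}
    sires_in = {h: [s for s in sires if sire_herd[s] == h] for h in herds}

    years = list(range(cfg.years[0], cfg.years[1] + 1))
    # guaranteed slot per dam, then extra unique (dam, year) slots
    slots = [(d, years[rng.integers(n_years)]) for d in dams]
    if n_litters > cfg.n_dams:
        used = set(slots)
        free = [(d, y) for d in dams for y in years if (d, y) not in used]
        extra_idx = rng.choice(len(free), size=n_litters - cfg.n_dams, replace=False)
        slots += [free[i] for i in sorted(extra_idx)]
    else:
        slots = [slots[i] for i in rng.choice(cfg.n_dams, size=n_litters, replace=False)]
    perm = rng.permutation(n_litters)
    slots = [slots[i] for i in perm]

    n_twin = cfg.n_kids - n_litters
    twin = np.zeros(n_litters, dtype=bool)
    twin[rng.choice(n_litters, size=n_twin, replace=False)] = True

    rows = []
    kid_no = 0
    for (dam, year), is_twin in zip(slots, twin):
        herd = dam_herd[dam]
        sire = sires_in[herd][rng.integers(len(sires_in[herd]))]
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        for _ in range(2 if is_twin else 1):
            kid_no += 1
            rows.append(
                (f"K{kid_no:05d}", sire, dam, herd, year, month, day, bool(is_twin))
            )
    litters = pd.DataFrame(
        rows, columns=["kid", "sire", "dam", "herd", "year", "month", "day", "twin"]
    )
    # parity class: birth order of the dam's litters, capped at 3
    litter_key = litters.drop_duplicates(["dam", "year"])[["dam", "year"]]
    litter_key = litter_key.sort_values(["dam", "year"], kind="stable")
    litter_key["parity"] = litter_key.groupby("dam").cumcount() + 1
    litter_key["parity"] = litter_key["parity"].clip(upper=3)
    litters = litters.merge(litter_key, on=["dam", "year"])
    litters = litters.sort_values(
        ["year", "month", "day", "kid"], kind="stable"
    ).reset_index(drop=True)

    records = [PedigreeRecord(s) for s in sires] + [PedigreeRecord(d) for d in dams]
    for row in litters.itertuples(index=False):
        records.append(PedigreeRecord(row.kid, row.sire, row.dam, int(row.year)))
    return SimulatedHerd(Pedigree(records), litters, dam_herd, sire_herd, cfg)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def _cov_sqrt(G0: np.ndarray) -> np.ndarray:
    """Symmetric square root, tolerating exactly singular (e.g. zero) G0."""
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    w, V = np.linalg.eigh(G0)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ValueError("additive covariance G0 is not positive semidefinite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _inbreeding_fast(ped: Pedigree) -> np.ndarray:
    """F per animal via memoised recursive kinship of each animal's parents.

    Linear memory (no dense A); fast for shallow pedigrees, which is what the
    generator produces.  Matches the diagonal of the tabular A minus one.
    """
    par = ped.parent_indices()
    memo: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            v = 0.5 * (1.0 + kin(par[i, 0], par[i, 1]))
        else:
            # j is the later-born animal in a sorted pedigree
            v = 0.5 * (kin(i, par[j, 0]) + kin(i, par[j, 1]))
        memo[key] = v
        return v

    n = len(ped)
    F = np.zeros(n)
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            F[i] = kin(s, d)
    return F


def simulate_breeding_values(
    ped: Pedigree,
    G0: np.ndarray,
    seed: int | np.random.Generator = 0,
    inbreeding_coefs: np.ndarray | None = None,
) -> np.ndarray:
    """Draw multivariate additive genetic values down a sorted pedigree.

    Founders are N(0, G0); non-founders get the parent average plus a
    Mendelian-sampling deviation with covariance G0 * (0.5 - 0.25(F_s + F_d))
    (an unknown parent contributes its founder share: one unknown parent gives
    factor 0.75 - 0.25 F_known, two give 1).  Returns (n_animals, n_traits)
    in pedigree order.
    """
    if not ped.is_sorted():
        raise ValueError("pedigree must be sorted")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    k = G0.shape[0]
    L = _cov_sqrt(G0)
    F = _inbreeding_fast(ped) if inbreeding_coefs is None else inbreeding_coefs
    par = ped.parent_indices()
    n = len(ped)
    z = rng.standard_normal((n, k)) @ L.T
    a = np.zeros((n, k))
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            a[i] = z[i]
        elif s >= 0 and d >= 0:
            fac = 0.5 - 0.25 * (F[s] + F[d])
            a[i] = 0.5 * (a[s] + a[d]) + np.sqrt(max(fac, 0.0)) * z[i]
        else:
            p = s if s >= 0 else d
            fac = 0.75 - 0.25 * F[p]
            a[i] = 0.5 * a[p] + np.sqrt(max(fac, 0.0)) * z[i]
    return a


# ---------------------------------------------------------------------------
# record simulation
# ---------------------------------------------------------------------------

def build_component_covariances(config: SimulationConfig) -> dict[str, np.ndarray]:
    """4x4 covariance of (bw, cg, bl, hw) for each model term.

    Cross-trait correlations follow a single-factor structure through BW:
    corr(bw, x) is the configured value and corr(x, y) is their product,
    which guarantees positive semidefiniteness.
    """
    out = {}
    for comp in ("a", "m", "p", "c", "e"):
        rho = {
            t: (config.genetic_correlations if comp == "a" else config.env_correlations)[t]
            for t in TRAITS[1:]
        }
        sd = np.array([np.sqrt(config.growth_variances[t][comp]) for t in TRAITS])
        loadings = np.array([1.0] + [rho[t] for t in TRAITS[1:]])
        corr = np.outer(loadings, loadings)
        np.fill_diagonal(corr, 1.0)
        out[comp] = corr * np.outer(sd, sd)
    return out


def _fixed_cell_value(config: SimulationConfig, trait: str, age: str,
                      sex_male: np.ndarray, twin: np.ndarray,
                      parity: np.ndarray) -> np.ndarray:
    """Population-mean-preserving (weighted effect) coding of the fixed cells.

    The male-female and twin-single differences equal the configured
    contrasts, but offsets are weighted by expected class shares so that the
    cohort marginal mean at each age equals the configured age mean.
    Contrasts apply to body weight only.
    """
    base = np.full(sex_male.shape, config.age_means[trait][age])
    if trait != "bw":
        return base
    w_twin = 2.0 * config.twin_fraction / (1.0 + config.twin_fraction)
    sex_eff = np.where(sex_male, 0.5, -0.5) * config.sex_contrast
    bt_eff = np.where(
        twin, (1.0 - w_twin) * config.birth_type_contrast,
        -w_twin * config.birth_type_contrast,
    )
    par_eff = np.asarray(config.parity_effects)[parity - 1]
    return base + sex_eff + bt_eff + par_eff


def simulate_records(
    herd: SimulatedHerd, seed: int | None = None
) -> KidRecords:
    """Generate growth measurements and survival outcomes for a simulated herd.

    Survival random effects are drawn independently of the growth random
    effects (the two analysis models are not genetically linked), so later-age
    record loss, which is driven by survival and attrition, is ignorable for
    growth inference given the always-present birth records.
    """
    cfg = herd.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    ped = herd.pedigree
    lit = herd.litters
    n_kids = len(lit)

    covs = build_component_covariances(cfg)
    a = simulate_breeding_values(ped, covs["a"], rng)
    kid_pos = np.array([ped.index[k] for k in lit["kid"]])
    a_kid = a[kid_pos]

    dams = sorted(lit["dam"].unique())
    herds = sorted(lit["herd"].unique())
    dam_ix = lit["dam"].map({d: i for i, d in enumerate(dams)}).to_numpy()
    herd_ix = lit["herd"].map({h: i for i, h in enumerate(herds)}).to_numpy()

    m_eff = rng.standard_normal((len(dams), 4)) @ _cov_sqrt(covs["m"]).T
    p_eff = rng.standard_normal((n_kids, 4)) @ _cov_sqrt(covs["p"]).T
    c_eff = rng.standard_normal((len(herds), 4)) @ _cov_sqrt(covs["c"]).T
    Le = _cov_sqrt(covs["e"])

    sex_male = rng.random(n_kids) < 0.5
    twin = lit["twin"].to_numpy()
    parity = lit["parity"].to_numpy()

    # trait values for every kid x age (presence decided later)
    values = {}
    for age in AGE_CLASSES:
        resid = rng.standard_normal((n_kids, 4)) @ Le.T
        cell = np.column_stack(
            [_fixed_cell_value(cfg, t, age, sex_male, twin, parity) for t in TRAITS]
        )
        values[age] = cell + a_kid + m_eff[dam_ix] + p_eff + c_eff[herd_ix] + resid

    # survival: log-normal AFT with herd-year-season common effect
    sp = cfg.survival
    a_s = simulate_breeding_values(ped, np.array([[sp.var_a]]), rng)[:, 0]
    m_s = rng.standard_normal(len(dams)) * np.sqrt(sp.var_m)
    season = np.where(lit["month"].isin(DRY_SEASON_MONTHS), "dry", "wet")
    hys_labels = (
        lit["herd"].astype(str) + ":" + lit["year"].astype(str) + ":" + season
    )
    hys_levels = sorted(hys_labels.unique())
    hys_ix = hys_labels.map({h: i for i, h in enumerate(hys_levels)}).to_numpy()
    c_s = rng.standard_normal(len(hys_levels)) * np.sqrt(sp.var_c)
    e_s = rng.standard_normal(n_kids) * np.sqrt(sp.var_e)

    bw_birth = values["birth"][:, 0]
    log_st = (
        sp.intercept + sp.bw_slope * bw_birth + sp.twin_effect * twin.astype(float)
        + a_s[kid_pos] + m_s[dam_ix] + c_s[hys_ix] + e_s
    )
    st_days = np.floor(np.exp(log_st)).astype(np.int64)
    censored = st_days >= sp.censoring_horizon
    survival_days = np.where(censored, sp.censoring_horizon, st_days)

    kids = pd.DataFrame(
        {
            "kid": lit["kid"],
            "sire": lit["sire"],
            "dam": lit["dam"],
            "sex": np.where(sex_male, "male", "female"),
            "birth_type": np.where(twin, "twin", "single"),
            "parity": parity,
            "herd": lit["herd"],
            "village": "V-" + lit["herd"].astype(str),
            "province": np.where(
                herd_ix < len(herds) / 2.0, "Gitega", "Rutana"
            ),
            "birth_date": [
                f"{y}-{m:02d}-{d:02d}"
                for y, m, d in zip(lit["year"], lit["month"], lit["day"])
            ],
            "season": season,
            "survival_days": survival_days,
            "censored": censored,
        }
    )

    # measurement presence: alive at the age (birth always measured), then
    # independent retention (field attrition)
    meas_frames = []
    for age in AGE_CLASSES:
        age_days = AGE_DAYS[age]
        alive = (survival_days > age_days) | censored if age_days > 0 else np.ones(
            n_kids, dtype=bool
        )
        retained = rng.random(n_kids) < cfg.attrition[age]
        present = alive & retained
        v = values[age][present]
        meas_frames.append(
            pd.DataFrame(
                {
                    "kid": lit["kid"].to_numpy()[present],
                    "age_class": age,
                    "bw": v[:, 0], "cg": v[:, 1], "bl": v[:, 2], "hw": v[:, 3],
                }
            )
        )
    measures = pd.concat(meas_frames, ignore_index=True)
    order = {k: i for i, k in enumerate(lit["kid"])}
    measures = measures.sort_values(
        ["kid", "age_class"],
        key=lambda s: s.map(order) if s.name == "kid" else s.map(
            {a: i for i, a in enumerate(AGE_CLASSES)}
        ),
        kind="stable",
    ).reset_index(drop=True)
    return KidRecords(kids, measures)


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[Pedigree, KidRecords]:
    """Convenience wrapper: pedigree + records in one call."""
    cfg = config or SimulationConfig()
    base = cfg.seed if seed is None else seed
    herd = simulate_pedigree(cfg, seed=base)
    rec = simulate_records(herd, seed=base + 1_000_003)
    return herd.pedigree, rec
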