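"""Published reference estimates for Burundian indigenous goat kids.

Posterior summaries (mean, median, 95% HPD limits) of the variance components
of kid body weight (BW, kg^2), chest girth (CG, cm^2), body length (BL, cm^2)
and height at withers (HW, cm^2) under the bivariate repeatability-maternal
animal model, of log survival time to one year under the AFT animal model,
and the additive genetic correlations of BW with each conformation trait.

These numbers serve two purposes: they are the default "true" parameters of
the synthetic-herd generator (:mod:`hircus.simulate`), and they feed the
ratio arithmetic (heritability, repeatability) used as exact cross-checks of
the summary formulas.

Component keys: ``a`` additive, ``m`` maternal, ``p`` permanent environment,
``c`` common environment (herd; herd-year-season for survival), ``e`` residual.
"""

from __future__ import annotations

COMPONENT_ORDER = ("a", "m", "p", "c", "e")

#: Posterior summaries of growth-trait variance components.
GROWTH_COMPONENTS: dict[str, dict[str, dict[str, float]]] = {
    "bw": {
        "mean":   {"a": 0.58, "m": 0.22, "p": 0.55, "c": 0.41, "e": 1.57},
        "median": {"a": 0.57, "m": 0.23, "p": 0.54, "c": 0.42, "e": 1.57},
        "hpd_low":  {"a": 0.37, "m": 0.09, "p": 0.37, "c": 0.33, "e": 1.50},
        "hpd_high": {"a": 0.79, "m": 0.38, "p": 0.70, "c": 0.53, "e": 1.61},
    },
    "cg": {
        "mean":   {"a": 2.56, "m": 1.50, "p": 2.08, "c": 1.15, "e": 7.95},
        "median": {"a": 2.53, "m": 1.49, "p": 2.08, "c": 1.15, "e": 7.95},
        "hpd_low":  {"a": 1.44, "m": 0.76, "p": 1.23, "c": 0.80, "e": 7.56},
        "hpd_high": {"a": 3.65, "m": 2.20, "p": 2.88, "c": 1.50, "e": 8.31},
    },
    "bl": {
        "mean":   {"a": 0.59, "m": 1.00, "p": 3.10, "c": 1.19, "e": 7.00},
        "median": {"a": 0.54, "m": 1.00, "p": 3.12, "c": 1.19, "e": 6.99},
        "hpd_low":  {"a": 0.0004, "m": 0.39, "p": 2.31, "c": 0.86, "e": 6.67},
        "hpd_high": {"a": 1.49, "m": 1.59, "p": 3.86, "c": 1.54, "e": 7.34},
    },
    "hw": {
        "mean":   {"a": 1.65, "m": 1.37, "p": 1.77, "c": 1.12, "e": 5.96},
        "median": {"a": 1.61, "m": 1.36, "p": 1.78, "c": 1.11, "e": 5.96},
        "hpd_low":  {"a": 0.86, "m": 0.79, "p": 1.14, "c": 0.83, "e": 5.68},
        "hpd_high": {"a": 2.50, "m": 1.94, "p": 2.41, "c": 1.44, "e": 6.25},
    },
}

#: Posterior summaries of log-survival variance components (no permanent
#: environment term: one survival outcome per kid).
SURVIVAL_COMPONENTS: dict[str, dict[str, float]] = {
    "mean":   {"a": 0.05, "m": 0.05, "c": 1.78, "e": 0.05},
    "median": {"a": 0.06, "m": 0.06, "c": 1.81, "e": 0.05},
    "hpd_low":  {"a": 0.03, "m": 0.03, "c": 1.35, "e": 0.03},
    "hpd_high": {"a": 0.10, "m": 0.10, "c": 2.32, "e": 0.09},
}

#: Posterior additive genetic correlations of BW with each conformation trait.
GENETIC_CORRELATIONS: dict[str, dict[str, float]] = {
    "bw_cg": {"mean": 0.79, "median": 0.75, "hpd_low": 0.52, "hpd_high": 0.90},
    "bw_bl": {"mean": 0.65, "median": 0.61, "hpd_low": 0.24, "hpd_high": 0.85},
    "bw_hw": {"mean": 0.74, "median": 0.72, "hpd_low": 0.47, "hpd_high": 0.87},
}

#: Study cohort structure: kid counts by age class and pedigree composition.
STUDY_COUNTS = {
    "kids": 1538,
    "dams": 645,
    "sires": 106,
    "records_by_age": {"birth": 1538, "3mo": 1270, "6mo": 992, "9mo": 787, "12mo": 705},
    "survival_records": 1149,
}

#: Cohort descriptive targets used to parameterise the generator defaults.
DESCRIPTIVES = {
    "bw_age_means": {"birth": 2.1, "3mo": 6.4, "6mo": 9.0, "9mo": 11.4, "12mo": 13.6},
    "bw_age_sds": {"birth": 0.5, "3mo": 1.6, "6mo": 2.2, "9mo": 2.5, "12mo": 2.9},
    "phenotypic_correlations": {"bw_cg": 0.95, "bw_bl": 0.94, "bw_hw": 0.93},
    "mean_litter_size": 1.4,
    "mortality_one_year": 0.316,
    "mortality_twin": 0.42,
    "mortality_single": 0.242,
    "sex_contrast_kg": 0.58,     # male minus female body weight
    "birth_type_contrast_kg": -1.0,  # twin minus single body weight
    "censoring_horizon_days": 360,
}


def components_vector(trait: str, stat: str = "mean") -> list[float]:
    """Growth components for *trait* as the ordered list (a, m, p, c, e)."""
    table = GROWTH_COMPONENTS[trait][stat]
    return [table[k] for k in COMPONENT_ORDER]
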