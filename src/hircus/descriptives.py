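"""Descriptive statistics layer: growth means, correlations, mortality.

Reproduces the cohort-description numbers on any records table: per-age
mean +/- SD of the four traits, phenotypic correlations of body weight with
each conformation trait, litter size overall and per province, and one-year
mortality overall and stratified by birth type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import AGE_CLASSES, TRAITS, KidRecords

__all__ = ["growth_summary", "phenotypic_correlations", "mortality_report"]


def growth_summary(records: KidRecords) -> pd.DataFrame:
    """Per age class and trait: mean, SD (ddof 0) and record count.

    Missing measurements are excluded pairwise; an age class without records
    simply yields no rows.
    """
    meas = records.measures
    if len(meas) == 0:
        raise ValueError("no measurement records")
    rows = []
    for age in AGE_CLASSES:
        sub = meas[meas["age_class"] == age]
        for t in TRAITS:
            x = sub[t].dropna()
            if len(x) == 0:
                continue
            rows.append(
                {
                    "age_class": age,
                    "trait": t,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=0)),
                    "n": int(len(x)),
                }
            )
    return pd.DataFrame(rows)


def _corr(x: pd.Series, y: pd.Series) -> float:
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        return float("nan")
    xv, yv = x[ok], y[ok]
    if xv.std(ddof=0) == 0 or yv.std(ddof=0) == 0:
        return float("nan")  # undefined for a constant vector
    return float(np.corrcoef(xv, yv)[0, 1])


def phenotypic_correlations(
    records: KidRecords, within_age: bool = False
) -> pd.DataFrame:
    """Product-moment correlations of BW with CG/BL/HW on complete pairs.

    By default records are pooled across age classes (so the age trend itself
    contributes); ``within_age=True`` reports the correlation inside every
    age class instead.
    """
    meas = records.measures
    rows = []
    if within_age:
        for age in AGE_CLASSES:
            sub = meas[meas["age_class"] == age]
            for t in TRAITS[1:]:
                rows.append(
                    {"age_class": age, "pair": f"bw_{t}", "r": _corr(sub["bw"], sub[t])}
                )
    else:
        for t in TRAITS[1:]:
            rows.append(
                {"age_class": "pooled", "pair": f"bw_{t}", "r": _corr(meas["bw"], meas[t])}
            )
    return pd.DataFrame(rows)


def mortality_report(records: KidRecords, horizon: int = 360) -> dict:
    """One-year mortality (overall, by birth type), litter size, age counts.

    Mortality counts a kid as dead when it is uncensored with survival time
    below the horizon; the denominator is the kids carrying a survival
    outcome.  Litter size is kids per dam birth event (dam x birth date).
    """
    kids = records.kids
    has_outcome = kids["survival_days"].notna()
    obs = kids[has_outcome]
    dead = (~obs["censored"].astype(bool)) & (obs["survival_days"] < horizon)

    def _rate(mask) -> float:
        return float(dead[mask].mean()) if mask.sum() else float("nan")

    litters = kids.groupby(["dam", "birth_date"], sort=False).size()
    prov_litter = (
        kids.groupby(["province", "dam", "birth_date"], sort=False)
        .size()
        .groupby("province")
        .mean()
        .to_dict()
    )
    counts = {
        age: int((records.measures["age_class"] == age).sum()) for age in AGE_CLASSES
    }
    by_type = {
        bt: _rate(obs["birth_type"] == bt) for bt in ("single", "twin")
    }
    return {
        "n_kids": int(len(kids)),
        "n_with_outcome": int(has_outcome.sum()),
        "mortality": float(dead.mean()) if len(obs) else float("nan"),
        "mortality_by_birth_type": by_type,
        "mean_litter_size": float(litters.mean()),
        "litter_size_by_province": {k: float(v) for k, v in prov_litter.items()},
        "records_by_age": counts,
        "horizon": horizon,
    }


def describe_text(records: KidRecords) -> str:
    """Human-readable report block combining the three summaries."""
    g = growth_summary(records)
    bw = g[g["trait"] == "bw"].set_index("age_class")
    c = phenotypic_correlations(records).set_index("pair")["r"]
    m = mortality_report(records)
    lines = ["Growth (body weight, kg):"]
    for age in AGE_CLASSES:
        if age in bw.index:
            row = bw.loc[age]
            lines.append(
                f"  {age:>6}: {row['mean']:6.2f} +/- {row['sd']:.2f}  (n={int(row['n'])})"
            )
    lines.append(
        "Phenotypic correlations of BW with CG/BL/HW: "
        + ", ".join(f"{c[f'bw_{t}']:.2f}" for t in ("cg", "bl", "hw"))
    )
    lines.append(
        f"Mean litter size: {m['mean_litter_size']:.2f} "
        + " ".join(
            f"({p}: {v:.2f})" for p, v in sorted(m["litter_size_by_province"].items())
        )
    )
    mbt = m["mortality_by_birth_type"]
    lines.append(
        f"Mortality to {m['horizon']} d: {100 * m['mortality']:.1f}% overall "
        f"(singles {100 * mbt['single']:.1f}%, twins {100 * mbt['twin']:.1f}%) "
        f"on {m['n_with_outcome']} kids with outcomes"
    )
    return "\n".join(lines)
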