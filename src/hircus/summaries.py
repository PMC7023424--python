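"""Posterior summaries and genetic-parameter arithmetic.

Chains are reduced to the quantities a breeder reads: posterior mean, median
and highest-posterior-density (HPD) interval for every (co)variance
component, plus the derived ratios

    s2_ph = s2_a + s2_m + s2_p + s2_c + s2_e     phenotypic variance
    h2    = s2_a / s2_ph                          heritability
    r     = (s2_a + s2_p) / s2_ph                 repeatability
    r_g   = g12 / sqrt(g11 * g22)                 genetic correlation

Derived quantities are always computed sample-wise first and summarised
afterwards (the posterior of a ratio, never a ratio of posterior summaries).
Convergence is screened numerically: effective sample size from the initial
positive sequence of autocorrelations, and a Geweke-style z comparing early
and late chain segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth_model import MCMCChain

__all__ = [
    "hpd_interval",
    "heritability",
    "repeatability",
    "genetic_correlation",
    "phenotypic_variance",
    "derived_growth_samples",
    "summarize_chain",
    "effective_sample_size",
    "geweke_z",
    "diagnostics",
]


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(prob * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        if n == 1:
            return float(x[0]), float(x[0])
        raise ValueError("need at least one finite sample")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    k = int(np.ceil(prob * n))
    k = min(max(k, 2), n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _component_arrays(components) -> list[np.ndarray]:
    arrs = [np.atleast_1d(np.asarray(v, dtype=float)) for v in components]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("variance components must be nonnegative")
    return arrs


def phenotypic_variance(components) -> np.ndarray:
    """s2_ph as the element-wise sum of the five components (a, m, p, c, e)."""
    arrs = _component_arrays(components)
    return np.sum(arrs, axis=0)


def heritability(components) -> np.ndarray:
    """h2 = s2_a / s2_ph element-wise; components ordered (a, m, p, c, e)."""
    arrs = _component_arrays(components)
    total = np.sum(arrs, axis=0)
    if np.any(total <= 0):
        raise ValueError("total phenotypic variance must be positive")
    return arrs[0] / total


def repeatability(components) -> np.ndarray:
    """r = (s2_a + s2_p) / s2_ph element-wise; components ordered (a, m, p, c, e)."""
    arrs = _component_arrays(components)
    total = np.sum(arrs, axis=0)
    if np.any(total <= 0):
        raise ValueError("total phenotypic variance must be positive")
    return (arrs[0] + arrs[2]) / total


def genetic_correlation(g11, g12, g22) -> np.ndarray:
    """r_g = g12 / sqrt(g11 g22) element-wise; no artificial clipping."""
    g11 = np.atleast_1d(np.asarray(g11, dtype=float))
    g22 = np.atleast_1d(np.asarray(g22, dtype=float))
    g12 = np.atleast_1d(np.asarray(g12, dtype=float))
    if np.any(g11 <= 0) or np.any(g22 <= 0):
        raise ValueError("additive variances must be positive")
    return g12 / np.sqrt(g11 * g22)


def derived_growth_samples(chain: MCMCChain) -> pd.DataFrame:
    """Per-sample h2 and r for both traits plus r_g, from a growth chain."""
    s = chain.samples
    out = {}
    for tix, suffix in ((1, "1"), (2, "2")):
        comps = [s[f"{t}{tix}{tix}"].to_numpy() for t in ("a", "m", "p", "c", "e")]
        out[f"h2_{suffix}"] = heritability(comps)
        out[f"r_{suffix}"] = repeatability(comps)
        out[f"s2_ph_{suffix}"] = phenotypic_variance(comps)
    out["r_g"] = genetic_correlation(
        s["a11"].to_numpy(), s["a12"].to_numpy(), s["a22"].to_numpy()
    )
    return pd.DataFrame(out)


def _summary_row(trait, param, samples, prob) -> dict:
    lo, hi = hpd_interval(samples, prob)
    return {
        "trait": trait,
        "parameter": param,
        "mean": float(np.mean(samples)),
        "median": float(np.median(samples)),
        "hpd_low": lo,
        "hpd_high": hi,
    }


def summarize_chain(chain: MCMCChain, prob: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: one row per component and derived parameter.

    Growth chains yield, per trait, the five variance components plus h2 and
    r, followed by the genetic-correlation row; survival chains yield the
    regression coefficients, four components and h2.
    """
    if len(chain.samples) == 0:
        raise ValueError("empty chain")
    s = chain.samples
    rows = []
    if chain.kind == "growth":
        traits = chain.meta.get("trait_pair", ["trait1", "trait2"])
        derived = derived_growth_samples(chain)
        for tix, trait in ((1, traits[0]), (2, traits[1])):
            for comp in ("a", "m", "p", "c", "e"):
                rows.append(_summary_row(
                    trait, f"s2_{comp}", s[f"{comp}{tix}{tix}"].to_numpy(), prob
                ))
            rows.append(_summary_row(trait, "h2", derived[f"h2_{tix}"].to_numpy(), prob))
            rows.append(_summary_row(trait, "r", derived[f"r_{tix}"].to_numpy(), prob))
        pair = f"{traits[0]}_{traits[1]}"
        rows.append(_summary_row(pair, "r_g", derived["r_g"].to_numpy(), prob))
        rows.append(_summary_row(pair, "g12", s["a12"].to_numpy(), prob))
    elif chain.kind == "survival":
        for param in s.columns:
            rows.append(_summary_row("survival", param, s[param].to_numpy(), prob))
        if all(c in s.columns for c in ("s2_a", "s2_m", "s2_c", "s2_e")):
            from .survival_model import survival_heritability

            h2 = survival_heritability(
                [s[c].to_numpy() for c in ("s2_a", "s2_m", "s2_c", "s2_e")]
            )
            rows.append(_summary_row("survival", "h2", h2, prob))
    else:
        for param in s.columns:
            rows.append(_summary_row(chain.kind, param, s[param].to_numpy(), prob))
    return pd.DataFrame(rows)


def effective_sample_size(x) -> float:
    """ESS from the initial positive sequence of the autocorrelation function."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    v = np.dot(x, x) / n
    if v == 0:
        return 1.0
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / v
    tau = 1.0
    for k in range(1, n - 1):
        if rho[k] <= 0:
            break
        tau += 2.0 * rho[k]
    return float(min(n, max(1.0, n / tau)))


def geweke_z(x, first: float = 0.1, last: float = 0.5) -> float:
    """Z score comparing the means of the first and last chain fractions.

    Segment variances are corrected for autocorrelation through the segment
    ESS, following the usual 10% / 50% window convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[n - max(int(last * n), 2):]
    va = np.var(a, ddof=1) / effective_sample_size(a)
    vb = np.var(b, ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def diagnostics(chain: MCMCChain, min_samples: int = 100) -> pd.DataFrame:
    """Per-parameter ESS and Geweke z; flags degenerate (constant) traces."""
    if len(chain.samples) < min_samples:
        raise ValueError(f"need at least {min_samples} retained samples")
    rows = []
    for col in chain.samples.columns:
        x = chain.samples[col].to_numpy()
        constant = bool(np.ptp(x) == 0)
        rows.append(
            {
                "parameter": col,
                "ess": 1.0 if constant else effective_sample_size(x),
                "geweke_z": 0.0 if constant else geweke_z(x),
                "constant": constant,
            }
        )
    return pd.DataFrame(rows)


def plot_chain(chain: MCMCChain, path, parameters=None) -> None:
    """Trace + posterior-density panels written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = list(parameters or chain.samples.columns)
    fig, axes = plt.subplots(len(params), 2, figsize=(9, 2.2 * len(params)),
                             squeeze=False)
    for i, p in enumerate(params):
        x = chain.samples[p].to_numpy()
        axes[i, 0].plot(x, lw=0.4)
        axes[i, 0].set_ylabel(p)
        axes[i, 1].hist(x, bins=40, density=True)
    axes[-1, 0].set_xlabel("retained iteration")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
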