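import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hircus.pedigree import relationship_matrix
from hircus.recovery import survival_recovery_config
from hircus.simulate import KidRecords, simulate_dataset
from hircus.survival_model import (
    SurvivalPriorSpec,
    aft_gibbs_chain,
    censor_records,
    survival_heritability,
)


def _cohort(n=6, survival_days=(90, 400, 0, 200, 360, 50), censored=None):
    if censored is None:
        censored = [d >= 360 for d in survival_days]
    kids = pd.DataFrame(
        dict(
            kid=[f"K{i}" for i in range(n)],
            sire="S1", dam=[f"D{i}" for i in range(n)],
            sex="female", birth_type="single", parity=1, herd="H1",
            village="V", province="P", birth_date="2016-03-01", season="wet",
            survival_days=list(survival_days), censored=list(censored),
        )
    )
    meas = pd.DataFrame(
        dict(kid=[f"K{i}" for i in range(n)], age_class="birth",
             bw=np.linspace(1.5, 3.0, n), cg=np.nan, bl=np.nan, hw=np.nan)
    )
    return KidRecords(kids, meas)


class TestCensoring:
    def test_death_keeps_observed_day(self):
        design = censor_records(_cohort())
        k0 = design.kid_ids.index("K0")
        assert not design.censored[k0]
        assert design.log_time[k0] == pytest.approx(np.log(90))

    def test_alive_past_horizon_censored_at_horizon(self):
        design = censor_records(_cohort(survival_days=(400, 90, 0, 100, 20, 30),
                                        censored=[True] + [False] * 5))
        k0 = design.kid_ids.index("K0")
        assert design.censored[k0]
        assert design.time_days[k0] == 360

    def test_zero_day_death_floored_before_log(self):
        design = censor_records(_cohort())
        k2 = design.kid_ids.index("K2")
        assert design.log_time[k2] == pytest.approx(np.log(0.5))

    def test_negative_days_rejected(self):
        rec = _cohort(survival_days=(-1, 10, 20, 30, 40, 50))
        with pytest.raises(ValueError, match="negative"):
            censor_records(rec)

    def test_all_censored_unidentifiable(self):
        rec = _cohort(survival_days=(360,) * 6, censored=[True] * 6)
        with pytest.raises(ValueError, match="censored"):
            censor_records(rec)

    def test_horizon_monotonicity(self):
        rec = _cohort()
        n_censored = [censor_records(rec, horizon=h).censored.sum()
                      for h in (90, 180, 360, 500)]
        assert n_censored == sorted(n_censored, reverse=True)

    def test_default_cohort_censored_fraction(self, default_dataset):
        ped, rec = default_dataset
        design = censor_records(rec, ped)
        frac = design.censored.mean()
        assert frac == pytest.approx(0.684, abs=0.1)

    def test_group_levels_are_herd_year_season(self, default_dataset):
        ped, rec = default_dataset
        design = censor_records(rec, ped)
        assert all(len(g.split(":")) == 3 for g in design.grp_labels)
        assert len(design.grp_labels) <= 8 * 4 * 2


class TestPriors:
    def test_default_flat(self):
        pdf, ps = SurvivalPriorSpec().arrays()
        assert np.all(pdf == -2.0) and np.all(ps == 0.0)

    def test_proper_needs_positive_df(self):
        with pytest.raises(ValueError, match="df"):
            SurvivalPriorSpec(df={"a": -1.0, "m": 4, "c": 4, "e": 4},
                              scale={"a": 0.1, "m": 0.1, "c": 0.1, "e": 0.1})


class TestChain:
    def test_degenerate_limit_matches_ols(self):
        """No censoring, no random effects: the posterior mean slope equals
        the least-squares slope of log-time on birth weight."""
        cfg = survival_recovery_config(n_kids=500, n_dams=250, seed=3)
        sp = dataclasses.replace(cfg.survival, var_a=0.0, var_m=0.0,
                                 var_c=0.0, var_e=0.09,
                                 censoring_horizon=10 ** 7, intercept=6.7)
        cfg = dataclasses.replace(cfg, survival=sp)
        ped, rec = simulate_dataset(cfg)
        design = censor_records(rec, ped, horizon=10 ** 7)
        assert design.censored.sum() == 0
        chain = aft_gibbs_chain(
            design, None, n_iter=3000, burn_in=500, thin=2, seed=4,
            include_additive=False, include_maternal=False,
            include_common_env=False,
        )
        b_ols = np.polyfit(design.birth_weight, design.log_time, 1)[0]
        b1 = chain.samples["b1"]
        mcse = b1.std() / np.sqrt(len(b1) / 10)
        assert abs(b1.mean() - b_ols) < 3 * mcse

    def test_same_seed_identical(self, small_dataset):
        ped, rec = small_dataset
        design = censor_records(rec, ped)
        A = relationship_matrix(ped)
        kw = dict(n_iter=500, burn_in=100, thin=2, seed=8)
        c1 = aft_gibbs_chain(design, A, **kw)
        c2 = aft_gibbs_chain(design, A, **kw)
        assert (c1.samples.values == c2.samples.values).all()

    def test_augmented_times_exceed_log_horizon(self, small_survival_chain):
        meta = small_survival_chain.meta
        assert meta["min_augmented_log_time"] > np.log(meta["horizon"])

    def test_variances_positive_and_counts(self, small_survival_chain):
        chain = small_survival_chain
        s = chain.samples
        assert (s[["s2_a", "s2_m", "s2_c", "s2_e"]].values > 0).all()
        meta = chain.meta
        assert len(chain) == (meta["n_iter"] - meta["burn_in"]) // meta["thin"]

    def test_exponential_family_matches_mle_oracle(self):
        """Exponential-error AFT with fixed effects only agrees with a
        direct maximum-likelihood fit of the same model."""
        rng = np.random.default_rng(2)
        n = 400
        bw = rng.normal(2.1, 0.5, n)
        t = rng.exponential(np.exp(4.0 + 0.4 * bw))
        cens = t >= 360
        days = np.where(cens, 360, np.maximum(t, 1)).astype(int)
        kids = pd.DataFrame(
            dict(kid=[f"K{i}" for i in range(n)], sire="S",
                 dam=[f"D{i}" for i in range(n)], sex="f",
                 birth_type="single", parity=1, herd="H1", village="V",
                 province="P", birth_date="2016-01-01", season="wet",
                 survival_days=days, censored=cens)
        )
        meas = pd.DataFrame(dict(kid=[f"K{i}" for i in range(n)],
                                 age_class="birth", bw=bw, cg=np.nan,
                                 bl=np.nan, hw=np.nan))
        design = censor_records(KidRecords(kids, meas))
        chain = aft_gibbs_chain(
            design, None, n_iter=6000, burn_in=1000, thin=5, seed=3,
            include_additive=False, include_maternal=False,
            include_common_env=False, error_family="exponential", mh_step=0.1,
        )

        def nll(b):
            eta = b[0] + b[1] * design.birth_weight
            ll = np.where(design.censored,
                          -design.time_days * np.exp(-eta),
                          -eta - design.time_days * np.exp(-eta))
            return -ll.sum()

        mle = minimize(nll, [5.0, 0.0]).x
        assert abs(chain.samples["b0"].mean() - mle[0]) < 0.2
        assert abs(chain.samples["b1"].mean() - mle[1]) < 0.1
        assert "s2_e" not in chain.samples.columns

    def test_unknown_error_family(self, small_dataset):
        ped, rec = small_dataset
        design = censor_records(rec, ped)
        with pytest.raises(ValueError, match="error_family"):
            aft_gibbs_chain(design, None, error_family="weibull",
                            include_additive=False)


class TestHeritability:
    def test_zero_additive(self):
        assert survival_heritability((0.0, 1.0, 1.0, 1.0)) == 0.0

    def test_equal_components(self):
        assert survival_heritability((2.0, 2.0, 2.0, 2.0)) == pytest.approx(0.25)

    def test_reference_component_arithmetic(self):
        from hircus.reference import SURVIVAL_COMPONENTS

        m = SURVIVAL_COMPONENTS["mean"]
        h2 = survival_heritability((m["a"], m["m"], m["c"], m["e"]))
        assert h2 == pytest.approx(0.0259, abs=1e-3)

    def test_vectorised_over_samples(self):
        h2 = survival_heritability(
            (np.array([0.0, 1.0]), np.array([1.0, 1.0]),
             np.array([1.0, 1.0]), np.array([2.0, 1.0]))
        )
        assert np.allclose(h2, [0.0, 0.25])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            survival_heritability((0.0, 0.0, 0.0, 0.0))
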