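import dataclasses

import numpy as np
import pandas as pd
import pytest

from hircus.pedigree import Pedigree, PedigreeRecord
from hircus.simulate import (
    AGE_CLASSES,
    KidRecords,
    SimulationConfig,
    build_component_covariances,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
)

from conftest import no_contrast_config


class TestConfig:
    def test_negative_variance_rejected(self):
        gv = SimulationConfig().growth_variances
        gv["bw"]["a"] = -1.0
        with pytest.raises(ValueError, match="negative variance"):
            SimulationConfig(growth_variances=gv)

    def test_twin_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(twin_fraction=1.5)

    def test_infeasible_counts(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_pedigree(SimulationConfig(n_kids=1000, n_dams=10,
                                               years=(2016, 2017)))

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_kids=50, n_dams=30, n_sires=5, seed=3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg


class TestPedigreeStructure:
    def test_default_counts_match_study_structure(self, default_dataset):
        ped, rec = default_dataset
        assert len(rec) == 1538
        assert rec.kids["dam"].nunique() == 645
        assert rec.kids["sire"].nunique() <= 106

    def test_no_twins_when_fraction_zero(self):
        herd = simulate_pedigree(
            SimulationConfig(n_kids=200, n_dams=120, n_sires=10,
                             twin_fraction=0.0, seed=2)
        )
        assert not herd.litters["twin"].any()

    def test_mean_litter_size_matches_binomial_expectation(self):
        cfg = SimulationConfig(n_kids=14000, n_dams=4000, n_sires=100,
                               twin_fraction=0.4, seed=4)
        herd = simulate_pedigree(cfg)
        litters = herd.litters.groupby(["dam", "year"]).size()
        assert litters.mean() == pytest.approx(1.4, abs=0.02)

    def test_sires_serve_within_their_herd(self):
        herd = simulate_pedigree(SimulationConfig(n_kids=300, n_dams=160,
                                                  n_sires=16, seed=5))
        lit = herd.litters
        assert (lit["sire"].map(herd.sire_herd) == lit["herd"]).all()


class TestBreedingValues:
    def test_zero_G0_gives_zero_values(self):
        ped = Pedigree([PedigreeRecord(f"F{i}") for i in range(10)])
        a = simulate_breeding_values(ped, np.zeros((2, 2)), seed=0)
        assert np.all(a == 0.0)

    def test_non_psd_G0_rejected(self):
        ped = Pedigree([PedigreeRecord("F0")])
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), 0)

    def test_founder_sample_variance_matches_G0(self):
        ped = Pedigree([PedigreeRecord(f"F{i}") for i in range(5000)])
        G0 = np.diag([0.58, 2.56])
        a = simulate_breeding_values(ped, G0, seed=1)
        var = a.var(axis=0)
        assert np.all(np.abs(var - np.diag(G0)) < 0.05 * np.diag(G0))

    def test_parent_offspring_covariance_is_half_G0(self):
        n = 5000
        recs = [PedigreeRecord(f"P{i}") for i in range(n)]
        recs += [PedigreeRecord(f"K{i}", sire_id=f"P{i}") for i in range(n)]
        ped = Pedigree(recs)
        a = simulate_breeding_values(ped, np.array([[1.0]]), seed=2)[:, 0]
        cov = np.cov(a[:n], a[n:])[0, 1]
        assert cov == pytest.approx(0.5, abs=0.04)


class TestRecords:
    def test_deterministic_in_fixed_effects_when_variances_zero(self):
        cfg = no_contrast_config(n_kids=40, n_dams=25, n_sires=5, n_herds=2,
                                 seed=6)
        gv = {t: {k: 0.0 for k in comps}
              for t, comps in cfg.growth_variances.items()}
        cfg = dataclasses.replace(cfg, growth_variances=gv)
        ped, rec = simulate_dataset(cfg)
        for age in AGE_CLASSES:
            sub = rec.records_at(age)
            assert np.allclose(sub["bw"], cfg.age_means["bw"][age])

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_kids=120, n_dams=70, n_sires=8, seed=11)
        for run in ("x", "y"):
            ped, rec = simulate_dataset(cfg)
            rec.write(tmp_path / f"{run}.csv")
        assert (tmp_path / "x.csv").read_bytes() == (tmp_path / "y.csv").read_bytes()

    def test_records_file_round_trip(self, tmp_path, small_dataset):
        _, rec = small_dataset
        path = tmp_path / "records.csv"
        rec.write(path)
        back = KidRecords.read(path)
        assert len(back) == len(rec)
        assert back.n_measurements == rec.n_measurements
        left = back.kids.sort_values("kid").reset_index(drop=True).sort_index(axis=1)
        right = rec.kids.sort_values("kid").reset_index(drop=True).sort_index(axis=1)
        pd.testing.assert_frame_equal(left, right, check_dtype=False)

    def test_kid_record_view(self, small_dataset):
        _, rec = small_dataset
        kids = rec.to_kid_records()
        assert len(kids) == len(rec)
        k = kids[0]
        assert k.censored == (k.survival_days == 360)
        assert set(k.measurements) <= set(AGE_CLASSES)

    def test_measurements_only_while_alive(self, default_dataset):
        _, rec = default_dataset
        merged = rec.measures.merge(rec.kids, on="kid")
        age_days = {"birth": 0, "3mo": 90, "6mo": 180, "9mo": 270, "12mo": 360}
        days = merged["age_class"].map(age_days)
        alive = merged["censored"] | (merged["survival_days"] > days) | (days == 0)
        assert alive.all()

    def test_twelve_month_mean_near_cohort_target(self, default_dataset):
        _, rec = default_dataset
        bw12 = rec.records_at("12mo")["bw"]
        assert bw12.mean() == pytest.approx(13.6, abs=0.5)

    def test_birth_mean_near_cohort_target_across_seeds(self, calibration_cohorts):
        # herd-level common effects (8 herds) dominate the seed-to-seed
        # wobble of the cohort mean, hence the generous band
        means = [rec.records_at("birth")["bw"].mean()
                 for _, rec in calibration_cohorts]
        assert np.mean(means) == pytest.approx(2.1, abs=0.2)

    def test_component_covariances_psd_and_one_factor(self):
        covs = build_component_covariances(SimulationConfig())
        for comp, C in covs.items():
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestVarianceDecomposition:
    def test_moment_oracle_recovers_components(self):
        """Pairwise-covariance U-statistics on a large no-herd cohort recover
        every generative component of body weight within 10%."""
        cfg = no_contrast_config(
            n_kids=100000, n_dams=20000, n_sires=2000, n_herds=500, seed=11,
        )
        gv = {t: dict(d) for t, d in cfg.growth_variances.items()}
        for t in gv:
            gv[t]["c"] = 0.0
        cfg = dataclasses.replace(cfg, growth_variances=gv)
        cfg.attrition.update({"6mo": 0.0, "9mo": 0.0, "12mo": 0.0})
        ped, rec = simulate_dataset(cfg)
        m = rec.measures.pivot(index="kid", columns="age_class", values="bw")
        kids = rec.kids.set_index("kid")
        df = m.join(kids[["sire", "dam"]])
        for age in ("birth", "3mo"):
            df[age] = df[age] - df[age].mean()
        wk = (df["birth"] * df["3mo"]).mean()          # a + m + p
        e_hat = 0.5 * ((df["birth"] - df["3mo"]) ** 2).mean()
        g = df.reset_index()

        def pair_cov(group, sub=None):
            tot = 0.0
            npairs = 0.0
            for _, sdf in g.groupby(group):
                s = sdf["birth"].sum()
                n = len(sdf)
                if sub is None:
                    ssq = (sdf["birth"] ** 2).sum()
                    tot += (s * s - ssq) / 2
                    npairs += (n * n - n) / 2
                else:
                    sums = sdf.groupby(sub)["birth"].sum()
                    ns = sdf.groupby(sub).size()
                    tot += (s * s - (sums ** 2).sum()) / 2
                    npairs += (n * n - (ns ** 2).sum()) / 2
            return tot / npairs

        a_hat = 4.0 * pair_cov("sire", sub="dam")       # paternal half sibs
        m_hat = pair_cov(["dam", "sire"]) - 0.5 * a_hat  # full sibs
        p_hat = wk - a_hat - m_hat
        truth = {"a": 0.58, "m": 0.22, "p": 0.55, "e": 1.57}
        for name, est in (("a", a_hat), ("m", m_hat), ("p", p_hat), ("e", e_hat)):
            assert abs(est - truth[name]) < 0.10 * truth[name], (name, est)

    def test_mortality_strata_ordering(self):
        from hircus.descriptives import mortality_report

        worse = 0
        for seed in range(5):
            _, rec = simulate_dataset(SimulationConfig(seed=40 + seed))
            m = mortality_report(rec)["mortality_by_birth_type"]
            worse += m["twin"] > m["single"]
        assert worse >= 4
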