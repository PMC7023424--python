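import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hircus.growth_model import (
    DesignMatrices,
    ModelSpec,
    PriorSpec,
    build_design,
    gibbs_chain,
)
from hircus.pedigree import Pedigree, PedigreeRecord, relationship_matrix
from hircus.simulate import KidRecords, simulate_dataset

from conftest import no_contrast_config


def _kid_row(kid, dam="D1", sire="S1", herd="H1", **kw):
    row = dict(kid=kid, sire=sire, dam=dam, sex="female", birth_type="single",
               parity=1, herd=herd, village="V", province="P",
               birth_date="2016-01-01", season="wet",
               survival_days=360, censored=True)
    row.update(kw)
    return row


def _tiny_records(n_kids=1, ages=("birth",)):
    kids = pd.DataFrame([_kid_row(f"K{i}") for i in range(n_kids)])
    meas = pd.DataFrame(
        [dict(kid=f"K{i}", age_class=a, bw=2.0 + i, cg=25.0 + i,
              bl=np.nan, hw=np.nan)
         for i in range(n_kids) for a in ages]
    )
    return KidRecords(kids, meas)


def _tiny_pedigree(n_kids=1):
    recs = [PedigreeRecord("S1"), PedigreeRecord("D1")]
    recs += [PedigreeRecord(f"K{i}", "S1", "D1") for i in range(n_kids)]
    return Pedigree(recs)


class TestModelSpec:
    def test_first_trait_must_be_body_weight(self):
        with pytest.raises(ValueError):
            ModelSpec(trait_pair=("cg", "bw"))

    def test_unknown_second_trait(self):
        with pytest.raises(ValueError):
            ModelSpec(trait_pair=("bw", "xx"))


class TestPriorSpec:
    def test_default_is_flat(self):
        pdf, ps = PriorSpec().arrays_2d()
        assert np.all(pdf == -3.0)
        assert np.all(ps == 0.0)

    def test_proper_prior_needs_enough_df(self):
        with pytest.raises(ValueError, match="df"):
            PriorSpec(df={"a": 1.0, "m": 4, "p": 4, "c": 4, "e": 4},
                      scale={k: 0.1 * np.eye(2) for k in "ampce"})

    def test_non_psd_scale_rejected(self):
        bad = {k: 0.1 * np.eye(2) for k in "ampce"}
        bad["a"] = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            PriorSpec(df={k: 4.0 for k in "ampce"}, scale=bad)


class TestBuildDesign:
    def test_single_kid_single_record(self):
        design = build_design(_tiny_records(), _tiny_pedigree())
        assert design.X.shape == (1, 1)
        assert design.Z_a.shape == (1, 3)
        assert design.Z_m.shape == (1, 1)

    def test_repeatability_structure(self):
        ages = ("birth", "3mo", "6mo", "9mo", "12mo")
        design = build_design(_tiny_records(2, ages), _tiny_pedigree(2))
        assert design.Z_p.shape[1] == 2
        counts = np.asarray(design.Z_p.sum(axis=0)).ravel()
        assert list(counts) == [5, 5]

    def test_column_counts_match_records_table(self, small_dataset):
        ped, rec = small_dataset
        design = build_design(rec, ped, ModelSpec(trait_pair=("bw", "bl")))
        meas = rec.measures.merge(rec.kids, on="kid")
        cells = meas[["age_class", "sex", "parity", "birth_type"]].drop_duplicates()
        assert design.X.shape[1] == len(cells)
        assert design.Z_m.shape[1] == meas["dam"].nunique()
        assert design.Z_p.shape[1] == meas["kid"].nunique()
        assert design.Z_c.shape[1] == meas["herd"].nunique()
        assert design.Z_a.shape[1] == len(ped)

    def test_missing_second_trait_masked_not_dropped(self):
        rec = _tiny_records(3, ages=("birth", "3mo"))
        rec.measures.loc[2, "cg"] = np.nan
        design = build_design(rec, _tiny_pedigree(3))
        assert design.n_records == 6
        assert design.miss.sum() == 1

    def test_unknown_animal_rejected(self):
        rec = _tiny_records(2)
        with pytest.raises(ValueError, match="K1"):
            build_design(rec, _tiny_pedigree(1))

    def test_empty_records_rejected(self):
        rec = KidRecords(pd.DataFrame([_kid_row("K0")]),
                         pd.DataFrame(columns=KidRecords.MEASURE_COLUMNS))
        with pytest.raises(ValueError, match="no measurement"):
            build_design(rec, _tiny_pedigree())


class TestGibbsChain:
    def test_same_seed_identical_samples(self, small_dataset):
        ped, rec = small_dataset
        design = build_design(rec, ped)
        A = relationship_matrix(ped)
        c1 = gibbs_chain(design, A, n_iter=400, burn_in=100, thin=2, seed=5)
        c2 = gibbs_chain(design, A, n_iter=400, burn_in=100, thin=2, seed=5)
        assert (c1.samples.values == c2.samples.values).all()

    def test_retained_count_and_psd(self, small_growth_chain):
        chain = small_growth_chain
        meta = chain.meta
        expect = (meta["n_iter"] - meta["burn_in"]) // meta["thin"]
        assert len(chain) == expect
        s = chain.samples
        for term in ("a", "m", "p", "c", "e"):
            det = s[f"{term}11"] * s[f"{term}22"] - s[f"{term}12"] ** 2
            assert (s[f"{term}11"] > 0).all()
            assert (det >= -1e-12).all()
        assert (s["e11"] > 0).all() and (s["e22"] > 0).all()

    def test_bad_iteration_settings(self, small_dataset):
        ped, rec = small_dataset
        design = build_design(rec, ped)
        A = relationship_matrix(ped)
        with pytest.raises(ValueError, match="burn_in"):
            gibbs_chain(design, A, n_iter=100, burn_in=100)

    def test_mismatched_relationship_matrix(self, small_dataset):
        ped, rec = small_dataset
        design = build_design(rec, ped)
        wrong = relationship_matrix(_tiny_pedigree())
        with pytest.raises(ValueError, match="order"):
            gibbs_chain(design, wrong, n_iter=100, burn_in=10)

    def test_chain_write_read_round_trip(self, small_growth_chain, tmp_path):
        path = tmp_path / "chain.tsv"
        small_growth_chain.write(path)
        from hircus.growth_model import MCMCChain

        back = MCMCChain.read(path)
        assert back.meta["seed"] == small_growth_chain.meta["seed"]
        assert np.allclose(back.samples.values, small_growth_chain.samples.values)

    def test_missing_trait_imputation_runs(self, small_dataset):
        ped, rec = small_dataset
        rng = np.random.default_rng(0)
        meas = rec.measures.copy()
        mask = rng.random(len(meas)) < 0.3
        meas.loc[mask, "cg"] = np.nan
        rec2 = KidRecords(rec.kids, meas)
        design = build_design(rec2, ped)
        assert design.n_records == rec.n_measurements
        A = relationship_matrix(ped)
        chain = gibbs_chain(design, A, n_iter=600, burn_in=100, thin=2, seed=9)
        assert np.isfinite(chain.samples.values).all()


class TestParameterRecovery:
    def test_null_additive_variance_shrinks_to_zero(self):
        """With zero true additive variance the posterior additive share
        stays below a tenth of the residual variance."""
        cfg = no_contrast_config(n_kids=500, n_sires=50, n_dams=250,
                                 n_herds=8, seed=9)
        gv = {t: dict(d) for t, d in cfg.growth_variances.items()}
        for t in gv:
            gv[t]["a"] = 0.0
        cfg = dataclasses.replace(cfg, growth_variances=gv)
        ped, rec = simulate_dataset(cfg)
        design = build_design(rec, ped)
        A = relationship_matrix(ped)
        chain = gibbs_chain(design, A, n_iter=8000, burn_in=1000, thin=5, seed=10)
        s = chain.samples
        assert s["a11"].median() < 0.1 * s["e11"].median()

    def test_heritability_matches_parent_offspring_regression(self):
        """Single record per animal, additive + residual only: the sampler's
        posterior h2 agrees with the midparent-offspring regression oracle."""
        rng = np.random.default_rng(0)
        npair, va, ve = 400, 2.0, 2.0
        recs, kid_rows, meas_rows = [], [], []
        for i in range(npair):
            s_id, d_id, k_id = f"S{i}", f"D{i}", f"K{i}"
            recs += [PedigreeRecord(s_id), PedigreeRecord(d_id),
                     PedigreeRecord(k_id, s_id, d_id)]
            a_s, a_d = rng.normal(0, np.sqrt(va), 2)
            a_k = 0.5 * (a_s + a_d) + rng.normal(0, np.sqrt(0.5 * va))
            for aid, a in ((s_id, a_s), (d_id, a_d), (k_id, a_k)):
                y = 10 + a + rng.normal(0, np.sqrt(ve))
                kid_rows.append(_kid_row(aid, dam=f"X{aid}", sire="0"))
                meas_rows.append(dict(kid=aid, age_class="birth", bw=y,
                                      cg=y + rng.normal(0, 1),
                                      bl=np.nan, hw=np.nan))
        rec = KidRecords(pd.DataFrame(kid_rows), pd.DataFrame(meas_rows))
        ped = Pedigree(recs)
        spec = ModelSpec(trait_pair=("bw", "cg"), include_maternal=False,
                         include_common_env=False, include_permanent_env=False)
        design = build_design(rec, ped, spec)
        A = relationship_matrix(ped)
        chain = gibbs_chain(design, A, n_iter=2500, burn_in=500, thin=5, seed=11)
        h2_post = (chain.samples.a11 / (chain.samples.a11 + chain.samples.e11)).mean()
        bw = rec.measures.set_index("kid")["bw"]
        mid = np.array([(bw[f"S{i}"] + bw[f"D{i}"]) / 2 for i in range(npair)])
        off = np.array([bw[f"K{i}"] for i in range(npair)])
        h2_po = np.polyfit(mid, off, 1)[0]
        assert abs(h2_post - h2_po) < 0.1

    def test_prior_predictive_reproduces_prior_mean(self):
        """With a zero-row design, sampled covariances match the proper
        inverse-Wishart prior mean S/(df - p - 1)."""
        ped = Pedigree([PedigreeRecord(f"F{i}") for i in range(10)])
        empty = np.zeros(0)
        emptyi = np.zeros(0, dtype=np.int64)
        design0 = DesignMatrices(
            y1=empty, y2=empty, miss=emptyi,
            X=sp.csr_matrix((0, 0)), Z_a=sp.csr_matrix((0, 10)),
            Z_m=sp.csr_matrix((0, 0)), Z_p=sp.csr_matrix((0, 0)),
            Z_c=sp.csr_matrix((0, 0)),
            cell_codes=emptyi, anim_codes=emptyi, dam_codes=emptyi,
            pe_codes=emptyi, herd_codes=emptyi,
            parent_pos=ped.parent_indices(),
            cell_labels=[], animal_ids=ped.ids, dam_labels=[], pe_labels=[],
            herd_labels=[], trait_pair=("bw", "cg"), spec=ModelSpec(),
        )
        A = relationship_matrix(ped)
        pri = PriorSpec(df={k: 10.0 for k in "ampce"},
                        scale={k: 0.7 * np.eye(2) for k in "ampce"})
        chain = gibbs_chain(design0, A, priors=pri, n_iter=20000, burn_in=1000,
                            thin=2, seed=5)
        expected = 0.7 / (10 - 3)
        for col in ("a11", "e11", "e22"):
            assert chain.samples[col].mean() == pytest.approx(expected, rel=0.1)
        assert abs(chain.samples["e12"].mean()) < 0.02
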