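import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hircus.growth_model import MCMCChain
from hircus.summaries import (
    derived_growth_samples,
    diagnostics,
    effective_sample_size,
    genetic_correlation,
    geweke_z,
    heritability,
    hpd_interval,
    phenotypic_variance,
    repeatability,
    summarize_chain,
)

from _oracles import hpd_bruteforce


class TestHPD:
    def test_constant_samples_degenerate(self):
        assert hpd_interval([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_single_sample(self):
        assert hpd_interval([2.5]) == (2.5, 2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])

    def test_uniform_grid_minimum_window(self):
        lo, hi = hpd_interval(np.arange(1, 101), prob=0.95)
        assert hi - lo == 94

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(100_000), prob=0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_converges_to_range_as_prob_grows(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        lo, hi = hpd_interval(x, prob=0.9999)
        assert lo == x.min() and hi == x.max()

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=60),
           st.floats(0.2, 0.98))
    def test_matches_bruteforce_window_search(self, xs, prob):
        assert hpd_interval(xs, prob) == hpd_bruteforce(xs, prob)


class TestRatios:
    def test_reference_body_weight_heritability(self):
        h2 = heritability([0.58, 0.22, 0.55, 0.41, 1.57])
        assert np.round(h2, 2) == 0.17

    def test_reference_body_weight_repeatability_medians(self):
        r = repeatability([0.57, 0.23, 0.54, 0.42, 1.57])
        assert np.round(r, 2) == 0.33

    def test_reference_chest_girth_repeatability(self):
        r = repeatability([2.56, 1.5, 2.08, 1.15, 7.95])
        assert np.round(r, 2) == 0.30

    def test_zero_additive(self):
        assert heritability([0.0, 1, 1, 1, 1])[0] == 0.0

    def test_equal_components(self):
        assert heritability([2, 2, 2, 2, 2])[0] == pytest.approx(0.2)
        assert repeatability([2, 0, 2, 2, 2])[0] == pytest.approx(0.5)

    def test_repeatability_equals_h2_without_permanent(self):
        comps = [0.5, 0.2, 0.0, 0.3, 1.0]
        assert repeatability(comps) == pytest.approx(heritability(comps))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            heritability([0, 0, 0, 0, 0])

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            repeatability([-0.1, 1, 1, 1, 1])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0.0, 50.0), min_size=5, max_size=5)
           .filter(lambda c: sum(c) > 1e-6))
    def test_h2_bounded_by_repeatability_and_one(self, comps):
        h2 = heritability(comps)[0]
        r = repeatability(comps)[0]
        assert 0.0 <= h2 <= r <= 1.0
        assert phenotypic_variance(comps)[0] == pytest.approx(sum(comps))


class TestGeneticCorrelation:
    def test_zero_covariance(self):
        assert genetic_correlation(1.0, 0.0, 2.0)[0] == 0.0

    def test_perfect_correlation(self):
        assert genetic_correlation(0.7, 0.7, 0.7)[0] == pytest.approx(1.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            genetic_correlation(0.0, 0.1, 1.0)


def _synthetic_growth_chain():
    rng = np.random.default_rng(3)
    n = 400
    cols = {}
    for term, v in (("a", 0.6), ("m", 0.2), ("p", 0.5), ("c", 0.4), ("e", 1.6)):
        cols[f"{term}11"] = np.abs(rng.normal(v, 0.05, n))
        cols[f"{term}22"] = np.abs(rng.normal(4 * v, 0.2, n))
        cols[f"{term}12"] = 0.5 * np.sqrt(cols[f"{term}11"] * cols[f"{term}22"])
    samples = pd.DataFrame(cols)
    return MCMCChain(samples, {"kind": "growth", "trait_pair": ["bw", "cg"],
                               "n_iter": 400, "burn_in": 0, "thin": 1})


class TestSummarizeChain:
    def test_constant_chain_collapses(self):
        samples = pd.DataFrame({c: np.full(50, i + 1.0) for i, c in enumerate(
            ["a11", "a12", "a22", "m11", "m12", "m22", "p11", "p12", "p22",
             "c11", "c12", "c22", "e11", "e12", "e22"])})
        chain = MCMCChain(samples, {"kind": "growth", "trait_pair": ["bw", "cg"]})
        table = summarize_chain(chain)
        row = table[(table.trait == "bw") & (table.parameter == "s2_a")].iloc[0]
        assert row["mean"] == row["median"] == row["hpd_low"] == row["hpd_high"]

    def test_schema_and_derived_rows(self, small_growth_chain):
        table = summarize_chain(small_growth_chain)
        assert list(table.columns) == ["trait", "parameter", "mean", "median",
                                       "hpd_low", "hpd_high"]
        bw = table[table.trait == "bw"]["parameter"].tolist()
        assert bw == ["s2_a", "s2_m", "s2_p", "s2_c", "s2_e", "h2", "r"]
        assert "r_g" in table["parameter"].tolist()

    def test_invariant_to_sample_order(self):
        chain = _synthetic_growth_chain()
        shuffled = MCMCChain(
            chain.samples.sample(frac=1.0, random_state=1).reset_index(drop=True),
            chain.meta,
        )
        pd.testing.assert_frame_equal(summarize_chain(chain),
                                      summarize_chain(shuffled))

    def test_ratios_summarised_samplewise(self):
        chain = _synthetic_growth_chain()
        derived = derived_growth_samples(chain)
        s = chain.samples
        manual = s["a11"] / (s["a11"] + s["m11"] + s["p11"] + s["c11"] + s["e11"])
        assert np.allclose(derived["h2_1"], manual)
        table = summarize_chain(chain)
        h2_row = table[(table.trait == "bw") & (table.parameter == "h2")].iloc[0]
        assert h2_row["mean"] == pytest.approx(manual.mean())

    def test_survival_chain_summary(self, small_survival_chain):
        table = summarize_chain(small_survival_chain)
        params = table["parameter"].tolist()
        assert "b1" in params and "h2" in params

    def test_empty_chain_rejected(self):
        chain = MCMCChain(pd.DataFrame({"a11": []}), {"kind": "growth"})
        with pytest.raises(ValueError):
            summarize_chain(chain)

    def test_growth_chain_sample_identities(self, small_growth_chain):
        """Per retained sample: h2 <= r <= 1 and s2_ph equals the sum."""
        derived = derived_growth_samples(small_growth_chain)
        s = small_growth_chain.samples
        for tix in (1, 2):
            h2 = derived[f"h2_{tix}"]
            r = derived[f"r_{tix}"]
            assert ((h2 >= 0) & (h2 <= r + 1e-12) & (r <= 1 + 1e-12)).all()
            total = sum(s[f"{t}{tix}{tix}"] for t in ("a", "m", "p", "c", "e"))
            assert np.allclose(derived[f"s2_ph_{tix}"], total)


class TestDiagnostics:
    def test_iid_ess_near_n(self):
        rng = np.random.default_rng(0)
        n = 4000
        ess = effective_sample_size(rng.standard_normal(n))
        assert abs(ess - n) < 0.2 * n

    def test_ar1_ess_closed_form(self):
        rng = np.random.default_rng(1)
        n, rho = 20000, 0.9
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()
        expected = n * (1 - rho) / (1 + rho)
        assert abs(effective_sample_size(x) - expected) < 0.3 * expected

    def test_constant_chain_flagged(self):
        chain = MCMCChain(
            pd.DataFrame({"a11": np.ones(200)}), {"kind": "growth"}
        )
        table = diagnostics(chain)
        assert table.iloc[0]["constant"]
        assert table.iloc[0]["ess"] == 1.0

    def test_short_chain_rejected(self):
        chain = MCMCChain(pd.DataFrame({"a11": np.ones(10)}), {"kind": "growth"})
        with pytest.raises(ValueError):
            diagnostics(chain)

    def test_geweke_near_zero_for_iid(self):
        rng = np.random.default_rng(2)
        z = geweke_z(rng.standard_normal(5000))
        assert abs(z) < 3.0

    def test_diagnostics_table(self, small_growth_chain):
        table = diagnostics(small_growth_chain)
        assert set(table.columns) == {"parameter", "ess", "geweke_z", "constant"}
        assert (table["ess"] >= 1.0).all()

    def test_plot_files(self, small_growth_chain, tmp_path):
        from hircus.summaries import plot_chain

        out = tmp_path / "trace.png"
        plot_chain(small_growth_chain, out, parameters=["a11", "e11"])
        assert out.stat().st_size > 0
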