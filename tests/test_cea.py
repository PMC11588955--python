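"""ICER comparison, sensitivity analyses, and distribution fitters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from embocea.cea import (
    CEAComparison,
    beta_from_mean_sd,
    compare,
    gamma_from_mean_sd,
    one_way_dsa,
    run_arms,
    run_psa,
    threshold_search,
)
from embocea.engine import run_cohort


class TestCompare:
    def test_published_primary_deltas(self):
        c = CEAComparison(cost_tare=2_354_206, cost_deb=0.0,
                          qaly_tare=0.455062, qaly_deb=0.0, wtp=5e6)
        assert c.icer == pytest.approx(5_173_591, rel=1e-4)
        assert not c.cost_effective

    def test_ancillary_ratio(self):
        c = CEAComparison(1_974_434, 0.0, 0.475, 0.0, wtp=5e6)
        assert c.icer == pytest.approx(4_156_703, rel=1e-4)
        assert c.cost_effective

    def test_identical_results_undefined_icer(self, params_itt):
        res = run_cohort("deb", params_itt)
        c = compare(res, res, wtp=5e6)
        assert c.delta_cost == 0.0 and c.delta_qaly == 0.0
        assert c.icer is None

    def test_icer_identity(self, params_itt):
        tare, deb = run_arms(params_itt)
        c = compare(tare, deb, wtp=5e6)
        assert c.icer * c.delta_qaly == pytest.approx(c.delta_cost)
        assert c.nmb_tare - c.nmb_deb == pytest.approx(
            c.wtp * c.delta_qaly - c.delta_cost)

    def test_mixed_populations_rejected(self, params_itt, params_pp):
        with pytest.raises(ValueError, match="population"):
            compare(run_cohort("tare", params_pp),
                    run_cohort("deb", params_itt), wtp=5e6)

    def test_dominance_labels(self):
        assert CEAComparison(1, 2, 2, 1, 5e6).dominance == "tare"
        assert CEAComparison(2, 1, 1, 2, 5e6).dominance == "deb"
        assert CEAComparison(2, 1, 2, 1, 5e6).dominance == "none"


class TestDistributionFitters:
    def test_beta_example(self):
        a, b = beta_from_mean_sd(0.788, 0.0788)
        assert (a, b) == (pytest.approx(20.41, abs=0.01),
                          pytest.approx(5.49, abs=0.01))

    def test_beta_symmetry(self):
        a, b = beta_from_mean_sd(0.5, 0.1)
        assert a == pytest.approx(b)

    def test_gamma_examples(self):
        shape, scale = gamma_from_mean_sd(845_320, 84_532)
        assert shape == pytest.approx(100.0)
        assert scale == pytest.approx(8_453.2)
        assert gamma_from_mean_sd(7.0, 0.7)[0] == pytest.approx(100.0)

    @given(st.floats(min_value=0.05, max_value=0.95),
           st.floats(min_value=0.01, max_value=0.2))
    @settings(max_examples=50)
    def test_beta_round_trips_moments(self, mean, cv):
        sd = cv * mean
        if sd * sd >= mean * (1 - mean):
            return
        a, b = beta_from_mean_sd(mean, sd)
        dist = stats.beta(a, b)
        assert dist.mean() == pytest.approx(mean, abs=1e-9)
        assert dist.std() == pytest.approx(sd, abs=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e7),
           st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50)
    def test_gamma_round_trips_moments(self, mean, cv):
        shape, scale = gamma_from_mean_sd(mean, cv * mean)
        dist = stats.gamma(shape, scale=scale)
        assert dist.mean() == pytest.approx(mean, rel=1e-9)
        assert dist.std() == pytest.approx(cv * mean, rel=1e-9)

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_sd(0.99, 0.5)
        with pytest.raises(ValueError):
            gamma_from_mean_sd(-1.0, 1.0)


@pytest.fixture(scope="module")
def dsa(params_itt):
    return one_way_dsa(params_itt)


class TestDSA:
    def test_one_row_per_parameter_sorted_by_impact(self, dsa):
        widths = dsa.table["bar_width"].to_numpy()
        assert (np.diff(widths) <= 1e-9).all()
        assert len(dsa.table) == len(set(dsa.table["parameter"]))

    def test_pfs_dominates_the_tornado(self, dsa):
        """Progression-free survival is the most influential input."""
        assert dsa.table.iloc[0]["parameter"] in ("median_pfs_tare",
                                                  "median_pfs_deb")

    def test_utility_impact_is_small(self, dsa):
        util = dsa.table.set_index("parameter").loc[
            ["u_local", "u_eligible", "u_refractory", "u_decomp"]]
        rel = util["bar_width"] / dsa.base_icer
        assert (rel < 0.10).all()

    def test_microsphere_price_monotone_in_icer(self, dsa, params_itt):
        row = dsa.table.set_index("parameter").loc["microsphere_price"]
        assert row["icer_low"] < dsa.base_icer < row["icer_high"]

    def test_base_case_bit_intact_after_dsa(self, params_itt):
        before = run_arms(params_itt)
        one_way_dsa(params_itt)
        after = run_arms(params_itt)
        for a, b in zip(before, after):
            assert a.total_cost == b.total_cost
            assert a.total_qaly == b.total_qaly

    def test_zero_width_range_gives_zero_bar(self, params_itt):
        res = one_way_dsa(params_itt, ranges={
            "u_local": (0.788, 0.788)})
        row = res.table.set_index("parameter").loc["u_local"]
        assert row["bar_width"] == 0.0

    def test_range_must_bracket_base(self, params_itt):
        with pytest.raises(ValueError, match="bracket"):
            one_way_dsa(params_itt, ranges={"u_local": (0.9, 1.0)})

    def test_microsphere_threshold_column_populated(self, dsa):
        row = dsa.table.set_index("parameter").loc["microsphere_price"]
        assert row["threshold"] == pytest.approx(1_399_120, rel=1e-3)


class TestThresholdSearch:
    def test_microsphere_price_crossing(self, params_itt):
        theta = threshold_search("microsphere_price", params_itt,
                                 wtp=5_000_000,
                                 interval=(1_152_000, 1_728_000))
        assert theta == pytest.approx(1.399e6, rel=0.05)
        # root definition: the ICER at the returned value equals the WTP
        tare, deb = run_arms(params_itt.replace(microsphere_price=theta))
        icer = compare(tare, deb, 5e6).icer
        assert icer == pytest.approx(5_000_000, rel=1e-6)

    def test_no_crossing_returns_none(self, params_itt):
        assert threshold_search("u_decomp", params_itt,
                                interval=(0.5, 0.55)) is None


@pytest.fixture(scope="module")
def psa(params_itt):
    return run_psa(params_itt, n_iterations=500, seed=20,
                   wtp_grid=[0.0, 5e6, 1e12])


class TestPSA:
    def test_seed_reproducibility(self, params_itt):
        a = run_psa(params_itt, n_iterations=50, seed=3, wtp_grid=[5e6])
        b = run_psa(params_itt, n_iterations=50, seed=3, wtp_grid=[5e6])
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_ceac_limits(self, psa):
        d = psa.draws
        at_zero = psa.ceac.iloc[0]["prob_tare_cost_effective"]
        at_inf = psa.ceac.iloc[-1]["prob_tare_cost_effective"]
        assert at_zero == pytest.approx(float((d["delta_cost"] < 0).mean()))
        assert at_inf == pytest.approx(float((d["delta_qaly"] > 0).mean()))

    def test_fractions_in_unit_interval(self, psa):
        prob = psa.ceac["prob_tare_cost_effective"]
        assert ((0 <= prob) & (prob <= 1)).all()
        assert 0 <= psa.fraction_below_wtp <= 1

    def test_degenerate_distributions_reproduce_base_case(self, params_itt,
                                                          monkeypatch):
        import embocea.cea as cea_mod
        monkeypatch.setattr(cea_mod, "PSA_RELATIVE_SD", 0.0)
        p = params_itt.replace(discount_annual=0.0)
        res = run_psa(p, n_iterations=5, seed=1, wtp_grid=[5e6])
        tare, deb = run_arms(p)
        assert np.allclose(res.draws["delta_cost"],
                           tare.total_cost - deb.total_cost)
        assert np.allclose(res.draws["delta_qaly"],
                           tare.total_qaly - deb.total_qaly)

    def test_invalid_arguments(self, params_itt):
        with pytest.raises(ValueError):
            run_psa(params_itt, n_iterations=0)
        with pytest.raises(ValueError):
            run_psa(params_itt, n_iterations=1, wtp_grid=[])
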