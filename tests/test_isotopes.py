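"""Unit and property tests for isotope and growth phenotype derivation."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isofeed.isotopes import (
    IsotopeStandards,
    R_STD_C13_VPDB,
    R_STD_N15_AIR,
    atom_percent_excess,
    atom_percent_to_delta,
    delta_to_atom_percent,
    derive_phenotypes,
    dry_matter_intake,
    estimate_baseline,
    filter_growth_outliers,
    growth_traits,
    indicator_ratios,
    tank_fcr,
    tank_means,
)


class TestDeltaConversion:
    @pytest.mark.parametrize("r_std", [R_STD_N15_AIR, R_STD_C13_VPDB])
    def test_delta_zero_matches_closed_form(self, r_std):
        # At delta = 0 the sample has the standard's composition, so
        # atom% = 100 R / (1 + R); evaluated in exact rational arithmetic.
        r = Fraction(r_std).limit_denominator(10**12)
        expected = float(100 * r / (1 + r))
        assert delta_to_atom_percent(0.0, r_std) == pytest.approx(expected, abs=1e-9)

    def test_known_standard_values(self):
        assert delta_to_atom_percent(0.0, R_STD_N15_AIR) == pytest.approx(
            0.3662537, abs=1e-6
        )
        assert delta_to_atom_percent(0.0, R_STD_C13_VPDB) == pytest.approx(
            1.1112329, abs=1e-6
        )

    @settings(deadline=None, max_examples=200)
    @given(
        d1=st.floats(-999.0, 5000.0),
        d2=st.floats(-999.0, 5000.0),
        r=st.sampled_from([R_STD_N15_AIR, R_STD_C13_VPDB]),
    )
    def test_strictly_monotone(self, d1, d2, r):
        a1, a2 = delta_to_atom_percent(d1, r), delta_to_atom_percent(d2, r)
        if d2 > d1 + 1e-6:  # gap above float resolution of the map
            assert a2 > a1
        elif d2 < d1 - 1e-6:
            assert a2 < a1

    @settings(deadline=None, max_examples=200)
    @given(
        delta=st.floats(-999.0, 10000.0),
        r=st.sampled_from([R_STD_N15_AIR, R_STD_C13_VPDB]),
    )
    def test_round_trip_recovers_delta(self, delta, r):
        atom = delta_to_atom_percent(delta, r)
        assert 0.0 < atom < 100.0
        assert atom_percent_to_delta(atom, r) == pytest.approx(delta, abs=1e-9)

    def test_nonphysical_delta_rejected(self):
        with pytest.raises(ValueError):
            delta_to_atom_percent(-1000.0, R_STD_N15_AIR)


class TestApeAndBaseline:
    @pytest.mark.parametrize(
        "atom, ia, expected",
        [(1.01, 0.370, 0.64), (0.370, 0.370, 0.0), (1.59, 1.087, 0.503)],
    )
    def test_ape_is_subtraction(self, atom, ia, expected):
        assert atom_percent_excess(atom, ia) == pytest.approx(expected, abs=1e-12)

    def test_baseline_mean_and_sd(self):
        assert estimate_baseline([0.37, 0.37, 0.37]) == pytest.approx((0.37, 0.0))
        mean, sd = estimate_baseline([0.36, 0.38])
        assert mean == pytest.approx(0.37)
        assert sd == pytest.approx(0.0141421356, abs=1e-9)

    @pytest.mark.parametrize("bad", [[], [0.37]])
    def test_baseline_needs_two_fish(self, bad):
        with pytest.raises(ValueError):
            estimate_baseline(bad)


class TestGrowthTraits:
    def test_reference_scale_example(self):
        wg, rg = growth_traits(21.8, 32.6)
        assert wg == pytest.approx(10.8)
        assert rg == pytest.approx(10.8 / 32.6 * 100.0)

    def test_no_growth(self):
        assert growth_traits(20.0, 20.0) == pytest.approx((0.0, 0.0))

    def test_shrinkage_allowed(self):
        wg, rg = growth_traits(20.0, 18.0)
        assert wg == pytest.approx(-2.0)
        assert rg < 0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            growth_traits(0.0, 10.0)


class TestGrowthFilter:
    def _frame(self, rgs, iw=20.0):
        fw = iw / (1 - np.asarray(rgs) / 100.0)
        return pd.DataFrame({"iw": iw, "fw": fw, "rg": rgs})

    @pytest.mark.parametrize(
        "rg, flagged, reason",
        [
            (5.0, True, "low_growth"),
            (6.39, True, "low_growth"),
            (6.4, False, ""),  # threshold is strict
            (30.0, False, ""),
            (49.0, False, ""),  # threshold is strict
            (49.01, True, "high_growth"),
            (50.0, True, "high_growth"),
        ],
    )
    def test_thresholds_strict(self, rg, flagged, reason):
        out, _ = filter_growth_outliers(self._frame([rg]))
        assert bool(out["growth_missing"].iloc[0]) is flagged
        assert out["missing_reason"].iloc[0] == reason

    def test_missing_weight_flagged_and_counted(self):
        df = pd.DataFrame({"iw": [20.0, np.nan], "fw": [26.0, 25.0], "rg": [23.0, np.nan]})
        out, counts = filter_growth_outliers(df)
        assert counts == {
            "weight_missing": 1, "low_growth": 0, "high_growth": 0, "total_missing": 1,
        }
        assert out["missing_reason"].tolist() == ["", "weight_missing"]

    def test_idempotent(self):
        df = self._frame([5.0, 30.0, 55.0])
        once, c1 = filter_growth_outliers(df)
        twice, c2 = filter_growth_outliers(once)
        pd.testing.assert_frame_equal(once, twice)
        assert c1 == c2


class TestTankFcr:
    def test_reference_scale_division(self):
        # tank intake 363 g DM over 526.1 g of summed gain
        assert tank_fcr(363.0, [526.1]) == pytest.approx(0.690, abs=5e-4)

    def test_zero_intake(self):
        assert tank_fcr(0.0, [10.0, 5.0]) == 0.0

    def test_order_invariant(self):
        wgs = [3.0, 7.0, 2.5]
        assert tank_fcr(10.0, wgs) == tank_fcr(10.0, wgs[::-1])

    def test_all_members_missing_rejected(self):
        with pytest.raises(ValueError):
            tank_fcr(10.0, [np.nan, np.nan])


class TestIndicatorRatios:
    def test_reference_scale_example(self):
        ifcr, ifer = indicator_ratios(21.8, 32.6, 0.64)
        assert ifcr == pytest.approx(1.9319, abs=1e-4)
        assert ifer == pytest.approx(0.5176, abs=1e-4)

    @settings(deadline=None, max_examples=200)
    @given(
        iw=st.floats(5.0, 50.0),
        wg=st.floats(0.5, 30.0),
        ape=st.floats(0.01, 2.0),
    )
    def test_reciprocal_identity(self, iw, wg, ape):
        ifcr, ifer = indicator_ratios(iw, iw + wg, ape)
        assert ifcr * ifer == pytest.approx(1.0, rel=1e-12)

    def test_zero_ape(self):
        ifcr, ifer = indicator_ratios(20.0, 30.0, 0.0)
        assert ifcr == 0.0
        assert np.isnan(ifer)

    def test_no_gain_undefined(self):
        ifcr, ifer = indicator_ratios(20.0, 20.0, 0.5)
        assert np.isnan(ifcr) and np.isnan(ifer)


class TestDryMatterIntake:
    def test_reference_dm_fraction(self):
        assert dry_matter_intake(100.0, 10.0, 0.0, 0.9125) == pytest.approx(82.125)

    def test_identity_with_no_waste(self):
        assert dry_matter_intake(50.0, 0.0, 0.0, 1.0) == 50.0

    def test_corrected_waste_above_fed_rejected(self):
        with pytest.raises(ValueError):
            dry_matter_intake(100.0, 60.0, leaching_correction=0.5)


class TestTankMeans:
    def test_single_and_pair(self):
        df = pd.DataFrame({"tank": ["a", "b", "b"], "x": [3.0, 1.0, 2.0]})
        out = tank_means(df, "x")
        assert out.loc["a", "x"] == 3.0
        assert out.loc["b", "x"] == 1.5
        assert out["n"].tolist() == [1, 2]

    def test_empty_tank_rejected(self):
        df = pd.DataFrame({"tank": [], "x": []})
        with pytest.raises((ValueError, KeyError)):
            tank_means(df, "y")


class TestDerivePhenotypes:
    def test_delta_input_equals_atom_input(self, small_config):
        from isofeed.simulate import simulate_genotypes, simulate_phenotypes
        import dataclasses

        cfg = dataclasses.replace(small_config, emit_delta=True)
        geno = simulate_genotypes(cfg)
        ind, tanks, _ = simulate_phenotypes(geno, cfg)
        atom_cols = [c for c in ind.columns if c.startswith("atom_")]
        via_atom, tk_atom, _ = derive_phenotypes(ind.drop(columns=[c.replace("atom", "delta") for c in atom_cols]), tanks)
        via_delta, tk_delta, _ = derive_phenotypes(
            ind.drop(columns=atom_cols), tanks, units="delta"
        )
        for c in ("ape_amn", "ifcr_amn", "ifer_amc"):
            np.testing.assert_allclose(via_atom[c], via_delta[c], rtol=1e-9)
        np.testing.assert_allclose(tk_atom["fcr"], tk_delta["fcr"], rtol=1e-12)

    def test_flagged_fish_excluded_from_tank_sums(self, derived_small):
        ind, tanks, _counts = derived_small
        kept = ind[~ind["growth_missing"]]
        for _, row in tanks.iterrows():
            expected = kept.loc[kept["tank"] == row["tank"], "wg"].sum()
            assert row["sum_wg"] == pytest.approx(expected)
            assert row["fcr"] == pytest.approx(row["fi"] / expected)

    def test_negative_ape_flagging(self):
        ind = pd.DataFrame(
            {
                "fish_id": ["a", "b"], "family": ["f", "f"], "tank": ["t", "t"],
                "day": [1, 1], "iw": [20.0, 20.0], "fw": [26.0, 26.0],
                # one barely below baseline (noise), one far below (invalid)
                "atom_amn": [0.37 - 0.0002, 0.30],
            }
        )
        tanks = pd.DataFrame({"tank": ["t"], "day": [1], "fi": [10.0]})
        out, _tk, counts = derive_phenotypes(
            ind, tanks, indicator_keys=[("muscle", "n15")]
        )
        assert out["ape_amn_flag"].tolist() == ["negative_noise", "invalid"]
        assert counts["ape_amn_invalid"] == 1
        assert np.isnan(out["ifcr_amn"].iloc[1])
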