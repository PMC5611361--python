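import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

from twigscale.xylem_mechanics import (
    BendingTest,
    GravimetricRecord,
    PhysicalConstants,
    VesselSet,
    bending_moe,
    derive_bending_table,
    derive_gravimetric_table,
    derive_stem_hydraulics,
    derive_vessel_table,
    ellipse_equivalent_diameter,
    hydraulic_weighted_diameter,
    stem_composition,
    theoretical_conductivity,
    vessel_stats,
)

axis = st.floats(min_value=0.5, max_value=500.0, allow_nan=False)


class TestEllipseDiameter:
    def test_circle_limit_exact(self):
        assert ellipse_equivalent_diameter(7.5, 7.5) == pytest.approx(
            15.0, abs=1e-12
        )

    def test_worked_value_vs_poiseuille_oracle(self):
        # oracle: solve pi d^4/128 = pi a^3 b^3 / (4 (a^2+b^2)) numerically
        a, b = 10.0, 5.0
        target = np.pi * a**3 * b**3 / (4.0 * (a * a + b * b))
        d = optimize.brentq(lambda dd: np.pi * dd**4 / 128.0 - target, 1, 50)
        assert ellipse_equivalent_diameter(a, b) == pytest.approx(d, rel=1e-10)
        assert ellipse_equivalent_diameter(a, b) == pytest.approx(13.37, abs=0.01)

    @given(a=axis, b=axis, k=st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneous_degree_one(self, a, b, k):
        a, b = max(a, b), min(a, b)
        d1 = ellipse_equivalent_diameter(a, b)
        dk = ellipse_equivalent_diameter(k * a, k * b)
        assert dk == pytest.approx(k * d1, rel=1e-9)

    @given(a=axis, b=axis)
    def test_monotone_in_each_axis(self, a, b):
        a, b = max(a, b), min(a, b)
        d = ellipse_equivalent_diameter(a, b)
        assert ellipse_equivalent_diameter(a * 1.1, b) > d
        assert ellipse_equivalent_diameter(a * 1.1, b * 1.1) > d

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            ellipse_equivalent_diameter(0.0, 1.0)
        with pytest.raises(ValueError):
            ellipse_equivalent_diameter(5.0, -1.0)


class TestHydraulicWeightedDiameter:
    def test_constant_sequence(self):
        assert hydraulic_weighted_diameter([12, 12, 12]) == pytest.approx(
            12.0, abs=1e-12
        )

    def test_two_vessel_longhand(self):
        # ((10^4 + 20^4)/2)^(1/4) = 85000^(1/4)
        assert hydraulic_weighted_diameter([10, 20]) == pytest.approx(
            85000.0**0.25, rel=1e-12
        )
        assert hydraulic_weighted_diameter([10, 20]) == pytest.approx(17.08, abs=0.01)

    def test_single_vessel(self):
        assert hydraulic_weighted_diameter([33.3]) == pytest.approx(33.3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hydraulic_weighted_diameter([])

    @given(st.lists(st.floats(min_value=1, max_value=200), min_size=1, max_size=30))
    def test_power_mean_inequality_and_bounds(self, ds):
        dh = hydraulic_weighted_diameter(ds)
        assert min(ds) - 1e-9 <= dh <= max(ds) + 1e-9
        assert dh >= np.mean(ds) - 1e-9


class TestVesselStats:
    def test_density_definition(self):
        vs = VesselSet("s", np.full(50, 8.0), np.full(50, 8.0), 0.5)
        vd, _ = vessel_stats(vs)
        assert vd == pytest.approx(100.0)

    def test_fraction_circular_oracle(self):
        # 100 circular vessels of radius 10 um at VD = 100 mm^-2:
        # lumen area pi*100 um^2 = 3.1416e-4 mm^2, VF = 3.1416e-2
        vs = VesselSet("s", np.full(100, 10.0), np.full(100, 10.0), 1.0)
        vd, vf = vessel_stats(vs)
        assert vd == pytest.approx(100.0)
        assert vf == pytest.approx(np.pi * 1e-2, rel=1e-12)

    def test_overfull_fraction_warns(self):
        vs = VesselSet("s", np.full(10, 200.0), np.full(10, 200.0), 0.5)
        with pytest.warns(UserWarning, match="fraction"):
            vessel_stats(vs)

    def test_bounds_on_generator_output(self, small_dataset):
        hyd = derive_vessel_table(small_dataset.vessel_table)
        assert ((hyd["VF"] > 0) & (hyd["VF"] < 1)).all()
        assert (hyd["VD"] > 0).all()

    def test_invariants_on_random_stems(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            b = rng.uniform(2, 30, n)
            a = b * rng.uniform(1.0, 1.5, n)
            vs = VesselSet("s", a, b, float(rng.uniform(0.5, 5.0)))
            vd, vf = vessel_stats(vs)
            assert vd > 0 and 0 < vf < 1
            d = ellipse_equivalent_diameter(a, b)
            dh = hydraulic_weighted_diameter(d)
            assert d.min() - 1e-9 <= dh <= d.max() + 1e-9


class TestTheoreticalConductivity:
    def test_empty_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert theoretical_conductivity([], 1.0) == 0.0

    def test_worked_si_value(self):
        # independent longhand: 100 vessels, D = 20 um, A_s = 1 mm^2
        # K = pi*998.2/(128*1.002e-9*1e-6) * 100*(2e-5)^4 = 0.3912...
        k = theoretical_conductivity(np.full(100, 20.0), 1.0)
        longhand = (
            np.pi * 998.2 / (128.0 * 1.002e-9 * 1e-6) * 100 * (20e-6) ** 4
        )
        assert k == pytest.approx(longhand, rel=1e-12)
        assert k == pytest.approx(0.391, abs=5e-4)

    def test_fourth_power_scaling(self, rng):
        d = rng.uniform(5, 50, 20)
        assert theoretical_conductivity(2 * d, 1.0) == pytest.approx(
            16.0 * theoretical_conductivity(d, 1.0), rel=1e-12
        )

    def test_area_reciprocity(self, rng):
        d = rng.uniform(5, 50, 20)
        assert theoretical_conductivity(d, 2.0) == pytest.approx(
            theoretical_conductivity(d, 1.0) / 2.0, rel=1e-12
        )

    def test_permutation_invariance(self, rng):
        d = rng.uniform(5, 60, 200)
        k1 = theoretical_conductivity(d, 0.7)
        k2 = theoretical_conductivity(rng.permutation(d), 0.7)
        assert k2 == pytest.approx(k1, rel=1e-12)

    def test_custom_constants(self):
        c = PhysicalConstants(rho_water=500.0, mu_water=1.002e-9)
        half = theoretical_conductivity([20.0], 1.0, c)
        full = theoretical_conductivity([20.0], 1.0)
        assert half == pytest.approx(full * 500.0 / 998.2, rel=1e-12)


class TestStemComposition:
    def test_fully_saturated_at_sampling(self):
        rec = GravimetricRecord("s", 2.5, 2.5, 1.0, 2.0)
        _, swc = stem_composition(rec)
        assert swc == pytest.approx(100.0)

    def test_density_definition(self):
        rec = GravimetricRecord("s", 1.0, 1.1, 0.6, 1.2)
        wd, _ = stem_composition(rec)
        assert wd == pytest.approx(0.5)

    def test_swc_longhand(self):
        rec = GravimetricRecord("s", 2.0, 2.5, 1.0, 1.5)
        _, swc = stem_composition(rec)
        assert swc == pytest.approx(100.0 / 1.5)  # (2-1)/(2.5-1)*100

    def test_sw_equals_dw_diagnostic(self):
        rec = GravimetricRecord("s", 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ZeroDivisionError, match="saturable"):
            stem_composition(rec)

    def test_mass_ordering_enforced(self):
        with pytest.raises(ValueError, match="SW >= FW >= DW"):
            GravimetricRecord("s", 3.0, 2.5, 1.0, 1.0)

    def test_swc_bounded_on_generator_output(self, small_dataset):
        comp = derive_gravimetric_table(small_dataset.gravimetric_table)
        assert ((comp["SWC"] >= 0) & (comp["SWC"] <= 100)).all()
        assert (comp["WD"] > 0).all()


class TestBendingMoe:
    def _test(self, slope=0.5, span=100.0, diam=4.0, offset=0.0):
        loads = np.array([1.0, 2.0, 3.0, 4.0])
        return BendingTest("s", span, diam, loads, slope * loads + offset)

    def test_worked_example(self):
        ei, moe = bending_moe(self._test())
        assert ei == pytest.approx(100.0**3 / 48.0 / 0.5, rel=1e-9)  # 41666.7
        assert moe == pytest.approx(ei / (np.pi * 4.0**4 / 64.0), rel=1e-9)
        assert moe == pytest.approx(3316.0, abs=1.0)

    def test_doubling_slope_halves_ei(self):
        ei1, _ = bending_moe(self._test(slope=0.5))
        ei2, _ = bending_moe(self._test(slope=1.0))
        assert ei2 == pytest.approx(ei1 / 2.0, rel=1e-9)

    def test_offset_invariance(self):
        ei1, _ = bending_moe(self._test(offset=0.0))
        ei2, _ = bending_moe(self._test(offset=0.3))
        assert ei2 == pytest.approx(ei1, rel=1e-9)

    def test_nonincreasing_loads_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            BendingTest("s", 100, 4, [1.0, 1.0, 2.0], [0.5, 0.6, 1.0])

    def test_short_span_rejected_and_warned(self):
        with pytest.raises(ValueError, match="20"):
            self._test(span=70.0)
        with pytest.warns(UserWarning, match="25"):
            self._test(span=90.0)

    def test_nonlinear_rejected(self):
        loads = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        defl = np.array([0.1, 1.5, 0.2, 3.0, 0.3])
        with pytest.raises(ValueError, match="linear"):
            bending_moe(BendingTest("s", 100, 4, loads, defl))

    def test_weak_linearity_warns(self):
        loads = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        defl = 0.5 * loads + 0.25 * np.array([1.0, -1.2, 1.0, -1.0, 0.5])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            bending_moe(BendingTest("s", 100, 4, loads, defl))
        assert any("linearity" in str(w.message) for w in rec)


class TestTableDrivers:
    def test_vessel_table_roundtrip(self, noisefree_dataset):
        hyd = derive_vessel_table(noisefree_dataset.vessel_table)
        truth = noisefree_dataset.species_means
        merged = hyd.groupby("species")[["Dh", "VD", "VF", "Ktheo"]].mean()
        for col in ("Dh", "VD", "VF", "Ktheo"):
            assert np.allclose(merged[col], truth[col], rtol=1e-9)

    def test_bending_table_roundtrip(self, noisefree_dataset):
        moe = derive_bending_table(noisefree_dataset.bending_table)
        merged = moe.groupby("species")["MOE"].mean()
        assert np.allclose(merged, noisefree_dataset.species_means["MOE"], rtol=1e-9)

    def test_full_axis_ingest_flag(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "stem_id": ["s"] * 4,
                "a_um": [20.0, 24.0, 18.0, 30.0],
                "b_um": [16.0, 20.0, 14.0, 22.0],
                "analyzed_area_mm2": [0.4] * 4,
            }
        )
        semi = df.assign(a_um=df.a_um / 2, b_um=df.b_um / 2)
        out_full = derive_vessel_table(df, full_axes=True)
        out_semi = derive_vessel_table(semi)
        assert out_full["Dh"].iloc[0] == pytest.approx(out_semi["Dh"].iloc[0])
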