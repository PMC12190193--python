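import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lensepr.spectra import (
    HyperfineTensor,
    Spectrum,
    az_to_epsilon,
    default_tensor,
    extract_fluid_params,
    extract_two_az,
    hydrophobicity_compare,
    order_parameter,
    simulate_axial_spectrum,
)


class TestSimulate:
    def test_isotropic_limit_three_lines(self):
        a = 15.0
        sp = simulate_axial_spectrum(a, a, linewidth=1.0)
        # zero crossings of the three symmetric lines sit at center and +/- a
        f, y = sp.field, sp.amplitude
        center = 3350.0
        for pos in (center - a, center, center + a):
            i = np.argmin(np.abs(f - pos))
            window = y[max(i - 3, 0): i + 4]
            assert window.max() * window.min() < 0  # sign change at the line

    def test_outer_extrema_near_2Apar(self):
        sp = simulate_axial_spectrum(32.0, 9.0, linewidth=1.0)
        p = extract_fluid_params(sp)
        assert p.A_par_obs == pytest.approx(32.0, abs=0.5)

    def test_first_derivative_integrates_to_zero(self):
        sp = simulate_axial_spectrum(30.0, 8.0, linewidth=1.0)
        integral = np.trapezoid(sp.amplitude, sp.field)
        assert abs(integral) < 1e-3 * np.abs(sp.amplitude).max()

    def test_narrow_window_rejected(self):
        grid = np.linspace(3340, 3360, 256)
        with pytest.raises(ValueError, match="clips"):
            simulate_axial_spectrum(32.0, 9.0, linewidth=1.0, field=grid)

    def test_invalid_splittings(self):
        with pytest.raises(ValueError):
            simulate_axial_spectrum(9.0, 32.0)


class TestExtractFluid:
    def test_roundtrip_50_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a_par = rng.uniform(17, 34)
            a_perp = rng.uniform(6, 13)
            lw = rng.uniform(0.6, 1.4)
            sp = simulate_axial_spectrum(a_par, a_perp, linewidth=lw)
            p = extract_fluid_params(sp)
            assert p.A_par_obs == pytest.approx(a_par, abs=0.5)
            assert p.A_perp_obs is not None
            assert p.A_perp_obs == pytest.approx(a_perp, abs=0.5)

    def test_isotropic_spectrum_inner_unresolved(self):
        sp = simulate_axial_spectrum(15.0, 15.0, linewidth=1.0)
        p = extract_fluid_params(sp)
        # no separate inner features exist in the isotropic limit
        assert p.A_perp_obs is None and "inner unresolved" in p.flags

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(1)
        f = np.linspace(3300, 3400, 1024)
        sp = Spectrum(field=f, amplitude=rng.normal(size=f.size))
        with pytest.raises(ValueError):
            extract_fluid_params(sp)


class TestOrderParameter:
    def test_rigid_limit_is_one(self):
        t = default_tensor()
        s = order_parameter(t.A_zz, (t.A_xx + t.A_yy) / 2, t)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_limit_is_zero(self):
        assert order_parameter(15.0, 15.0) == 0.0

    def test_closed_form_oracle(self):
        t = HyperfineTensor(6.3, 5.8, 33.6)
        a_par, a_perp = 25.0, 8.0
        a_obs = (a_par + 2 * a_perp) / 3
        expected = ((a_par - a_perp) / (t.A_zz - (t.A_xx + t.A_yy) / 2)
                    * t.a_iso / a_obs)
        assert order_parameter(a_par, a_perp, t) == pytest.approx(expected)

    @given(st.floats(1.01, 3.0))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, k):
        t = default_tensor()
        t_scaled = HyperfineTensor(k * t.A_xx, k * t.A_yy, k * t.A_zz)
        s1 = order_parameter(25.0, 8.0, t)
        s2 = order_parameter(k * 25.0, k * 8.0, t_scaled)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_monotone_in_splitting_difference(self):
        t = default_tensor()
        # fix a_obs = (A_par + 2 A_perp)/3 while increasing the difference
        a_obs = 14.0
        prev = -1
        for diff in (3.0, 9.0, 15.0):
            a_perp = a_obs - diff / 3
            a_par = a_perp + diff
            s = order_parameter(a_par, a_perp, t)
            assert s > prev
            prev = s


class TestFrozen:
    def test_two_az_recovery(self):
        sp = simulate_axial_spectrum(34.0, 7.0, linewidth=1.5,
                                     temperature_label="frozen_minus165C")
        assert extract_two_az(sp) == pytest.approx(68.0, abs=0.75)

    def test_rigid_limit_matches_tensor(self):
        t = default_tensor()
        sp = simulate_axial_spectrum(t.A_zz, (t.A_xx + t.A_yy) / 2,
                                     linewidth=1.5,
                                     temperature_label="frozen_minus165C")
        assert extract_two_az(sp) == pytest.approx(2 * t.A_zz, abs=0.75)

    def test_monotone_in_azz(self):
        vals = [extract_two_az(simulate_axial_spectrum(
            azz, 6.0, linewidth=1.5, temperature_label="frozen_minus165C"))
            for azz in (30.0, 33.0, 36.0)]
        assert vals == sorted(vals)

    def test_noise_stability(self):
        vals = [extract_two_az(simulate_axial_spectrum(
            33.6, 6.0, linewidth=1.5, temperature_label="frozen_minus165C",
            noise_sd=0.01, seed=s)) for s in (1, 2)]
        assert abs(vals[0] - vals[1]) < 0.5


class TestHydrophobicity:
    def test_smaller_two_az_more_hydrophobic(self):
        assert hydrophobicity_compare(58, 64) == "first"
        assert hydrophobicity_compare(64, 58) == "second"
        assert hydrophobicity_compare(60, 60) == "indistinguishable"

    def test_transitivity(self):
        a, b, c = 58, 61, 64
        assert hydrophobicity_compare(a, b) == "first"
        assert hydrophobicity_compare(b, c) == "first"
        assert hydrophobicity_compare(a, c) == "first"


class TestAzToEpsilon:
    TABLE = [(60.0, 2.0), (70.0, 80.0)]

    def test_node_identity(self):
        assert az_to_epsilon(60.0, self.TABLE) == pytest.approx(2.0)

    def test_log_linear_midpoint(self):
        assert az_to_epsilon(65.0, self.TABLE) == pytest.approx(
            np.sqrt(2.0 * 80.0), rel=1e-9)

    def test_monotone_increasing(self):
        vals = [az_to_epsilon(x, self.TABLE) for x in (60, 63, 66, 70)]
        assert vals == sorted(vals)

    def test_out_of_range_clamps(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert az_to_epsilon(55.0, self.TABLE) == pytest.approx(2.0)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError):
            az_to_epsilon(65.0, [(60.0, 10.0), (70.0, 2.0)])
        with pytest.raises(ValueError):
            az_to_epsilon(65.0, [(60.0, 2.0)])
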