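import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lensepr.oximetry import (
    OTPMeasurement,
    averaged_otp,
    compute_otp,
    detect_cbd_onset,
    discriminate_domains,
    otp_from_decays,
)
from lensepr.sr import fit_double, fit_single
from lensepr.synth import make_decay_pair, make_titration, _center_decay_pair


class TestComputeOTP:
    def test_hand_arithmetic(self):
        m = compute_otp(T1_air=1.25, T1_n2=5.0)
        assert m.W == pytest.approx(0.6)

    def test_equal_t1_gives_zero(self):
        assert compute_otp(2.0, 2.0).W == 0.0

    def test_small_negative_clamped_large_negative_raises(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = compute_otp(5.05, 5.0, se_air=0.1, se_n2=0.1)
        assert m.W == 0.0
        with pytest.raises(ValueError, match="slower than nitrogen"):
            compute_otp(10.0, 5.0, se_air=0.001, se_n2=0.001)

    def test_se_propagation_against_monte_carlo(self):
        t1a, t1n, sa, sn = 1.25, 5.0, 0.01, 0.05
        m = compute_otp(t1a, t1n, sa, sn)
        rng = np.random.default_rng(0)
        draws = (1 / rng.normal(t1a, sa, 10_000)
                 - 1 / rng.normal(t1n, sn, 10_000))
        assert m.se_W == pytest.approx(draws.std(ddof=1), rel=0.05)

    def test_amplitude_invariance(self):
        # W depends only on time constants, not decay amplitudes
        grid = np.linspace(0, 25, 2048)
        from lensepr.sr import simulate_sr_decay
        for amp in (0.5, 1.0, 7.0):
            air = simulate_sr_decay([(amp, 1.25)], t_grid=grid)
            n2 = simulate_sr_decay([(amp, 5.0)], t_grid=grid)
            assert otp_from_decays(air, n2).W == pytest.approx(0.6, rel=1e-6)


class TestDiscriminateDomains:
    def _fits(self, w_bulk, w_cbd, seed, noise=0.01):
        air, n2 = _center_decay_pair(
            w_bulk, w_cbd, 0.2, noise, np.random.SeedSequence(seed))
        return fit_double(air, fix_baseline=0.0), fit_single(n2, fix_baseline=0.0)

    def test_assignment_rule(self):
        fa, fn = self._fits(0.7, 0.3, seed=0, noise=0.0)
        bulk, cbd = discriminate_domains(fa, fn)
        assert bulk.environment == "bulk" and cbd.environment == "CBD"
        assert bulk.W == pytest.approx(0.7, abs=1e-3)
        assert cbd.W == pytest.approx(0.3, abs=1e-3)
        assert cbd.W < bulk.W

    def test_recovery_over_seeds(self):
        errs_b, errs_c = [], []
        for s in range(20):
            fa, fn = self._fits(0.6, 0.25, seed=s)
            bulk, cbd = discriminate_domains(fa, fn)
            errs_b.append((bulk.W - 0.6) / 0.6)
            errs_c.append((cbd.W - 0.25) / 0.25)
        assert np.sqrt(np.mean(np.square(errs_b))) < 0.15
        assert np.sqrt(np.mean(np.square(errs_c))) < 0.15

    def test_ambiguous_components_unassigned(self):
        # near-equal W values: confidence intervals overlap
        fa, fn = self._fits(0.50, 0.45, seed=1)
        bulk, cbd = discriminate_domains(fa, fn)
        assert bulk.environment == "unassigned"
        assert cbd.environment == "unassigned"

    def test_requires_two_component_air_fit(self):
        air, n2 = make_decay_pair(1.25, 5.0, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="two components"):
            discriminate_domains(fit_single(air), fit_single(n2))


class TestAveragedOTP:
    def test_equal_weights(self):
        m = averaged_otp([0.5, 0.5], [0.7, 0.3])
        assert m.W == pytest.approx(0.5)
        assert m.environment == "averaged"

    def test_concentrated_weight_is_identity(self):
        assert averaged_otp([1.0], [0.42]).W == pytest.approx(0.42)

    def test_bad_weights_raise(self):
        with pytest.raises(ValueError, match="sum"):
            averaged_otp([0.5, 0.6], [0.7, 0.3])
        with pytest.raises(ValueError):
            averaged_otp([-0.5, 1.5], [0.7, 0.3])

    @given(
        st.lists(st.floats(0.01, 1), min_size=2, max_size=5),
        st.lists(st.floats(0.01, 1), min_size=5, max_size=5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_components(self, raw_w, ws):
        w = np.array(raw_w) / np.sum(raw_w)
        vals = ws[: len(w)]
        m = averaged_otp(w, vals)
        assert min(vals) - 1e-12 <= m.W <= max(vals) + 1e-12


class TestCBDOnset:
    RATIOS = [0, 0.5, 0.9, 1.5, 2.1, 3.3]

    def test_onset_is_first_sampled_ratio_past_truth(self):
        ser = make_titration("mouse", 1.0, self.RATIOS, seed=5)
        res = detect_cbd_onset(ser)
        assert res.onset_ratio == 1.5
        assert res.n_components == (1, 1, 1, 2, 2, 2)

    def test_never_oversaturated_gives_none(self):
        ser = make_titration("pig", 4.0, [0, 0.5, 1.0, 2.0, 3.3, 4.0], seed=6)
        res = detect_cbd_onset(ser)
        # onset at the very last sampled point is still reported
        assert res.onset_ratio == 4.0
        ser2 = make_titration("pig", 4.0, [0, 0.5, 1.0, 2.0, 3.0, 3.3], seed=6)
        assert detect_cbd_onset(ser2).onset_ratio is None

    def test_onset_at_first_point(self):
        ser = make_titration("human", 0.0, [0, 0.5, 1.0, 2.0], seed=7)
        assert detect_cbd_onset(ser).onset_ratio == 0.0

    def test_bulk_w_flat_above_onset(self):
        # saturation pins bulk membrane properties: the bulk W above onset
        # should show no trend beyond its own standard error
        from scipy import stats
        ser = make_titration("mouse", 0.5, [0, 0.4, 0.8, 1.5, 2.1, 2.7, 3.3],
                             seed=8)
        res = detect_cbd_onset(ser)
        pts = [(r, ms[0].W) for r, ms in res.measurements.items()
               if r >= 0.8 and len(ms) == 2]
        rr, ww = zip(*pts)
        fit = stats.linregress(rr, ww)
        assert abs(fit.slope) < 2 * fit.stderr

    def test_cbd_w_below_bulk_in_every_oversaturated_point(self):
        ser = make_titration("human", 1.0, self.RATIOS, seed=9)
        res = detect_cbd_onset(ser)
        for r, ms in res.measurements.items():
            if len(ms) == 2:
                bulk, cbd = ms
                assert cbd.W < bulk.W

    def test_too_few_points_rejected(self):
        ser = make_titration("mouse", 1.0, [0, 0.5, 1.5], seed=1)
        with pytest.raises(ValueError, match="4 titration points"):
            detect_cbd_onset(ser)

    def test_csl_series_rejected(self):
        ser = make_titration("mouse", 1.0, self.RATIOS, seed=2,
                             spin_label="CSL")
        with pytest.raises(ValueError, match="ASL"):
            detect_cbd_onset(ser)
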