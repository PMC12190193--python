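import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lensepr.composition import (
    PL_CLASSES,
    Phase,
    classify_phase,
    default_phase_boundaries,
    load_species_presets,
    molpercent_to_ratio,
    normalize_composition,
    predict_cst,
    predict_saturation_limit,
    ratio_to_molpercent,
)


def brute_force_weighted_sum(raw, per_pl):
    """Independent oracle: normalize and dot, no package code."""
    total = sum(raw.values())
    return sum(raw.get(pl, 0.0) / total * per_pl[pl] for pl in per_pl)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ({"PC": 46, "PE": 17, "PS": 17, "SM": 15},
             {"PC": 0.4842, "PE": 0.1789, "PS": 0.1789, "SM": 0.1579}),
            ({"PC": 11, "PE": 15, "PS": 15, "SM": 66},
             {"PC": 0.1028, "PE": 0.1402, "PS": 0.1402, "SM": 0.6168}),
            ({"PC": 100}, {"PC": 1.0, "PE": 0.0, "PS": 0.0, "SM": 0.0}),
        ],
    )
    def test_known_compositions(self, raw, expected):
        comp = normalize_composition(raw)
        for pl in PL_CLASSES:
            assert comp.fractions[pl] == pytest.approx(expected[pl], abs=1e-4)
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_and_negative_raise(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_composition({"PC": 0, "PE": 0})
        with pytest.raises(ValueError, match="negative"):
            normalize_composition({"PC": -1, "PE": 2})
        with pytest.raises(ValueError, match="unknown"):
            normalize_composition({"PC": 50, "PG": 50})

    @given(
        raw=st.fixed_dictionaries(
            {pl: st.floats(0.01, 100) for pl in PL_CLASSES}
        ),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, raw, k):
        a = normalize_composition(raw)
        b = normalize_composition({pl: k * v for pl, v in raw.items()})
        for pl in PL_CLASSES:
            assert a.fractions[pl] == pytest.approx(b.fractions[pl], rel=1e-9)


class TestPhaseBoundaries:
    def test_pure_pl_values(self):
        params = default_phase_boundaries()
        for pl, sat, cst in [
            ("PE", 33.0, 50.0), ("PC", 50.0, 66.0),
            ("PS", 50.0, 66.0), ("SM", 50.0, 66.0),
        ]:
            pure = normalize_composition({pl: 100})
            assert predict_saturation_limit(pure, params) == pytest.approx(sat)
            assert predict_cst(pure, params) == pytest.approx(cst)

    def test_species_predictions_match_oracle(self):
        params = default_phase_boundaries()
        for comp in load_species_presets().values():
            sat = predict_saturation_limit(comp, params)
            cst = predict_cst(comp, params)
            assert sat == pytest.approx(
                brute_force_weighted_sum(comp.raw_molpercent,
                                         params.sat_limit_per_pl), abs=1e-12)
            assert cst == pytest.approx(
                brute_force_weighted_sum(comp.raw_molpercent,
                                         params.cst_per_pl), abs=1e-12)

    def test_hand_computed_examples(self):
        presets = load_species_presets()
        assert predict_saturation_limit(presets["mouse"]) == pytest.approx(
            46.96, abs=0.01)
        assert predict_cst(presets["human"]) == pytest.approx(63.76, abs=0.01)

    def test_random_compositions_match_oracle_and_bounds(self):
        params = default_phase_boundaries()
        rng = np.random.default_rng(7)
        for _ in range(100):
            raw = {pl: float(rng.uniform(0.01, 100)) for pl in PL_CLASSES}
            comp = normalize_composition(raw)
            sat = predict_saturation_limit(comp, params)
            cst = predict_cst(comp, params)
            assert sat == pytest.approx(
                brute_force_weighted_sum(raw, params.sat_limit_per_pl),
                abs=1e-12)
            assert 33 <= sat <= 50 and 50 <= cst <= 66 and sat < cst

    def test_monotone_decreasing_in_pe(self):
        # only PE has lower per-PL boundaries: trading any PL for PE lowers both
        for other in ("PC", "PS", "SM"):
            prev_sat, prev_cst = np.inf, np.inf
            for pe in (10, 30, 50, 70):
                comp = normalize_composition({other: 100 - pe, "PE": pe})
                sat, cst = predict_saturation_limit(comp), predict_cst(comp)
                assert sat < prev_sat and cst < prev_cst
                prev_sat, prev_cst = sat, cst


class TestRatioConversion:
    @pytest.mark.parametrize("r,m", [(1.0, 50.0), (0.0, 0.0), (3.2, 76.19)])
    def test_known_values(self, r, m):
        assert ratio_to_molpercent(r) == pytest.approx(m, abs=0.01)

    @given(st.floats(0, 99.9))
    @settings(max_examples=100, derandomize=True)
    def test_mutual_inverse(self, m):
        assert ratio_to_molpercent(molpercent_to_ratio(m)) == pytest.approx(
            m, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_molpercent(-0.1)
        with pytest.raises(ValueError):
            molpercent_to_ratio(100.0)


class TestClassifyPhase:
    def test_mouse_states(self):
        mouse = load_species_presets()["mouse"]
        assert classify_phase(mouse, 40).phase is Phase.UNIFORM_PL_CHOL
        assert classify_phase(mouse, 50).phase is Phase.WITH_CBD
        assert classify_phase(mouse, 70).phase is Phase.WITH_CBD_AND_CRYSTALS

    def test_boundaries_keep_lower_phase(self):
        pure_pc = normalize_composition({"PC": 100})
        assert classify_phase(pure_pc, 50.0).phase is Phase.UNIFORM_PL_CHOL
        assert classify_phase(pure_pc, 66.0).phase is Phase.WITH_CBD

    def test_lifespan_metadata(self):
        presets = load_species_presets()
        assert presets["mouse"].lifespan_years == 3
        assert presets["pig"].lifespan_years == 23
        assert presets["human"].lifespan_years == 70
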