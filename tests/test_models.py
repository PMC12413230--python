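"""Unit and property tests for the lineshape / multiplet model layer."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multipletfit as mf
from multipletfit.models import (
    MultipletPattern,
    ParameterSpec,
    PeakShapeParams,
    SignalModel,
    peak_fwhm,
    signal_area,
)

F = Fraction

BUILTIN_TRUTH = {
    "singlet": {"x_s": 2.0, "I": 5.0, "lw": 0.01, "a": 0.5},
    "doublet": {"x_s": 2.0, "I": 5.0, "J": 0.3, "lw": 0.01, "a": 0.5},
    "triplet": {"x_s": 2.0, "I": 5.0, "J": 0.3, "lw": 0.01, "a": 0.5},
    "quadruplet": {"x_s": 2.0, "I": 5.0, "J": 0.3, "lw": 0.01, "a": 0.5},
    "doublet_of_doublets": {
        "x_s": 2.0, "I": 5.0, "J1": 0.6, "J2": 0.3, "lw": 0.01, "a": 0.5,
    },
}


# ---------------------------------------------------------------------------
# pseudo_voigt
# ---------------------------------------------------------------------------

class TestPseudoVoigt:
    def test_apex_equals_height_for_any_mixing(self):
        for a in (0.0, 0.25, 0.5, 1.0):
            p = PeakShapeParams(x0=1.3, h=10.0, lw=0.02, a=a)
            assert mf.pseudo_voigt(np.array([1.3]), p)[0] == pytest.approx(10.0)

    def test_lorentzian_half_maximum_at_one_linewidth(self):
        p = PeakShapeParams(x0=0.0, h=1.0, lw=0.5, a=0.0)
        assert mf.pseudo_voigt(np.array([0.5]), p)[0] == pytest.approx(0.5)

    def test_gaussian_value_at_one_linewidth(self):
        # exp(-lw^2 / (2 lw^2)) = exp(-1/2)
        p = PeakShapeParams(x0=0.0, h=1.0, lw=0.5, a=1.0)
        expected = math.exp(-0.5)
        assert mf.pseudo_voigt(np.array([0.5]), p)[0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_linewidth_rejected(self):
        with pytest.raises(mf.DomainError):
            PeakShapeParams(x0=0.0, h=1.0, lw=0.0, a=0.5)
        with pytest.raises(mf.DomainError):
            PeakShapeParams(x0=0.0, h=1.0, lw=-1.0, a=0.5)

    def test_mixing_fraction_outside_unit_interval_rejected(self):
        for a in (-0.1, 1.1):
            with pytest.raises(mf.DomainError):
                PeakShapeParams(x0=0.0, h=1.0, lw=0.1, a=a)

    @given(
        a=st.floats(0.0, 1.0),
        lw=st.floats(1e-4, 1.0),
        dx=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_even_function_of_offset(self, a, lw, dx):
        p = PeakShapeParams(x0=0.0, h=2.0, lw=lw, a=a)
        left = mf.pseudo_voigt(np.array([-dx]), p)[0]
        right = mf.pseudo_voigt(np.array([dx]), p)[0]
        assert left == pytest.approx(right, rel=1e-12, abs=1e-300)

    def test_pure_limits_match_direct_references(self, fine_grid):
        lw, h, x0 = 0.05, 3.0, 2.0
        u = (fine_grid - x0) / lw
        gauss_ref = h * np.exp(-0.5 * u**2)
        lorentz_ref = h * (1.0 / (1.0 + u**2))
        np.testing.assert_array_equal(
            mf.pseudo_voigt(fine_grid, PeakShapeParams(x0, h, lw, 1.0)), gauss_ref
        )
        np.testing.assert_array_equal(
            mf.pseudo_voigt(fine_grid, PeakShapeParams(x0, h, lw, 0.0)), lorentz_ref
        )


# ---------------------------------------------------------------------------
# expand_multiplet
# ---------------------------------------------------------------------------

class TestExpandMultiplet:
    def test_doublet_positions_and_weights(self, registry):
        got = mf.expand_multiplet(registry.get("doublet").pattern, 2.0, {"J": 0.1})
        assert got == [(pytest.approx(1.95), 0.5), (pytest.approx(2.05), 0.5)]

    def test_triplet_positions_and_weights(self, registry):
        got = mf.expand_multiplet(registry.get("triplet").pattern, 1.0, {"J": 0.2})
        pos = [p for p, _ in got]
        w = [w for _, w in got]
        assert pos == pytest.approx([0.8, 1.0, 1.2])
        assert w == [0.25, 0.5, 0.25]

    def test_quadruplet_positions_and_weights(self, registry):
        got = mf.expand_multiplet(registry.get("quadruplet").pattern, 0.0, {"J": 0.2})
        pos = [p for p, _ in got]
        w = [w for _, w in got]
        assert pos == pytest.approx([-0.3, -0.1, 0.1, 0.3])
        assert w == [0.125, 0.375, 0.375, 0.125]

    def test_dd_enumerates_four_sign_combinations(self, registry):
        # hand enumeration: 0 +/- 0.4/2 +/- 0.1/2
        got = mf.expand_multiplet(
            registry.get("doublet_of_doublets").pattern, 0.0, {"J1": 0.4, "J2": 0.1}
        )
        pos = [p for p, _ in got]
        assert pos == pytest.approx([-0.25, -0.15, 0.15, 0.25])
        assert all(w == 0.25 for _, w in got)

    @pytest.mark.parametrize("name", list(BUILTIN_TRUTH))
    def test_zero_coupling_collapses_to_centre(self, registry, name):
        model = registry.get(name)
        J = {j: 0.0 for j in model.pattern.j_names}
        got = mf.expand_multiplet(model.pattern, 1.7, J)
        assert all(p == pytest.approx(1.7) for p, _ in got)
        assert sum(w for _, w in got) == pytest.approx(1.0)

    def test_missing_coupling_name_is_configuration_error(self, registry):
        with pytest.raises(mf.ConfigurationError):
            mf.expand_multiplet(registry.get("doublet").pattern, 0.0, {})

    def test_negative_coupling_rejected(self, registry):
        with pytest.raises(mf.DomainError):
            mf.expand_multiplet(registry.get("doublet").pattern, 0.0, {"J": -0.1})

    def test_positions_sorted_ascending(self, registry):
        got = mf.expand_multiplet(
            registry.get("doublet_of_doublets").pattern, 5.0, {"J1": 0.03, "J2": 0.5}
        )
        pos = [p for p, _ in got]
        assert pos == sorted(pos)


# ---------------------------------------------------------------------------
# simulate_signal / simulate_spectrum
# ---------------------------------------------------------------------------

class TestSimulateSignal:
    def test_singlet_apex_is_total_intensity(self, registry):
        x = np.array([3.2])
        y = mf.simulate_signal(
            registry.get("singlet"), {"x_s": 3.2, "I": 5.0, "lw": 0.01, "a": 0.3}, x
        )
        assert y[0] == pytest.approx(5.0)

    def test_resolved_doublet_component_apex_is_half_intensity(self, registry):
        # analytic tail bound: twin peak at distance J contributes
        # a*exp(-(J/lw)^2/2) + (1-a)/(1+(J/lw)^2) per unit amplitude
        lw, J, a, I = 0.002, 0.1, 0.5, 2.0
        tail = (I / 2) * ((1 - a) / (1 + (J / lw) ** 2) + a * math.exp(-0.5 * (J / lw) ** 2))
        y = mf.simulate_signal(
            registry.get("doublet"),
            {"x_s": 2.0, "I": I, "J": J, "lw": lw, "a": a},
            np.array([2.0 + J / 2]),
        )
        assert abs(y[0] - 1.0) <= tail + 1e-12
        assert tail < 1e-3

    def test_triplet_centre_apex_twice_outer(self, registry):
        vals = {"x_s": 2.0, "I": 4.0, "J": 0.2, "lw": 0.002, "a": 0.5}
        centre = mf.simulate_signal(registry.get("triplet"), vals, np.array([2.0]))[0]
        outer = mf.simulate_signal(registry.get("triplet"), vals, np.array([2.2]))[0]
        assert centre / outer == pytest.approx(2.0, rel=1e-3)

    def test_missing_parameter_is_configuration_error(self, registry):
        with pytest.raises(mf.ConfigurationError):
            mf.simulate_signal(
                registry.get("doublet"), {"x_s": 2.0, "I": 1.0, "lw": 0.01, "a": 0.5},
                np.array([2.0]),
            )

    @pytest.mark.parametrize("name", list(BUILTIN_TRUTH))
    def test_symmetric_about_centre(self, registry, name):
        vals = BUILTIN_TRUTH[name]
        xs = vals["x_s"]
        offsets = np.linspace(0.0, 1.5, 301)
        left = mf.simulate_signal(registry.get(name), vals, xs - offsets)
        right = mf.simulate_signal(registry.get(name), vals, xs + offsets)
        np.testing.assert_allclose(left, right, rtol=1e-12)

    @pytest.mark.parametrize("name", list(BUILTIN_TRUTH))
    def test_apex_identity_for_resolved_peaks(self, registry, name):
        # min inter-peak distance > 20*lw -> max ~= I * max(weight) within 0.1%
        model = registry.get(name)
        vals = dict(BUILTIN_TRUTH[name], lw=0.005)
        peaks = mf.expand_multiplet(
            model.pattern, vals["x_s"], {j: vals[j] for j in model.pattern.j_names}
        )
        if len(peaks) > 1:
            gaps = np.diff([p for p, _ in peaks])
            gaps = gaps[gaps > 0]
            assert gaps.min() > 20 * vals["lw"]
        x = np.linspace(vals["x_s"] - 2, vals["x_s"] + 2, 400001)
        y = mf.simulate_signal(model, vals, x)
        expected = vals["I"] * max(w for _, w in peaks)
        assert y.max() == pytest.approx(expected, rel=1e-3)

    def test_integral_proportional_to_intensity(self, registry):
        # trapezoid integral over +/- 200*lw: constant of proportionality must
        # not depend on J or x_s (10 random draws)
        rng = np.random.default_rng(42)
        model = registry.get("doublet")
        lw, a = 0.01, 0.4
        unit_area = signal_area(1.0, lw, a)
        for _ in range(10):
            xs = rng.uniform(-5, 5)
            J = rng.uniform(0.0, 0.05)
            I = rng.uniform(0.5, 20.0)
            x = np.linspace(xs - 200 * lw, xs + 200 * lw, 60001)
            y = mf.simulate_signal(
                model, {"x_s": xs, "I": I, "J": J, "lw": lw, "a": a}, x
            )
            integral = np.trapezoid(y, x)
            # Lorentzian tails put ~0.3% of the area outside +/-200*lw
            assert integral / I == pytest.approx(unit_area, rel=5e-3)


class TestSimulateSpectrum:
    def test_empty_signal_list_gives_zero_vector(self, fine_grid):
        y = mf.simulate_spectrum([], fine_grid)
        assert y.shape == fine_grid.shape
        assert np.all(y == 0.0)

    def test_single_signal_matches_simulate_signal(self, registry, fine_grid):
        model = registry.get("triplet")
        vals = BUILTIN_TRUTH["triplet"]
        np.testing.assert_array_equal(
            mf.simulate_spectrum([(model, vals)], fine_grid),
            mf.simulate_signal(model, vals, fine_grid),
        )

    def test_sum_is_additive_and_order_invariant(self, registry, fine_grid):
        d = (registry.get("doublet"), {"x_s": 1.0, "I": 3.0, "J": 0.05, "lw": 0.01, "a": 0.2})
        t = (registry.get("triplet"), {"x_s": 3.0, "I": 7.0, "J": 0.08, "lw": 0.02, "a": 0.9})
        y1 = mf.simulate_spectrum([d, t], fine_grid)
        y2 = mf.simulate_spectrum([t, d], fine_grid)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_allclose(
            y1,
            mf.simulate_signal(*d, fine_grid) + mf.simulate_signal(*t, fine_grid),
            rtol=0, atol=1e-14,
        )

    def test_empty_grid_rejected(self):
        with pytest.raises(mf.DomainError):
            mf.simulate_spectrum([], np.array([]))


# ---------------------------------------------------------------------------
# registry / suggestion / custom models
# ---------------------------------------------------------------------------

class TestRegistry:
    def test_suggest_four_peaks(self, registry):
        assert registry.suggest(4) == ["doublet_of_doublets", "quadruplet"]

    def test_suggest_low_multiplicities(self, registry):
        assert registry.suggest(1) == ["singlet"]
        assert registry.suggest(2) == ["doublet"]
        assert registry.suggest(3) == ["triplet"]

    def test_suggest_unmatched_count_is_empty(self, registry):
        assert registry.suggest(7) == []

    def test_suggest_invalid_count(self, registry):
        with pytest.raises(mf.DomainError):
            registry.suggest(0)

    def test_duplicate_name_rejected(self, registry):
        with pytest.raises(mf.ValidationError):
            registry.register(registry.get("doublet"))

    def test_pattern_weights_sum_to_one_exactly(self, registry):
        for name in registry.names():
            assert sum(registry.get(name).pattern.peak_weights) == F(1)

    def test_asymmetric_offsets_rejected(self):
        with pytest.raises(mf.ValidationError):
            MultipletPattern(
                name="bad",
                j_names=("J",),
                peak_offsets=({"J": F(-1, 2)}, {"J": F(1, 3)}),
                peak_weights=(F(1, 2), F(1, 2)),
            )

    def test_weights_not_summing_to_one_rejected(self):
        with pytest.raises(mf.ValidationError):
            MultipletPattern(
                name="bad",
                j_names=("J",),
                peak_offsets=({"J": F(-1, 2)}, {"J": F(1, 2)}),
                peak_weights=(F(1, 2), F(1, 4)),
            )

    def test_register_doublet_of_triplets(self, registry):
        components = []
        for s1 in (F(-1, 2), F(1, 2)):
            for s2, w in ((F(-1), F(1, 8)), (F(0), F(1, 4)), (F(1), F(1, 8))):
                components.append(({"J1": s1, "J2": s2}, w))
        pattern = MultipletPattern(
            name="doublet_of_triplets",
            j_names=("J1", "J2"),
            peak_offsets=tuple(dict(o) for o, _ in components),
            peak_weights=tuple(w for _, w in components),
        )
        registry.register(SignalModel("doublet_of_triplets", pattern))
        assert "doublet_of_triplets" in registry.suggest(6)

    def test_module_level_register_uses_explicit_registry(self, registry):
        pattern = registry.get("singlet").pattern
        model = SignalModel("flat", pattern)
        mf.register_model(model, registry)
        assert "flat" in registry.suggest(1)


class TestParameterSpec:
    def test_relative_ppm_bounds_are_additive(self):
        spec = ParameterSpec("x_s", None, 0.1, 0.2, "relative", "ppm")
        assert spec.resolve_bounds(2.0) == (pytest.approx(1.9), pytest.approx(2.2))

    def test_relative_scale_bounds_are_multiplicative(self):
        spec = ParameterSpec("I", None, 0.5, 4.0, "relative", "intensity")
        assert spec.resolve_bounds(10.0) == (pytest.approx(5.0), pytest.approx(40.0))

    def test_absolute_bounds_validate_default(self):
        with pytest.raises(mf.ValidationError):
            ParameterSpec("a", 2.0, 0.0, 1.0, "absolute", "dimensionless")

    def test_unknown_bound_mode_rejected(self):
        with pytest.raises(mf.ValidationError):
            ParameterSpec("x", 0.0, 0.0, 1.0, "scaled", "ppm")


class TestModelFile:
    def test_load_declarative_model(self, tmp_path, registry):
        text = """
name: doublet_of_triplets
j_names: [J1, J2]
peaks:
  - {offset: {J1: -1/2, J2: -1}, weight: 1/8}
  - {offset: {J1: -1/2, J2: 0}, weight: 1/4}
  - {offset: {J1: -1/2, J2: 1}, weight: 1/8}
  - {offset: {J1: 1/2, J2: -1}, weight: 1/8}
  - {offset: {J1: 1/2, J2: 0}, weight: 1/4}
  - {offset: {J1: 1/2, J2: 1}, weight: 1/8}
parameters:
  a: {init: 0.2}
"""
        path = tmp_path / "dt.yaml"
        path.write_text(text)
        model = mf.load_model_file(path)
        assert model.n_peaks == 6
        assert model.parameter_specs["a"].default_init == 0.2
        registry.register(model)
        assert registry.suggest(6) == ["doublet_of_triplets"]

    def test_missing_required_key(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("name: x\n")
        with pytest.raises(mf.ValidationError):
            mf.load_model_file(path)


class TestDerivedQuantities:
    def test_fwhm_limits(self):
        assert peak_fwhm(0.5, 0.0) == pytest.approx(1.0)
        assert peak_fwhm(0.5, 1.0) == pytest.approx(math.sqrt(2 * math.log(2)), rel=1e-12)

    def test_fwhm_monotone_between_limits(self):
        widths = [peak_fwhm(1.0, a) for a in np.linspace(0, 1, 11)]
        assert all(np.diff(widths) > 0)

    def test_area_matches_numeric_integral(self, registry):
        lw, a, I = 0.02, 0.7, 6.0
        x = np.linspace(-40, 44, 2000001)
        y = mf.simulate_signal(
            registry.get("singlet"), {"x_s": 2.0, "I": I, "lw": lw, "a": a}, x
        )
        assert np.trapezoid(y, x) == pytest.approx(signal_area(I, lw, a), rel=1e-3)
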