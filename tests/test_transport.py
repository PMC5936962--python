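"""Diffusive resistance, oxygen currents, and the total-resistance breakdown."""

import numpy as np
import pytest

from placentox import (
    TransportOptions,
    blood_uptake,
    diffusive_prefactor,
    diffusive_resistance,
    diffusive_resistance_unsubstituted,
    oxygen_mass_current,
    oxygen_volume_flow,
    resistance_coefficients,
    total_resistance,
)

ML_MIN = 1e-6 / 60.0


class TestDiffusivePrefactor:
    def test_paper_value(self):
        assert diffusive_prefactor("paper") == 0.00875

    def test_exact_construction(self):
        # barrier fraction over (exchange-area coefficient x tail coefficient)
        exact = 0.2 / ((3 * np.pi / 2) / (1 - 2 ** (-1 / 3)))
        assert diffusive_prefactor("exact") == pytest.approx(exact, rel=1e-15)

    def test_rounded_construction_gives_published_number(self):
        assert 0.2 / ((3 * np.pi / 2) * 4.85) == pytest.approx(0.00875, abs=5e-6)


class TestDiffusiveResistance:
    def test_human_reference_value(self, human):
        # per cotyledon set (before the 1/alpha factor)
        assert diffusive_resistance(human, 18) == pytest.approx(4.1864e7, rel=1e-4)

    def test_quarters_every_three_levels(self, preset):
        for N in range(0, 30, 5):
            ratio = diffusive_resistance(preset, N + 3) / diffusive_resistance(preset, N)
            assert ratio == pytest.approx(0.25, rel=1e-12)

    def test_strictly_decreasing(self, preset):
        vals = [diffusive_resistance(preset, n) for n in range(40)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("N", range(0, 61, 4))
    def test_substituted_equals_unsubstituted_in_exact_mode(self, preset, N):
        # the closed form with the tail coefficient folded in must agree with
        # the raw form that uses d_ft from the tree geometry
        folded = diffusive_resistance(preset, N, coefficients="exact")
        raw = diffusive_resistance_unsubstituted(preset, N, tail="exact")
        assert folded == pytest.approx(raw, rel=1e-12)

    def test_paper_mode_agrees_to_rounding_error(self, human):
        folded = diffusive_resistance(human, 10, coefficients="paper")
        raw = diffusive_resistance_unsubstituted(human, 10, tail="paper")
        assert folded == pytest.approx(raw, rel=2e-3)


class TestOxygenCurrents:
    def test_zero_drop_zero_current(self, human):
        assert oxygen_mass_current(human, 18, 0.0) == 0.0

    def test_linearity_in_pressure_drop(self, preset):
        one = oxygen_mass_current(preset, 12, 100.0)
        assert oxygen_mass_current(preset, 12, 200.0) == pytest.approx(2 * one, rel=1e-12)
        assert one / 100.0 == pytest.approx(
            oxygen_mass_current(preset, 12, 1.0), rel=1e-12
        )

    def test_human_reference_value(self, human):
        assert oxygen_mass_current(human, 18, 2533.1) == pytest.approx(2.830e-6, rel=1e-3)

    def test_blood_uptake_reference(self):
        assert blood_uptake(8.333e-6, 1.777, 4.374) == pytest.approx(2.164e-5, rel=1e-3)
        assert blood_uptake(8.333e-6, 4.374, 1.777) == blood_uptake(8.333e-6, 1.777, 4.374)
        assert blood_uptake(1.0, 2.0, 2.0) == 0.0

    def test_uptake_linear_in_flow(self):
        assert blood_uptake(2e-6, 1.0, 3.0) == pytest.approx(2 * blood_uptake(1e-6, 1.0, 3.0))


class TestTotalResistance:
    def test_human_reference_breakdown(self, human):
        b = total_resistance(human, 18)
        assert b.R_conv_ox == pytest.approx(2.911e10, rel=1e-3)
        assert b.R_diff_ox == pytest.approx(5.233e5, rel=1e-3)
        assert b.R_total == pytest.approx(b.R_conv_ox + b.R_diff_ox, rel=1e-15)
        assert b.log10_R_total == pytest.approx(np.log10(b.R_total), rel=1e-15)

    def test_cotyledon_count_scales_all_components(self, human):
        single = total_resistance(human.model_copy(update={"alpha_cotyledons": 1}), 18)
        many = total_resistance(human, 18)
        assert single.R_conv_ox == pytest.approx(80 * many.R_conv_ox, rel=1e-12)
        assert single.R_diff_ox == pytest.approx(80 * many.R_diff_ox, rel=1e-12)

    def test_bifurcation_included_only_on_request(self, mouse):
        base = total_resistance(mouse, 10)
        with_b = total_resistance(mouse, 10, TransportOptions(include_bifurcation=True))
        # the junction term is ~20 orders of magnitude below the channel terms
        # (the reason it is negligible); the inclusion is exactly additive
        assert base.R_bifur > 0
        assert with_b.R_total == base.R_total + base.R_bifur
        assert base.R_total == base.R_conv_ox + base.R_diff_ox

    def test_first_differences_change_sign_at_most_once(self, preset):
        totals = np.array([total_resistance(preset, n).R_total for n in range(1, 61)])
        signs = np.sign(np.diff(totals))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes <= 1

    def test_rho_b_cancels_in_component_ratio(self, human):
        ratio = lambda p: (lambda b: b.R_diff_ox / b.R_conv_ox)(total_resistance(p, 18))
        heavier = human.model_copy(update={"rho_b": 1234.5})
        assert ratio(human) == pytest.approx(ratio(heavier), rel=1e-12)

    def test_computed_concentration_source_changes_dC(self, human):
        printed = total_resistance(human, 18)
        computed = total_resistance(human, 18, TransportOptions(concentration_source="computed"))
        # computed Hill contents give a larger driving dC, hence smaller R_conv
        assert computed.R_conv_ox < printed.R_conv_ox

    def test_zero_dC_is_an_error(self, human):
        degenerate = human.model_copy(
            update={"C_bound_artery": 4.244, "C_bound_capillary": 4.244}
        )
        with pytest.raises(ValueError, match="zero"):
            total_resistance(degenerate, 18)

    def test_coefficients_expose_landscape_form(self, preset):
        A, C = resistance_coefficients(preset)
        b = total_resistance(preset, 7)
        assert b.R_total == pytest.approx(A * 8 + C * 2.0 ** ((1 - 14) / 3), rel=1e-12)


class TestOxygenVolumeFlow:
    def test_human_published_value_with_default_drop(self, human):
        assert oxygen_volume_flow(human, 18) / ML_MIN == pytest.approx(25.13, abs=5e-3)

    def test_mouse_value_at_same_drop(self, mouse):
        flow = oxygen_volume_flow(mouse, 22, 2533.1)
        assert flow / ML_MIN == pytest.approx(0.6157, rel=1e-3)

    def test_decreasing_in_depth(self, human):
        flows = [oxygen_volume_flow(human, n) for n in range(30)]
        assert all(b < a for a, b in zip(flows, flows[1:]))

    def test_nonpositive_drop_rejected(self, human):
        with pytest.raises(ValueError):
            oxygen_volume_flow(human, 18, 0.0)
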