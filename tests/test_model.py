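"""Unit tests for the kinetic rate laws and the state/parameter data model."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labferm import (
    InoculumSpec,
    ParameterSet,
    StateVector,
    StoichiometryConstants,
    cfu_to_mass,
    control_parameters,
    mass_to_cfu,
    p_acidilactici_parameters,
    rhs,
)
from labferm.exceptions import ConfigurationError, DomainError
from labferm.model import (
    biomass_rate,
    formate_rate,
    glucose_rate,
    lactate_rate,
    lag_factor,
    protein_npn_rates,
)


class TestLagFactor:
    def test_zero_at_inoculation(self):
        assert lag_factor(0.0, 0.141) == 0.0

    def test_limit_is_one(self):
        assert lag_factor(1e6, 0.141) == pytest.approx(1.0, abs=1e-12)

    def test_published_lag_rate_at_24h(self):
        # 1 - exp(-0.141*24), frozen from a 20-digit evaluation
        assert lag_factor(24.0, 0.141) == pytest.approx(0.96608846306751113, rel=1e-12)

    @pytest.mark.parametrize("t,k3", [(-1.0, 0.1), (1.0, 0.0), (1.0, -0.2)])
    def test_domain_errors(self, t, k3):
        with pytest.raises(DomainError):
            lag_factor(t, k3)

    @given(st.floats(0.0, 200.0), st.floats(1e-3, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, t, k3):
        v = lag_factor(t, k3)
        # mathematically in [0, 1); the supremum is attainable in floats
        assert 0.0 <= v <= 1.0
        assert lag_factor(t + 1.0, k3) >= v


class TestBiomassRate:
    def test_zero_biomass_is_fixed_point(self, control_p):
        y = np.array([0.0, 0.5, 0.1, 0.0, 0.0, 1.0])
        assert biomass_rate(10.0, y, control_p) == 0.0

    def test_at_carrying_capacity_only_lysis_remains(self, control_p):
        y = np.array([control_p.y1_max, 0.5, 0.1, 0.0, 0.0, 1.0])
        # logistic bracket vanishes; lag factor ~1 at large t
        assert biomass_rate(1e4, y, control_p) == pytest.approx(
            -control_p.k12 * control_p.y1_max, rel=1e-12
        )

    def test_monod_saturation_limit(self, control_p):
        # y2 >> k2, t large, y1 << y1_max  =>  dy1 ~ (k1 - k12) * y1
        y1 = control_p.y1_max * 1e-6
        y = np.array([y1, 1e4 * control_p.k2, 0.1, 0.0, 0.0, 1.0])
        expected = (control_p.k1 - control_p.k12) * y1
        assert biomass_rate(1e4, y, control_p) == pytest.approx(expected, rel=1e-3)

    def test_lag_kills_growth_at_time_zero(self, control_p):
        """At t=0 the lag factor is exactly zero, so only lysis acts."""
        y = np.array([0.01, 0.5, 0.1, 0.0, 0.0, 1.0])
        assert biomass_rate(0.0, y, control_p) == pytest.approx(
            -control_p.k12 * 0.01, rel=1e-14
        )


def _coupled_rates_oracle(y2, dy1, p, s):
    """Independent 2x2 linear solve of the protein/NPN balance.

    [1   b] [dy2]   [-a*dy1 - loss]
    [k4  1] [dy3] = [k5*y2        ]
    """
    a = p.cor_bio * s.nitrogen_fraction_biomass
    b = p.cor_npn * s.nitrogen_fraction_npn
    loss = p.cor_x * y2 if p.protein_loss == "first_order" else p.cor_x
    A = np.array([[1.0, b], [p.k4, 1.0]])
    rhs_vec = np.array([-a * dy1 - loss, p.k5 * y2])
    return np.linalg.solve(A, rhs_vec)


class TestProteinNpnCoupling:
    def test_decoupled_constant_loss_case(self, stoich):
        p = control_parameters(k4=0.0, k5=0.0, protein_loss="constant")
        y = np.array([0.0, 0.5, 0.1, 0.0, 0.0, 1.0])
        dy2, dy3 = protein_npn_rates(0.0, y, 0.0, p, stoich)
        assert dy3 == 0.0
        assert dy2 == pytest.approx(-p.cor_x, rel=1e-14)

    def test_one_way_coupling_without_k4(self, control_p, stoich):
        p = control_p.replace(k4=0.0)
        y = np.array([0.01, 0.563, 0.109, 0.0, 0.0, 1.0])
        dy1 = 0.003
        dy2, dy3 = protein_npn_rates(5.0, y, dy1, p, stoich)
        assert dy3 == pytest.approx(p.k5 * 0.563, rel=1e-14)
        a = p.cor_bio * stoich.nitrogen_fraction_biomass
        b = p.cor_npn * stoich.nitrogen_fraction_npn
        assert dy2 == pytest.approx(-a * dy1 - b * dy3 - p.cor_x * 0.563, rel=1e-12)

    @pytest.mark.parametrize("batch_params", ["control", "pa"])
    @pytest.mark.parametrize("dy1", [0.0, 0.002, -0.0005])
    def test_matches_linear_solve_oracle(self, batch_params, dy1, stoich):
        p = control_parameters() if batch_params == "control" else p_acidilactici_parameters()
        y = np.array([0.01, 0.563, 0.109, 0.2, 0.01, 0.8])
        dy2, dy3 = protein_npn_rates(12.0, y, dy1, p, stoich)
        exp2, exp3 = _coupled_rates_oracle(0.563, dy1, p, stoich)
        assert dy2 == pytest.approx(exp2, rel=1e-12)
        assert dy3 == pytest.approx(exp3, rel=1e-12)

    def test_residuals_of_both_balances_vanish(self, control_p, stoich):
        """Substituting the closed-form rates back leaves residuals < 1e-12."""
        y = np.array([0.05, 0.4, 0.12, 0.5, 0.02, 0.7])
        dy1 = 0.004
        dy2, dy3 = protein_npn_rates(20.0, y, dy1, control_p, stoich)
        a = control_p.cor_bio * stoich.nitrogen_fraction_biomass
        b = control_p.cor_npn * stoich.nitrogen_fraction_npn
        res2 = dy2 - (-(a * dy1 + b * dy3) - control_p.cor_x * 0.4)
        res3 = dy3 - (-control_p.k4 * dy2 + control_p.k5 * 0.4)
        assert abs(res2) < 1e-12 and abs(res3) < 1e-12

    def test_npn_increases_while_protein_degrades(self, control_p, stoich):
        y = np.array([0.05, 0.4, 0.12, 0.5, 0.02, 0.7])
        dy2, dy3 = protein_npn_rates(20.0, y, 0.004, control_p, stoich)
        assert dy2 <= 0.0 and dy3 >= 0.0

    def test_singular_coupling_reports_parameters(self, stoich):
        b = stoich.nitrogen_fraction_npn  # cor_npn=1 -> b*k4 must equal 1
        p = control_parameters(cor_npn=1.0, k4=1.0 / b)
        y = np.array([0.01, 0.5, 0.1, 0.0, 0.0, 1.0])
        with pytest.raises(ConfigurationError, match="k4"):
            protein_npn_rates(0.0, y, 0.0, p, stoich)


class TestProductRates:
    def test_lactate_saturated_and_nogrowth(self, control_p):
        y = np.array([0.1, 0.4, 0.1, control_p.y4_max, 0.0, 1.0])
        assert lactate_rate(10.0, y, 0.0, control_p) == 0.0

    def test_lactate_zero_product_rate_is_k7(self, control_p):
        y = np.array([0.1, 0.4, 0.1, 0.0, 0.0, 1.0])
        assert lactate_rate(10.0, y, 0.0, control_p) == pytest.approx(control_p.k7)

    def test_lactate_scalar_oracle(self, control_p):
        # k6*dy1 + k7*(1 - 1/2) with the published control coefficients
        y = np.array([0.1, 0.4, 0.1, control_p.y4_max / 2, 0.0, 1.0])
        assert lactate_rate(10.0, y, 0.001, control_p) == pytest.approx(
            0.414 * 0.001 + 0.032, rel=1e-12
        )

    def test_formate_saturated(self, pa_p):
        y = np.array([0.1, 0.4, 0.1, 0.0, pa_p.y5_max, 1.0])
        assert formate_rate(10.0, y, 0.0, pa_p) == 0.0

    def test_formate_zero_level_rate_is_k9(self, pa_p):
        p = pa_p.replace(k8=0.0)
        y = np.array([0.1, 0.4, 0.1, 0.0, 0.0, 1.0])
        assert formate_rate(10.0, y, 0.01, p) == pytest.approx(p.k9)

    def test_formate_scalar_oracle(self, pa_p):
        y = np.array([0.1, 0.4, 0.1, 0.0, 0.05, 1.0])
        dy1 = 0.0021
        expected = pa_p.k8 * dy1 + pa_p.k9 * (1 - 0.05 / pa_p.y5_max)
        assert formate_rate(24.0, y, dy1, pa_p) == pytest.approx(expected, rel=1e-12)

    def test_glucose_no_flux_at_saturation(self, control_p):
        y = np.array([0.1, 0.4, 0.1, control_p.y4_max, 0.0, 1.0])
        assert glucose_rate(10.0, y, 0.0, control_p) == 0.0

    def test_glucose_zero_lactate_rate(self, control_p):
        y = np.array([0.1, 0.4, 0.1, 0.0, 0.0, 1.0])
        assert glucose_rate(10.0, y, 0.0, control_p) == pytest.approx(-control_p.k11)

    def test_glucose_scalar_oracle(self, control_p):
        y = np.array([0.1, 0.4, 0.1, 0.5 * control_p.y4_max, 0.0, 1.0])
        expected = -(9.855e-3 * 0.002 + 0.101 * 0.5)
        assert glucose_rate(10.0, y, 0.002, control_p) == pytest.approx(expected, rel=1e-12)

    def test_glucose_nonpositive_under_growth(self, control_p):
        y = np.array([0.1, 0.4, 0.1, 0.9, 0.0, 1.0])
        assert glucose_rate(10.0, y, 0.001, control_p) <= 0.0


class TestRhs:
    def test_composition_identity_on_random_states(self, control_p, stoich):
        """rhs agrees with assembling the component rate laws by hand."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.uniform(0.0, 1.0, 6)
            y[0] = rng.uniform(0.0, control_p.y1_max)
            t = rng.uniform(0.0, 60.0)
            d = rhs(t, y, control_p, stoich)
            dy1 = biomass_rate(t, y, control_p)
            dy2, dy3 = protein_npn_rates(t, y, dy1, control_p, stoich)
            expected = np.array([
                dy1, dy2, dy3,
                lactate_rate(t, y, dy1, control_p),
                formate_rate(t, y, dy1, control_p),
                glucose_rate(t, y, dy1, control_p),
            ])
            np.testing.assert_allclose(d, expected, rtol=1e-13)

    def test_all_zero_state_closed_form(self, stoich):
        p = control_parameters(protein_loss="constant")
        d = rhs(0.0, np.zeros(6), p, stoich)
        b = p.cor_npn * stoich.nitrogen_fraction_npn
        exp_dy2 = -p.cor_x / (1 - b * p.k4)
        np.testing.assert_allclose(
            d, [0.0, exp_dy2, -p.k4 * exp_dy2, p.k7, p.k9, -p.k11], rtol=1e-12
        )

    def test_batched_evaluation_matches_loop(self, control_p, stoich):
        rng = np.random.default_rng(3)
        Y = rng.uniform(0.01, 0.9, (6, 5))
        t = 12.0
        batched = rhs(t, Y, control_p, stoich)
        for m in range(5):
            np.testing.assert_allclose(batched[:, m], rhs(t, Y[:, m], control_p, stoich),
                                       rtol=1e-13)


class TestConversions:
    def test_zero_count(self):
        assert cfu_to_mass(0.0) == 0.0

    def test_doublet_morphology_dose(self):
        assert cfu_to_mass(2e7, 2e-12) == pytest.approx(4e-3, rel=1e-12)

    def test_tetrad_morphology_dose(self):
        assert cfu_to_mass(2e7, 3e-12) == pytest.approx(6e-3, rel=1e-12)

    def test_round_trip(self):
        spec = InoculumSpec(dose=2e7, conversion=3e-12, morphology_label="doublets+tetrads")
        m = spec.initial_biomass()
        assert mass_to_cfu(m, spec) == pytest.approx(2e7, rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            cfu_to_mass(-1.0)


class TestDataModel:
    def test_parameter_json_round_trip(self, tmp_path, control_p):
        path = tmp_path / "params.json"
        control_p.to_json(path)
        doc = json.loads(path.read_text())
        # JSON uses the conventional symbol spellings
        assert "cor_NPN" in doc and "cor_X" in doc and "k12" in doc
        assert ParameterSet.from_json(path) == control_p

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            control_parameters(k2=0.0)
        with pytest.raises(DomainError):
            control_parameters(y4_max=-1.0)
        with pytest.raises(DomainError):
            control_parameters(k6=-0.1)

    def test_state_vector_round_trip(self):
        sv = StateVector.from_array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], t=12.0)
        np.testing.assert_array_equal(sv.as_array(), [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert sv.t == 12.0

    def test_stoichiometry_nitrogen_fractions(self, stoich):
        assert 0.0 < stoich.nitrogen_fraction_biomass < 1.0
        assert 0.0 < stoich.nitrogen_fraction_npn < 1.0
        with pytest.raises(DomainError):
            StoichiometryConstants(mw_bio=-1.0)
        # a unit with more nitrogen mass than formula weight is unphysical
        with pytest.raises(DomainError):
            StoichiometryConstants(n_npn=10.0, mw_npn=20.0)
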