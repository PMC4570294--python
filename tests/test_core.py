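"""Cost-model arithmetic: multiplier, decomposition, baselines, surfaces."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tumor_energetics import (
    EnergyConstants,
    PatientState,
    TumorEnergetics,
    cost_multiplier,
    cost_surface,
    cost_surface_frame,
    cunningham_ree,
    decompose_specific_cost,
    kleiber_bmr,
    patient_metabolic_rate,
    round_half_away,
    round_sigfigs,
    tumor_cost,
)
from tumor_energetics.exceptions import DomainError, UsageError

fractions = st.floats(0.0, 1.0, allow_nan=False)
rates = st.floats(0.0, 2000.0, allow_nan=False)


class TestCostMultiplier:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 1.0), (1.0, 3.0), (0.25, 1.5), (0.5, 2.0)],
    )
    def test_known_values(self, x, expected):
        assert cost_multiplier(x) == pytest.approx(expected)

    @pytest.mark.parametrize("x", [-0.01, 1.01, 2.0])
    def test_out_of_range_raises_naming_value(self, x):
        with pytest.raises(DomainError, match=str(x)):
            cost_multiplier(x)

    @given(fractions)
    def test_range_is_one_to_three(self, x):
        assert 1.0 <= cost_multiplier(x) <= 3.0


class TestDecomposeSpecificCost:
    def test_ree_cohort_row(self):
        """K_cost 300 +/- 110 at X=0.25 splits 200/50/150/150 with SEs 73/18/55/55."""
        d = decompose_specific_cost(300.0, 0.25, se_k_cost=110.0)
        assert d.cancer == pytest.approx(200.0)
        assert d.aerobic == pytest.approx(150.0)
        assert d.anaerobic == pytest.approx(50.0)
        assert d.cori == pytest.approx(150.0)
        assert d.se_cancer == pytest.approx(110.0 / 1.5)
        assert d.se_aerobic == pytest.approx(55.0)
        assert d.se_anaerobic == pytest.approx(110.0 / 6.0)
        assert d.se_cori == pytest.approx(55.0)
        assert d.specific

    def test_fully_aerobic_has_no_cori_component(self):
        d = decompose_specific_cost(480.0, 0.0)
        assert d.cancer == 480.0
        assert d.cori == 0.0 and d.anaerobic == 0.0

    def test_oxygen_study_upper_bound(self):
        d = decompose_specific_cost(470.0, 0.25)
        assert d.cancer == pytest.approx(313.333, abs=1e-3)
        assert round_sigfigs(d.cancer, 2) == 310.0

    def test_negative_inputs_raise(self):
        with pytest.raises(DomainError):
            decompose_specific_cost(-1.0, 0.25)
        with pytest.raises(DomainError):
            decompose_specific_cost(300.0, 0.25, se_k_cost=-5.0)

    @given(rates, fractions)
    def test_identities_and_recomposition(self, k_cost, x):
        d = decompose_specific_cost(k_cost, x)
        d.validate(rtol=1e-9)
        assert d.aerobic + d.cori == pytest.approx(k_cost, rel=1e-12, abs=1e-12)

    @given(rates, fractions, st.floats(0.0, 500.0, allow_nan=False))
    def test_se_propagates_as_scalar_multiple(self, k_cost, x, se):
        d = decompose_specific_cost(k_cost, x, se_k_cost=se)
        if k_cost > 0:
            assert d.se_cancer == pytest.approx(se * d.cancer / k_cost, rel=1e-12)
            assert d.se_cori == pytest.approx(se * d.cori / k_cost, rel=1e-12)


class TestTumorCost:
    @pytest.mark.parametrize(
        "k, m, x, expected",
        [
            (200.0, 1.8, 0.25, 540.0),  # disseminated metastatic example
            (200.0, 0.83, 0.25, 249.0),  # mean retrospective burden
            (350.0, 0.0, 0.7, 0.0),
        ],
    )
    def test_known_costs(self, k, m, x, expected):
        assert tumor_cost(TumorEnergetics(k, m, x)).cost == pytest.approx(expected)

    def test_identities_hold_over_random_draws(self):
        rng = np.random.default_rng(7)
        for k, m, x in zip(
            rng.uniform(0, 500, 10_000),
            rng.uniform(0, 5, 10_000),
            rng.uniform(0, 1, 10_000),
        ):
            tumor_cost(TumorEnergetics(k, m, x)).validate(rtol=1e-9)

    @given(
        st.floats(0.1, 500.0),
        st.floats(0.01, 5.0),
        fractions,
        st.floats(0.1, 10.0),
    )
    def test_homogeneous_degree_one_in_mass_and_rate(self, k, m, x, scale):
        base = tumor_cost(TumorEnergetics(k, m, x)).cost
        assert tumor_cost(TumorEnergetics(k, m * scale, x)).cost == pytest.approx(
            base * scale, rel=1e-9
        )
        assert tumor_cost(TumorEnergetics(k * scale, m, x)).cost == pytest.approx(
            base * scale, rel=1e-9
        )

    def test_invalid_tumor_parameters_raise(self):
        with pytest.raises(DomainError):
            TumorEnergetics(-1.0, 1.0, 0.5)
        with pytest.raises(DomainError):
            TumorEnergetics(200.0, 1.0, 1.5)


class TestBaselines:
    def test_kleiber_reference_values(self):
        assert kleiber_bmr(1.0) == pytest.approx(69.6)
        assert kleiber_bmr(70.0) == pytest.approx(69.6 * 70.0**0.75, rel=1e-12)
        assert kleiber_bmr(70.0) == pytest.approx(1684.4, abs=0.05)

    def test_headline_tumor_is_a_third_of_reference_bmr(self):
        cost = tumor_cost(TumorEnergetics(200.0, 1.8, 0.25)).cost
        pct = 100.0 * cost / kleiber_bmr(70.0)
        assert round_half_away(pct) == 32.0

    @pytest.mark.parametrize("ffm, expected", [(50.0, 1450.0), (60.0, 1666.0)])
    def test_cunningham_linear_values(self, ffm, expected):
        assert cunningham_ree(ffm) == pytest.approx(expected)

    def test_cunningham_intercept_limit(self):
        assert cunningham_ree(1e-12) == pytest.approx(370.0)

    @pytest.mark.parametrize("fn", [kleiber_bmr, cunningham_ree])
    def test_nonpositive_mass_raises(self, fn):
        with pytest.raises(DomainError):
            fn(0.0)
        with pytest.raises(DomainError):
            fn(-10.0)

    def test_patient_rate_linear_in_tumor_mass(self):
        base = patient_metabolic_rate(70.0, TumorEnergetics(200.0, 0.0, 0.25), 300.0)
        one = patient_metabolic_rate(70.0, TumorEnergetics(200.0, 1.0, 0.25), 300.0)
        two = patient_metabolic_rate(70.0, TumorEnergetics(200.0, 2.0, 0.25), 300.0)
        assert base == pytest.approx(kleiber_bmr(70.0))
        assert one == pytest.approx(base + 300.0)
        assert two - one == pytest.approx(300.0)

    def test_constants_override_flows_through(self):
        c = EnergyConstants().replace(kleiber_coefficient=69.9)
        assert kleiber_bmr(1.0, c) == pytest.approx(69.9)

    def test_patient_state_composes_ree(self):
        cost = tumor_cost(TumorEnergetics(200.0, 1.8, 0.25))
        ps = PatientState.with_tumor(70.0, 55.0, 1600.0, cost)
        assert ps.ree_ic == pytest.approx(1600.0 + cost.cost)


class TestCostSurface:
    def test_single_cell_matches_worked_example(self):
        assert cost_surface(200.0, [1.8], [0.25])[0, 0] == pytest.approx(540.0)

    def test_anaerobic_extremes_differ_threefold(self):
        grid = cost_surface(200.0, [0.5, 1.0, 2.5], [0.0, 1.0])
        assert np.allclose(grid[:, 1] / grid[:, 0], 3.0)

    def test_monotone_and_corner(self):
        m = np.linspace(0, 3, 31)
        x = np.linspace(0, 1, 21)
        grid = cost_surface(200.0, m, x)
        assert grid.max() == pytest.approx(1800.0)
        assert (np.diff(grid, axis=0) >= 0).all()
        assert (np.diff(grid, axis=1) >= 0).all()

    def test_long_format_frame_round_trips(self):
        frame = cost_surface_frame(200.0, [0.0, 1.8], [0.0, 0.25])
        assert list(frame.columns) == [
            "m_cancer_kg",
            "x_anaerobic",
            "p_cost_kcal_per_day",
        ]
        row = frame[(frame.m_cancer_kg == 1.8) & (frame.x_anaerobic == 0.25)]
        assert row.p_cost_kcal_per_day.iloc[0] == pytest.approx(540.0)

    def test_empty_grid_raises(self):
        with pytest.raises(UsageError):
            cost_surface(200.0, [], [0.25])


class TestRounding:
    @pytest.mark.parametrize(
        "value, n, expected",
        [
            (466.9, 2, 470.0),
            (249.0, 2, 250.0),
            (0.0, 2, 0.0),
            (313.333, 2, 310.0),
            (18.333, 2, 18.0),
            (-466.9, 2, -470.0),
            (0.0425, 1, 0.04),
            (145.0, 2, 150.0),  # half rounds away from zero
        ],
    )
    def test_sigfigs(self, value, n, expected):
        assert round_sigfigs(value, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_sigfig_count(self):
        with pytest.raises(DomainError):
            round_sigfigs(1.0, 0)

    @pytest.mark.parametrize(
        "value, expected", [(22.89, 23.0), (0.5, 1.0), (-0.5, -1.0), (2.5, 3.0)]
    )
    def test_half_away(self, value, expected):
        assert round_half_away(value) == expected


class TestEnergyConstants:
    def test_defaults_satisfy_atp_bookkeeping(self):
        c = EnergyConstants()
        assert c.atp_cori_cost_per_glucose == 3 * c.atp_glycolysis_per_glucose
        assert c.atp_aerobic_per_glucose / c.atp_glycolysis_per_glucose == 15
        assert c.cori_multiplier_slope == 2.0

    def test_rejects_nonpositive_and_unknown_fields(self):
        with pytest.raises(DomainError):
            EnergyConstants(glucose_energy_kcal_per_mol=-686.0)
        with pytest.raises(DomainError):
            EnergyConstants().replace(not_a_field=1.0)

    def test_config_file_round_trip(self, tmp_path):
        path = tmp_path / "constants.yaml"
        path.write_text("kleiber_coefficient: 69.9\n")
        c = EnergyConstants.from_file(path)
        assert c.kleiber_coefficient == 69.9
        assert c.cunningham_slope == 21.6  # untouched default
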