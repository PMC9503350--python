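import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipoquant import (
    FrameSchedule,
    SteadyPhaseRule,
    Tac,
    bat_sat_ratio,
    fractional_extraction,
    glucose_uptake,
    group_bat_sat_ratio,
    sat_mass,
    tissue_tac,
    whole_depot_gu,
)


def _fine_schedule(dt=0.1, end=60.0):
    starts = np.arange(0.0, end, dt)
    return FrameSchedule(starts, np.full(starts.size, dt))


class TestFractionalExtraction:
    def test_constant_curves_closed_form(self):
        # blood 1 kBq/mL throughout, tissue 0.6 in the 40-60 min window,
        # endpoint at the window midpoint: GE -> 0.6 / 50 = 0.012 min^-1
        sched = _fine_schedule()
        blood = Tac(sched, np.ones(sched.n_frames), "blood")
        tissue = Tac(sched, np.where(sched.mid >= 40, 0.6, 0.0), "SAT")
        ge = fractional_extraction(tissue, blood)
        assert ge == pytest.approx(0.012, rel=1e-2)

    def test_zero_tissue_gives_zero(self, default_blood_tac):
        zero = Tac(default_blood_tac.schedule, np.zeros(default_blood_tac.activity.size))
        assert fractional_extraction(zero, default_blood_tac) == 0.0

    def test_round_trip_recovers_published_extraction_rate(self, default_blood_tac):
        tissue = tissue_tac(default_blood_tac, true_ge=0.013)
        ge = fractional_extraction(tissue, default_blood_tac)
        assert ge == pytest.approx(0.013, rel=0.01)

    def test_noise_free_recovery_under_one_percent_over_grid(self, default_blood_tac):
        for true_ge in [0.001, 0.002, 0.005, 0.008, 0.012, 0.016, 0.02]:
            tissue = tissue_tac(default_blood_tac, true_ge)
            ge = fractional_extraction(tissue, default_blood_tac)
            assert abs(ge - true_ge) / true_ge < 0.01

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, default_blood_tac, scale):
        tissue = tissue_tac(default_blood_tac, 0.01)
        base = fractional_extraction(tissue, default_blood_tac)
        scaled = fractional_extraction(
            Tac(tissue.schedule, tissue.activity * scale),
            Tac(default_blood_tac.schedule, default_blood_tac.activity * scale),
        )
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_empty_window_fails(self, default_blood_tac):
        tissue = tissue_tac(default_blood_tac, 0.01)
        with pytest.raises(ValueError, match="window"):
            fractional_extraction(
                tissue, default_blood_tac, SteadyPhaseRule(57.9, 58.0)
            )

    def test_zero_blood_is_invalid_input_function(self, default_schedule):
        zero = Tac(default_schedule, np.zeros(default_schedule.n_frames), "blood")
        tissue = Tac(default_schedule, np.ones(default_schedule.n_frames), "SAT")
        with pytest.raises(ValueError, match="invalid input function"):
            fractional_extraction(tissue, zero)

    def test_mismatched_schedules_rejected(self, default_blood_tac):
        other = _fine_schedule(dt=1.0)
        with pytest.raises(ValueError, match="schedule"):
            fractional_extraction(
                Tac(other, np.ones(other.n_frames)), default_blood_tac
            )


class TestNoisyRecovery:
    def test_median_bias_under_five_percent_with_five_percent_noise(
        self, default_blood_tac
    ):
        rng = np.random.default_rng(42)
        errors = []
        for true_ge in [0.002, 0.005, 0.013, 0.02]:
            for _ in range(100):
                tissue = tissue_tac(default_blood_tac, true_ge, noise_sd=0.05, rng=rng)
                ge = fractional_extraction(tissue, default_blood_tac)
                errors.append(abs(ge - true_ge) / true_ge)
        assert np.median(errors) < 0.05


class TestDerivedQuantities:
    def test_uptake_from_published_example(self):
        # GE 0.013 min^-1 at scan glycemia 7.2 mmol/L -> 9.36 ~ 9.4 umol/min/100 g
        assert glucose_uptake(0.013, 7.2) == pytest.approx(9.36)

    def test_uptake_linear_in_glycemia(self):
        assert glucose_uptake(0.01, 10.0) == 2 * glucose_uptake(0.01, 5.0)
        assert glucose_uptake(0.0, 5.0) == 0.0

    def test_uptake_rejects_nonpositive_glycemia(self):
        with pytest.raises(ValueError):
            glucose_uptake(0.01, 0.0)

    @pytest.mark.parametrize(
        "weight,age,expected",
        [(38, "6mo", 0.76), (18, "1mo", 0.27), (27, "adult", 0.54), (100, "6mo", 2.0)],
    )
    def test_sat_mass_fractions(self, weight, age, expected):
        assert sat_mass(weight, age) == pytest.approx(expected)

    def test_sat_mass_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sat_mass(0, "6mo")
        with pytest.raises(ValueError, match="age group"):
            sat_mass(30, "12mo")

    @pytest.mark.parametrize(
        "gu,mass,expected",
        [(2.1, 0.51, 0.01071), (1.9, 0.26, 0.00494), (0.0, 0.5, 0.0)],
    )
    def test_whole_depot_scaling(self, gu, mass, expected):
        assert whole_depot_gu(gu, mass) == pytest.approx(expected, abs=1e-6)

    def test_ratio_mean_of_per_animal_ratios(self):
        assert bat_sat_ratio(3.0, 3.0) == 1.0
        assert group_bat_sat_ratio([2.0, 4.0]) == 3.0

    def test_zero_sat_gu_flagged_missing(self):
        assert np.isnan(bat_sat_ratio(2.0, 0.0))
        assert group_bat_sat_ratio([np.nan, 2.0, 4.0]) == 3.0

    def test_exact_identities_to_machine_precision(self):
        ge, gly, weight = 0.0123456789, 7.654321, 33.33
        gu = glucose_uptake(ge, gly)
        mass = sat_mass(weight, "6mo")
        assert gu == ge * gly * 100.0
        assert whole_depot_gu(gu, mass) == gu * mass / 100.0
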