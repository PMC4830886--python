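"""Transwell kinetics: sampling correction, rates, Papp, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtoxrank.transport import (
    TranswellConfig,
    TransportTimeCourse,
    corrected_cumulative_amounts,
    estimate_appearance_rate,
    intracellular_accumulation_percent,
    mass_balance,
    papp_coefficient,
    relative_papp,
    summarize_transport,
)


def tc(concs, times=None, **kw):
    times = times if times is not None else 15.0 * np.arange(1, len(concs) + 1)
    return TransportTimeCourse("x", "r1", np.asarray(times), np.asarray(concs), **kw)


class TestCorrectedAmounts:
    @pytest.mark.parametrize(
        "concs, expected",
        [
            ([1.0], [1.5]),
            ([1.0, 1.8], [1.5, 2.9]),
            ([2.0, 2.0, 2.0], [3.0, 3.4, 3.8]),
        ],
    )
    def test_hand_computed_series(self, cfg, concs, expected):
        np.testing.assert_allclose(
            corrected_cumulative_amounts(tc(concs), cfg), expected
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tc([1.0, -0.1])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            tc([])

    @given(
        increments=st.lists(
            st.floats(0.0, 5.0, allow_nan=False), min_size=1, max_size=12
        ),
        vb=st.floats(0.5, 5.0),
        vs=st.floats(0.05, 0.4),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_event_by_event_bookkeeping(self, increments, vb, vs):
        """The closed-form correction equals an explicit simulator that
        tracks every withdrawal and buffer replacement: measured
        concentrations are generated from arbitrary true transport
        increments, and the corrected amounts must recover the true
        cumulative transported mass exactly."""
        vs = min(vs, 0.9 * vb)
        cfg = TranswellConfig(basolateral_volume_ml=vb, sample_volume_ml=vs)
        mass = 0.0
        measured, truth = [], []
        total = 0.0
        for inc in increments:
            mass += inc
            total += inc
            c = mass / vb
            measured.append(c)
            truth.append(total)
            mass -= c * vs  # aliquot withdrawn, blank buffer replaces volume
        got = corrected_cumulative_amounts(tc(measured), cfg)
        np.testing.assert_allclose(got, truth, rtol=1e-12, atol=1e-12)


class TestAppearanceRate:
    def test_single_point_is_unit_conversion(self, cfg):
        amounts = [1.5, 3.6]
        assert estimate_appearance_rate(amounts, [15, 30], 30) == pytest.approx(
            3.6 / 1800
        )

    @pytest.mark.parametrize("mode", ["single_point", "ols"])
    def test_exact_on_noiseless_line(self, mode):
        r = 0.002  # nmol/s
        times = np.array([15.0, 30.0, 60.0])
        amounts = r * times * 60.0
        assert estimate_appearance_rate(amounts, times, 30, mode) == pytest.approx(r)

    def test_ols_matches_closed_form(self):
        t = np.array([15.0, 30.0]) * 60.0
        q = np.array([1.5, 2.9])
        expected = np.sum(t * q) / np.sum(t**2)
        got = estimate_appearance_rate([1.5, 2.9], [15, 30], 30, "ols")
        assert got == pytest.approx(expected)

    def test_window_must_be_a_sample_time(self):
        with pytest.raises(ValueError, match="available times"):
            estimate_appearance_rate([1.0, 2.0], [15, 30], 45)


class TestPapp:
    def test_zero_rate(self, cfg):
        assert papp_coefficient(0.0, cfg) == 0.0

    def test_dimensional_hand_calculation(self, cfg):
        # 2.179e-3 nmol/s over 1.12 cm2 at 50 uM (= 50 nmol/cm3)
        assert papp_coefficient(2.179e-3, cfg) == pytest.approx(38.9e-6, rel=5e-3)

    def test_doubling_c0_halves_papp(self):
        lo = TranswellConfig(initial_apical_concentration_um=50.0)
        hi = TranswellConfig(initial_apical_concentration_um=100.0)
        assert papp_coefficient(1e-3, hi) == pytest.approx(
            papp_coefficient(1e-3, lo) / 2
        )

    def test_scaling_concentrations_and_c0_together_is_invariant(self, cfg):
        """Papp is homogeneous of degree zero in (concentrations, C0)."""
        concs = np.array([1.0, 1.8, 3.0, 4.0])
        for scale in (0.1, 10.0):
            cfg2 = TranswellConfig(
                initial_apical_concentration_um=cfg.initial_apical_concentration_um
                * scale
            )
            q1 = corrected_cumulative_amounts(tc(concs), cfg)
            q2 = corrected_cumulative_amounts(tc(concs * scale), cfg2)
            p1 = papp_coefficient(estimate_appearance_rate(q1, [15, 30, 45, 60], 30), cfg)
            p2 = papp_coefficient(estimate_appearance_rate(q2, [15, 30, 45, 60], 30), cfg2)
            assert p2 == pytest.approx(p1, rel=1e-12)

    def test_relative_papp_reference_is_identity(self):
        assert relative_papp(38.9e-6, 38.9e-6) == 1.0

    def test_relative_papp_requires_positive_reference(self):
        with pytest.raises(ValueError, match="reference"):
            relative_papp(1e-6, 0.0)


class TestMassBalance:
    def test_full_conservation_all_apical(self, cfg):
        course = tc(
            [0.0],
            final_apical_concentration_um=50.0,
            cell_associated_amount_nmol=0.0,
        )
        percent, flags = mass_balance(course, cfg)
        assert percent == pytest.approx(100.0)
        assert flags == []

    def test_hand_summed_recovery(self, cfg):
        # apical 17.5 nmol (35 uM x 0.5 ml) + corrected basolateral 3.75 + cells 2.5
        course = tc(
            [2.5],
            final_apical_concentration_um=35.0,
            cell_associated_amount_nmol=2.5,
        )
        percent, _ = mass_balance(course, cfg)
        assert percent == pytest.approx(95.0)

    def test_out_of_window_flagged_not_dropped(self, cfg):
        course = tc(
            [0.0],
            final_apical_concentration_um=42.5,  # 21.25/25 = 85 %
            cell_associated_amount_nmol=0.0,
        )
        percent, flags = mass_balance(course, cfg, acceptance_window=(90, 110))
        assert percent == pytest.approx(85.0)
        assert len(flags) == 1 and "outside acceptance window" in flags[0]

    def test_missing_terminal_measurements_listed(self, cfg):
        with pytest.raises(ValueError, match="cell_associated_amount_nmol"):
            mass_balance(tc([1.0], final_apical_concentration_um=40.0), cfg)


class TestAccumulation:
    @pytest.mark.parametrize(
        "amount, expected", [(0.0, 0.0), (5.0, 20.0), (19.75, 79.0)]
    )
    def test_percent_of_added(self, cfg, amount, expected):
        assert intracellular_accumulation_percent(amount, cfg) == pytest.approx(expected)


class TestSummarize:
    def test_reference_relative_papp_exactly_one_and_table_shape(self, cfg):
        courses = [
            TransportTimeCourse("ref", f"r{i}", [15, 30], [c, 2 * c])
            for i, c in enumerate([1.0, 1.1, 0.9])
        ] + [TransportTimeCourse("slow", "r1", [15, 30], [0.2, 0.4])]
        table = summarize_transport(courses, cfg, reference_compound="ref")
        assert table.loc["ref", "relative_papp"] == 1.0
        assert 0 < table.loc["slow", "relative_papp"] < 1
        assert table.loc["ref", "n_replicates"] == 3

    def test_missing_reference_is_an_error(self, cfg):
        courses = [TransportTimeCourse("a", "r1", [15, 30], [1.0, 2.0])]
        with pytest.raises(ValueError, match="antipyrine"):
            summarize_transport(courses, cfg)
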