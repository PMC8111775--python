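"""Organelle statistics, division-corrected rates and phase detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidtraj.errors import ArgumentError, PlastidTrajError
from plastidtraj.trajectory import (
    chloroplast_index,
    compute_trajectory,
    cumulative_division_rounds,
    detect_phases,
    division_rate,
    growth_rate,
    reference_trajectory,
    summarize_cells,
)


def _cells(sample_id, areas, counts, plastid_areas, replicate=1):
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "replicate": replicate,
            "cell_id": [f"c{i}" for i in range(len(areas))],
            "cell_area": areas,
            "plastid_count": counts,
            "mean_plastid_area": plastid_areas,
        }
    )


class TestSummarizeCells:
    def test_identical_cells_have_zero_iqr(self):
        table = _cells([1] * 48, [100.0] * 48, [10] * 48, [5.0] * 48)
        out = summarize_cells(table)
        assert out.loc[1, "cell_area_median"] == 100.0
        assert out.loc[1, "cell_area_q3"] - out.loc[1, "cell_area_q1"] == 0.0

    def test_median_of_consecutive_areas(self):
        areas = list(range(1, 49))
        table = _cells([1] * 48, areas, [10] * 48, [5.0] * 48)
        assert summarize_cells(table).loc[1, "cell_area_median"] == 24.5

    def test_missing_sample_is_named_in_error(self):
        table = _cells([1] * 6, [10.0] * 6, [4] * 6, [2.0] * 6)
        with pytest.raises(PlastidTrajError, match="sample 7 has no cells"):
            summarize_cells(table, expected_samples=[1, 7])

    def test_total_area_identity_holds_exactly(self, experiment):
        out = summarize_cells(experiment.cells)
        assert np.array_equal(out["A"].to_numpy(), (out["N"] * out["a"]).to_numpy())


class TestRates:
    def test_two_rounds_in_a_third_of_a_day(self):
        # corrected four-fold multiplication over 8 h = 6 rounds/day
        assert division_rate(10.0, 40.0, 1.0, 0.0, 1.0 / 3.0) == pytest.approx(6.0)

    def test_unchanged_counts_without_division(self):
        assert division_rate(30.0, 30.0, 1.0, 0.0, 0.5) == 0.0

    def test_halving_offset_by_cell_doubling(self):
        assert division_rate(30.0, 15.0, 2.0, 0.0, 0.5) == 0.0

    def test_late_decline_is_negative_not_clipped(self):
        assert division_rate(50.0, 45.0, 1.0, 0.0, 1.0) < 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ArgumentError):
            division_rate(0.0, 10.0, 1.0, 0.0, 1.0)
        with pytest.raises(ArgumentError):
            division_rate(10.0, 20.0, 1.0, 1.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_under_uniform_count_rescaling(self, scale):
        base = division_rate(8.0, 20.0, 1.5, 0.0, 0.4)
        scaled = division_rate(8.0 * scale, 20.0 * scale, 1.5, 0.0, 0.4)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_growth_rate_doubling_in_one_day(self):
        assert growth_rate(100.0, 200.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_growth_rate_constant_area_with_division(self):
        assert growth_rate(100.0, 100.0, 2.0, 0.0, 0.5) == pytest.approx(2.0)

    def test_growth_rate_halving_offset_by_division(self):
        assert growth_rate(100.0, 50.0, 2.0, 0.0, 0.7) == 0.0


class TestCumulativeRounds:
    def test_reference_fixture_lies_in_four_to_five_band(self):
        fixture = reference_trajectory().set_index("point")
        rounds = cumulative_division_rounds(
            fixture.loc["basal", "plastid_count"],
            fixture.loc["peak", "plastid_count"],
            fixture.loc["peak", "cumulative_correction"],
        )
        assert rounds == pytest.approx(np.log2(18.0))
        assert 4.0 <= rounds <= 5.0

    def test_no_change_no_correction(self):
        assert cumulative_division_rounds(20.0, 20.0, 1.0) == 0.0

    def test_maintenance_divisions(self):
        # constant counts in a doubling population = one maintenance round
        assert cumulative_division_rounds(20.0, 20.0, 2.0) == 1.0


class TestChloroplastIndex:
    def test_half_occupancy(self):
        assert chloroplast_index(100.0, 25.0, 5000.0) == pytest.approx(0.5)

    def test_single_plastid_filling_the_cell(self):
        assert chloroplast_index(1.0, 400.0, 400.0) == 1.0

    def test_zero_count_rejected(self):
        with pytest.raises(ArgumentError):
            chloroplast_index(0.0, 10.0, 100.0)
        with pytest.raises(ArgumentError):
            chloroplast_index(10.0, 10.0, 0.0)


class TestDetectPhases:
    def test_planted_trough_is_found(self):
        series = [3.0, 5.0, 4.0, 2.0, 1.0, 0.4, 0.1, 0.3, 1.0, 1.8, 1.2]
        split = detect_phases(series, smooth=False)
        assert split.transition == 6
        assert split.plastid == tuple(range(6))
        assert split.chloroplast == tuple(range(7, 11))

    def test_monotone_series_has_no_biphasic_structure(self):
        with pytest.raises(PlastidTrajError, match="no biphasic structure"):
            detect_phases([5.0, 4.0, 3.0, 2.0, 1.0], smooth=False)

    def test_equal_minima_resolve_to_earlier_index(self):
        series = [1.0, 4.0, 0.5, 1.0, 0.5, 4.0, 1.0]
        assert detect_phases(series, smooth=False).transition == 2

    def test_short_series_rejected(self):
        with pytest.raises(ArgumentError):
            detect_phases([1.0, 0.1, 1.0])


class TestLineageOracle:
    """division_rate must agree with an explicit cell/plastid simulation."""

    def _simulate(self, rng, n_cells, n_start, rate, c, dt):
        counts = np.full(n_cells, n_start, dtype=float)
        # every plastid lineage multiplies by 2^(rate*dt) in expectation
        fold = 2.0 ** (rate * dt)
        counts = rng.binomial(np.round(counts * 8).astype(int), fold / 8.0)
        # a fraction (c-1) of cells divides once, halving its counts
        dividing = rng.random(n_cells) < (c - 1.0)
        daughters = rng.binomial(counts[dividing].astype(int), 0.5)
        mothers = counts[dividing] - daughters
        survived = np.concatenate([counts[~dividing], daughters, mothers])
        return survived.mean()

    def test_rate_formula_matches_brute_force_lineages(self):
        rng = np.random.default_rng(7)
        n_start, true_rate, c, dt = 24, 2.0, 1.6, 0.5
        estimates = []
        for _ in range(30):
            mean_after = self._simulate(rng, 1000, n_start, true_rate, c, dt)
            estimates.append(division_rate(n_start, mean_after, c, 0.0, dt))
        # Monte-Carlo error of the mean over 30 runs of 1000 cells
        assert np.mean(estimates) == pytest.approx(true_rate, abs=0.05)


class TestTrajectoryRecovery:
    def test_phase_boundary_and_rounds_recovered(self, experiment):
        result = compute_trajectory(
            experiment.cells, experiment.cell_cycle, experiment.samples
        )
        truth = experiment.ground_truth
        assert abs(result["transition_sample"] - truth.phase_boundary_transition) <= 1
        assert result["plastid_phase_division_rounds"] == pytest.approx(
            truth.organelle_rounds_total, abs=0.3
        )

    def test_phase_labels_partition_samples(self, experiment):
        result = compute_trajectory(
            experiment.cells, experiment.cell_cycle, experiment.samples
        )
        phases = result["summary"]["phase"]
        assert set(phases.unique()) == {"plastid", "transition", "chloroplast"}
        assert (phases == "transition").sum() == 1
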