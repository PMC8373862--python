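import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digitcoord import (
    circular_distance,
    circular_median,
    coordination_difference,
    coordination_difference_from_phases,
    per_pair_table,
    relative_phase,
    typical_pattern,
)
from digitcoord.coordination import CoordinationPattern, trial_pair_phases
from digitcoord.kinematics import PeakTrain, trial_peak_trains
from digitcoord.preprocess import preprocess_trial
from digitcoord.trajio import PAIR_COLUMNS
from tests.conftest import make_sine_trial


def _train(digit, times):
    return PeakTrain(digit, np.asarray(times, dtype=float))


class TestRelativePhase:
    @pytest.mark.parametrize(
        "h_times,expected",
        [
            ([0.5, 1.5], [0.5, 0.5]),       # antiphase
            ([0.0, 1.0], [0.0, 0.0]),       # coincident peaks, in phase
            ([0.25, 1.25], [0.25, 0.25]),   # quarter-cycle lag
        ],
    )
    def test_canonical_phase_anchors(self, h_times, expected):
        res = relative_phase(_train("thumb", [0, 1, 2]), _train("index", h_times))
        np.testing.assert_allclose(res.phi_values, expected)

    def test_ambiguous_cycles_dropped_not_resolved(self):
        # second reference cycle holds two index peaks, third holds none
        res = relative_phase(
            _train("thumb", [0.0, 1.0, 2.0, 3.0]),
            _train("index", [0.5, 1.2, 1.8]),
        )
        np.testing.assert_allclose(res.phi_values, [0.5])
        assert res.n_dropped_cycles == 2

    def test_too_few_reference_peaks_gives_empty_series(self):
        res = relative_phase(_train("thumb", [0.5]), _train("index", [0.2]))
        assert res.phi_values.size == 0

    @given(
        offset=st.floats(0.01, 0.99),
        period=st.floats(0.3, 1.2),
        n=st.integers(3, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_phase_of_constant_lag_is_lag_over_period(self, offset, period, n):
        ref = np.arange(n) * period
        other = ref[:-1] + offset * period
        res = relative_phase(_train("thumb", ref), _train("index", other))
        assert res.phi_values.size == n - 1
        np.testing.assert_allclose(res.phi_values, offset, atol=1e-9)
        assert ((res.phi_values >= 0) & (res.phi_values < 1)).all()


class TestCircularStatistics:
    def test_median_equals_linear_median_away_from_seam(self):
        assert circular_median([0.2, 0.3, 0.4]) == pytest.approx(0.3)

    def test_median_across_the_seam(self):
        assert circular_median([0.95, 0.00, 0.05]) == pytest.approx(0.0)

    def test_single_value(self):
        assert circular_median([0.7]) == pytest.approx(0.7)

    def test_even_count_midpoint_convention(self):
        pooled = [0.2, 0.2, 0.2, 0.4, 0.4, 0.4]
        assert circular_median(pooled) == pytest.approx(0.3)

    @given(
        center=st.floats(0, 1),
        spread=st.floats(0.01, 0.2),
        n=st.integers(1, 25),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_median_minimises_circular_distance_sum(self, center, spread, n, seed):
        """Brute-force oracle: no grid candidate beats the returned median."""
        rng = np.random.default_rng(seed)
        vals = (center + rng.uniform(-spread, spread, n)) % 1.0
        med = circular_median(vals)
        assert 0 <= med < 1
        cost = circular_distance(vals, med).sum()
        grid = np.linspace(0, 1, 2001, endpoint=False)
        best = circular_distance(vals[:, None], grid[None, :]).sum(axis=0).min()
        assert cost <= best + 1e-6

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_distance_symmetric_and_bounded(self, a, b):
        d1 = circular_distance(a, b)
        d2 = circular_distance(b, a)
        assert d1 == pytest.approx(d2)
        assert 0 <= d1 <= 0.5
        assert circular_distance(a, a) == pytest.approx(0.0)


def _pattern(values):
    return CoordinationPattern(
        context=("p", 1, 1, "BRT"),
        pair_medians=dict(zip(PAIR_COLUMNS, values)),
    )


class TestCoordinationDifference:
    def test_identical_phases_give_zero_difference(self):
        typical = _pattern([0.1 * i % 1 for i in range(10)])
        phases = {k: np.full(5, v) for k, v in typical.pair_medians.items()}
        diff = coordination_difference_from_phases(phases, typical)
        assert diff.mean_diff == pytest.approx(0.0)

    def test_seam_crossing_pair_uses_circular_distance(self):
        typical = _pattern([0.95] + [0.2] * 9)
        phases = {k: np.full(4, v) for k, v in typical.pair_medians.items()}
        phases["d1_d2"] = np.full(4, 0.05)
        diff = coordination_difference_from_phases(phases, typical)
        assert diff.pair_diffs["d1_d2"] == pytest.approx(0.10)
        assert diff.mean_diff == pytest.approx(0.01)

    def test_linear_mode_breaks_phase_topology(self):
        typical = _pattern([0.95] + [0.2] * 9)
        phases = {k: np.full(4, v) for k, v in typical.pair_medians.items()}
        phases["d1_d2"] = np.full(4, 0.05)
        diff = coordination_difference_from_phases(phases, typical, circular=False)
        assert diff.pair_diffs["d1_d2"] == pytest.approx(0.90)

    def test_missing_pair_dropped_with_record(self):
        typical = _pattern([0.3] * 10)
        phases = {k: np.full(3, 0.3) for k in PAIR_COLUMNS}
        phases["d4_d5"] = np.empty(0)
        diff = coordination_difference_from_phases(phases, typical)
        assert diff.dropped_pairs == ["d4_d5"]
        assert len(diff.pair_diffs) == 9

    @given(shift=st.floats(0, 1), seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_seam_invariance_under_common_rotation(self, shift, seed):
        """Rotating all phases (REP and typical alike) changes nothing."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 1, 10)
        typical = _pattern(base)
        phases = {
            k: (v + rng.normal(0, 0.05, 6)) % 1.0
            for k, v in typical.pair_medians.items()
        }
        d0 = coordination_difference_from_phases(phases, typical)
        typical2 = _pattern((base + shift) % 1.0)
        phases2 = {k: (v + shift) % 1.0 for k, v in phases.items()}
        d1 = coordination_difference_from_phases(phases2, typical2)
        for k in PAIR_COLUMNS:
            assert d1.pair_diffs[k] == pytest.approx(d0.pair_diffs[k], abs=1e-9)


class TestTypicalPattern:
    def test_constant_phase_trial_gives_that_median(self):
        trial = make_sine_trial(phase_offsets=(0, 0.3, 0.5, 0.7, 0.9), noise_sd=0.0)
        peaks = trial_peak_trains(preprocess_trial(trial))
        pattern = typical_pattern([peaks])
        assert pattern.complete
        # thumb leads index by 0.3 cycles -> recovered pair phase (0 - 0.3) mod 1
        assert pattern.pair_medians["d1_d2"] == pytest.approx(0.7, abs=0.01)

    def test_pooled_even_count_uses_circular_midpoint(self):
        t1 = {"thumb": _train("thumb", [0, 1, 2, 3]),
              "index": _train("index", [0.2, 1.2, 2.2])}
        t2 = {"thumb": _train("thumb", [0, 1, 2, 3]),
              "index": _train("index", [0.4, 1.4, 2.4])}
        for d in ("middle", "ring", "little"):
            t1[d] = _train(d, [0.5, 1.5, 2.5])
            t2[d] = _train(d, [0.5, 1.5, 2.5])
        pattern = typical_pattern([t1, t2])
        assert pattern.pair_medians["d1_d2"] == pytest.approx(0.3)

    def test_self_difference_is_zero_for_noiseless_block(self):
        trials = [make_sine_trial(noise_sd=0.0) for _ in range(3)]
        peak_sets = [trial_peak_trains(preprocess_trial(t)) for t in trials]
        typical = typical_pattern(peak_sets)
        diff = coordination_difference(peak_sets, typical, context=("p", 1, 1))
        assert diff.mean_diff < 1e-3

    def test_recovers_generator_pair_offsets(self):
        offsets = (0.0, 0.15, 0.35, 0.55, 0.8)
        trials = [make_sine_trial(phase_offsets=offsets, noise_sd=0.05, seed=s) for s in range(3)]
        peak_sets = [trial_peak_trains(preprocess_trial(t)) for t in trials]
        pattern = typical_pattern(peak_sets)
        offs = dict(zip(("thumb", "index", "middle", "ring", "little"), offsets))
        from digitcoord.trajio import PAIRS, pair_label
        for f, h in PAIRS:
            truth = (offs[f] - offs[h]) % 1.0
            from digitcoord import circular_distance
            assert circular_distance(pattern.pair_medians[pair_label(f, h)], truth) < 0.02


class TestPerPairTable:
    def test_reshape_identity_and_column_count(self):
        typical = _pattern([0.3] * 10)
        phases = {k: np.full(3, 0.35) for k in PAIR_COLUMNS}
        diff = coordination_difference_from_phases(phases, typical, context=("p1", 1, 2))
        table = per_pair_table([diff])
        assert len(table) == 1
        assert list(table.columns[4:]) == list(PAIR_COLUMNS)
        assert len(PAIR_COLUMNS) == 10
        row = table.iloc[0]
        assert row["coord_diff"] == pytest.approx(diff.mean_diff)
        for k in PAIR_COLUMNS:
            assert row[k] == pytest.approx(diff.pair_diffs[k])
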