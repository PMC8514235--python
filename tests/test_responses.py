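"""Calcium-response indices: z-score, ON-OFF, DSI/OSI, QI, cosine grouping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retinotype.core import TrialResponse
from retinotype.responses import (
    TuningCurve,
    assign_groups,
    average_trials,
    cosine_similarity,
    direction_selectivity,
    epoch_mean,
    group_mean,
    on_off_index,
    orientation_selectivity,
    peak_by_direction,
    quality_index,
    zscore_trace,
)


def brute_force_index(angles_deg, resp, harmonic):
    """Independent oracle: direct complex summation, plain Python floats."""
    import cmath
    import math

    z = 0 + 0j
    total = 0.0
    for a, r in zip(angles_deg, resp):
        z += r * cmath.exp(1j * harmonic * math.radians(a))
        total += r
    return abs(z) / total, math.degrees(cmath.phase(z))


EIGHT = np.arange(0.0, 360.0, 45.0)


class TestZScore:
    def trace(self, values, rate=10.0):
        return TrialResponse(values, rate, {"baseline": (0.0, 1.0), "stim": (1.0, 2.0)})

    def test_baseline_mean_maps_to_zero_and_sd_to_units(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5.0, 2.0, 10)
        values = np.concatenate([base, np.full(10, base.mean() + 2 * base.std())])
        z = zscore_trace(self.trace(values))
        assert epoch_mean(z, "stim") == pytest.approx(2.0)
        assert epoch_mean(z, "baseline") == pytest.approx(0.0, abs=1e-12)

    def test_large_sample_convergence(self):
        """With a long N(5, 2²) baseline, a sample at 9 scores z ≈ 2."""
        rng = np.random.default_rng(1)
        n = 100_000
        values = np.concatenate([rng.normal(5.0, 2.0, n), [9.0]])
        trial = TrialResponse(values, 1000.0, {"baseline": (0.0, n / 1000.0)})
        z = zscore_trace(trial)
        assert abs(z.values[-1] - 2.0) < 0.02

    def test_flat_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            zscore_trace(self.trace(np.ones(20)))


class TestEpochMean:
    def test_constant_and_single_sample(self):
        t = TrialResponse(
            np.concatenate([np.full(10, 3.0), [7.0]]),
            10.0,
            {"a": (0.0, 1.0), "b": (1.0, 1.1)},
        )
        assert epoch_mean(t, "a") == 3.0
        assert epoch_mean(t, "b") == 7.0

    def test_ramp_mean_is_half(self):
        values = np.linspace(0.0, 1.0, 101)
        t = TrialResponse(values, 100.0, {"ramp": (0.0, 1.01)})
        assert epoch_mean(t, "ramp") == pytest.approx(0.5, abs=0.01)

    def test_missing_epoch_raises(self):
        t = TrialResponse(np.ones(4), 1.0, {})
        with pytest.raises(KeyError):
            epoch_mean(t, "nope")


class TestOnOffIndex:
    @pytest.mark.parametrize(
        "on, off, expected", [(1.0, 0.0, 1.0), (2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (0.0, 1.0, -1.0)]
    )
    def test_values(self, on, off, expected):
        assert on_off_index(on, off) == pytest.approx(expected)

    def test_negative_responses_rectified(self):
        assert on_off_index(1.0, -5.0) == 1.0

    def test_unresponsive_cell_rejected(self):
        with pytest.raises(ValueError, match="unresponsive"):
            on_off_index(0.0, -1.0)


class TestPeakByDirection:
    def make_trials(self, peaks_by_trial):
        """Trials with one bar epoch per direction, peak injected mid-epoch."""
        rate = 10.0
        epochs = {"baseline": (0.0, 1.0)}
        n = 10 + 10 * len(EIGHT)
        trials = []
        for peaks in peaks_by_trial:
            values = np.zeros(n)
            for k, theta in enumerate(EIGHT):
                t0 = 1.0 + k
                epochs[f"bar_{theta:g}"] = (t0, t0 + 1.0)
                values[int(t0 * rate) + 5] = peaks[k]
            trials.append(TrialResponse(values, rate, dict(epochs)))
        return trials

    def test_single_peak_recovered(self):
        peaks = np.zeros(8)
        peaks[2] = 4.0  # 90° epoch
        tuning = peak_by_direction(self.make_trials([peaks]))
        assert tuning.responses[2] == 4.0
        assert np.all(tuning.responses[np.arange(8) != 2] == 0)

    def test_negative_epochs_rectify_to_zero(self):
        tuning = peak_by_direction(self.make_trials([np.full(8, -3.0)]))
        assert np.all(tuning.responses == 0)

    def test_average_then_max(self):
        """Two trials with peaks 2 and 4 at the same frame give Respθ = 3."""
        a = np.zeros(8)
        b = np.zeros(8)
        a[0], b[0] = 2.0, 4.0
        tuning = peak_by_direction(self.make_trials([a, b]))
        assert tuning.responses[0] == 3.0


class TestSelectivityIndices:
    def test_uniform_tuning_is_unselective(self):
        tuning = TuningCurve(EIGHT, np.ones(8))
        assert direction_selectivity(tuning).index < 1e-12
        assert orientation_selectivity(tuning).index < 1e-12

    def test_single_direction_is_perfectly_selective(self):
        resp = np.zeros(8)
        resp[2] = 5.0
        res = direction_selectivity(TuningCurve(EIGHT, resp))
        assert res.index == pytest.approx(1.0)
        assert res.preferred_angle == pytest.approx(90.0)

    def test_two_to_one_tuning_matches_closed_form(self):
        """Resp = [2,1,1,1,1,1,1,1]: the resultant is (2−1)/9 = 1/9 at 0°."""
        resp = np.array([2.0, 1, 1, 1, 1, 1, 1, 1])
        res = direction_selectivity(TuningCurve(EIGHT, resp))
        assert res.index == pytest.approx(1.0 / 9.0, abs=1e-12)
        assert res.preferred_angle % 360 == pytest.approx(0.0, abs=1e-9)

    def test_axial_tuning_perfect_osi_zero_dsi(self):
        resp = np.zeros(8)
        resp[0] = resp[4] = 1.0  # 0° and 180°
        osi = orientation_selectivity(TuningCurve(EIGHT, resp))
        assert osi.index == pytest.approx(1.0)
        assert osi.preferred_angle == pytest.approx(0.0, abs=1e-9)
        assert direction_selectivity(TuningCurve(EIGHT, resp)).index < 1e-12

    def test_orthogonal_pair_cancels_osi(self):
        resp = np.zeros(8)
        resp[0] = resp[2] = 1.0  # 0° and 90°: e^0 + e^{iπ} = 0
        assert orientation_selectivity(TuningCurve(EIGHT, resp)).index < 1e-12

    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        resp = rng.uniform(0.0, 10.0, 8)
        for harmonic, fn in [(1, direction_selectivity), (2, orientation_selectivity)]:
            res = fn(TuningCurve(EIGHT, resp))
            idx, _ = brute_force_index(EIGHT, resp, harmonic)
            assert abs(res.index - idx) < 1e-12

    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, factor):
        resp = np.random.default_rng(seed).uniform(0.0, 10.0, 8)
        a = direction_selectivity(TuningCurve(EIGHT, resp))
        b = direction_selectivity(TuningCurve(EIGHT, factor * resp))
        assert a.index == pytest.approx(b.index, abs=1e-12)

    @given(st.integers(0, 10_000), st.integers(1, 7))
    def test_rotation_equivariance(self, seed, shift):
        """Rotating the curve rotates the preferred angle, index unchanged."""
        resp = np.random.default_rng(seed).uniform(0.1, 10.0, 8)
        a = direction_selectivity(TuningCurve(EIGHT, resp))
        b = direction_selectivity(TuningCurve(EIGHT, np.roll(resp, shift)))
        assert b.index == pytest.approx(a.index, abs=1e-12)
        assert (b.preferred_angle - a.preferred_angle) % 360 == pytest.approx(
            45.0 * shift, abs=1e-6
        ) or a.index < 1e-9

    def test_all_zero_tuning_rejected(self):
        with pytest.raises(ValueError):
            direction_selectivity(TuningCurve(EIGHT, np.zeros(8)))


class TestQualityIndex:
    def test_identical_trials_score_one(self):
        trial = np.sin(np.linspace(0, 6, 100))
        m = np.tile(trial, (5, 1))
        assert quality_index(m) == pytest.approx(1.0)

    def test_white_noise_scores_one_over_n(self):
        n_trials, t = 20, 1000
        qis = [
            quality_index(np.random.default_rng(s).normal(size=(n_trials, t)))
            for s in range(200)
        ]
        se = np.std(qis, ddof=1) / np.sqrt(len(qis))
        assert abs(np.mean(qis) - 1.0 / n_trials) <= 3 * se

    def test_high_snr_approaches_one(self):
        rng = np.random.default_rng(0)
        signal = np.sin(np.linspace(0, 12, 400))
        m = signal + rng.normal(0, 1e-3, (10, 400))
        assert quality_index(m) > 0.99

    def test_flat_trials_rejected(self):
        with pytest.raises(ValueError):
            quality_index(np.ones((3, 10)))


class TestCosineGrouping:
    def test_similarity_extremes(self):
        a = np.array([1.0, 0.0, 2.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, -a) == pytest.approx(-1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_trace_equal_to_group_mean(self):
        means = np.random.default_rng(0).normal(size=(3, 50))
        labels, sim = assign_groups(means.copy(), means)
        np.testing.assert_array_equal(labels, [0, 1, 2])
        assert np.allclose(np.diag(sim), 1.0)

    def test_single_group_takes_all(self):
        traces = np.random.default_rng(1).normal(size=(6, 30))
        labels, _ = assign_groups(traces, traces[:1])
        assert np.all(labels == 0)

    def test_tie_broken_to_lowest_group(self):
        trace = np.array([[1.0, 0.0]])
        means = np.array([[1.0, 0.0], [1.0, 0.0]])
        labels, _ = assign_groups(trace, means)
        assert labels[0] == 0

    def test_labeled_mixture_recovered(self):
        """Four smooth templates + per-sample noise at 0.2× the signal norm."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 1, 200)
        templates = np.stack(
            [np.exp(-((t - c) ** 2) / 0.02) for c in (0.2, 0.4, 0.6, 0.8)]
        )
        templates /= np.linalg.norm(templates, axis=1, keepdims=True)
        correct = total = 0
        for s in range(100):
            rng_s = np.random.default_rng(s)
            truth = np.concatenate([np.arange(4), rng_s.integers(0, 4, 16)])
            traces = templates[truth] + rng_s.normal(0, 0.2, (20, 200)) / np.sqrt(200)
            means = np.stack(
                [group_mean(traces[truth == g]) for g in range(4)]
            )
            labels, _ = assign_groups(traces, means)
            correct += int(np.sum(labels == truth))
            total += truth.size
        assert correct / total >= 0.95


class TestAverageTrials:
    def test_mean_and_epoch_passthrough(self):
        a = TrialResponse(np.array([1.0, 3.0]), 1.0, {"e": (0.0, 1.0)})
        b = TrialResponse(np.array([3.0, 5.0]), 1.0, {"e": (0.0, 1.0)})
        avg = average_trials([a, b])
        np.testing.assert_array_equal(avg.values, [2.0, 4.0])
        assert avg.epochs == {"e": (0.0, 1.0)}
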