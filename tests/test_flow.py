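import numpy as np
import pytest

from beatkit import flow
from beatkit.errors import (
    GeometryError,
    InsufficientCyclesError,
    NoPeriodicityError,
    ValidationError,
)
from beatkit.io import MovieStack
from beatkit.synthetic import HeartSimConfig, simulate_brightfield_movie, synthetic_annotation


def make_kymograph(lines, spacing=1.0, frame_rate=240.0):
    return flow.Kymograph(values=np.asarray(lines, dtype=float),
                          sample_spacing=spacing, frame_rate=frame_rate)


class TestExtractKymograph:
    def test_uniform_movie_gives_constant_lines(self, bright_config):
        ann = synthetic_annotation(bright_config)
        pixels = np.full((5, *bright_config.image_size), 42.0, dtype=np.float32)
        movie = MovieStack(pixels=pixels, frame_rate=240.0, pixel_width=1.92)
        kym = flow.extract_kymograph(movie, ann)
        np.testing.assert_allclose(kym.values, 42.0, atol=1e-6)

    def test_window_past_heart_end_rejected(self, bright_movie):
        movie, _, ann = bright_movie
        with pytest.raises(GeometryError):
            flow.extract_kymograph(movie, ann, window_halfwidth=500.0)

    def test_kymograph_slope_follows_schedule(self, bright_movie):
        """Mean signed displacement flips sign exactly at schedule changes."""
        movie, truth, ann = bright_movie
        kym = flow.extract_kymograph(movie, ann)
        disp, _ = flow.estimate_frame_displacement(kym)
        cls = truth.per_frame_flow_class[:-1]
        assert disp[cls == "anterograde"].mean() > 0.5
        assert disp[cls == "retrograde"].mean() < -0.5
        assert abs(disp[cls == "no_flow"].mean()) < 0.3


class TestEstimateDisplacement:
    def test_integer_circular_shift_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 100, 64)
        lines = [base, np.roll(base, 3)]  # pattern moves +3 samples
        disp, conf = flow.estimate_frame_displacement(
            make_kymograph(lines, spacing=2.0), max_lag=12.0,
            smooth_sigma=0.0, temporal_sigma=0.0,
        )
        assert disp[0] == pytest.approx(6.0, abs=0.1)  # 3 samples x 2 um
        assert conf[0] > 0.95

    def test_fractional_shift_matches_fine_lag_oracle(self):
        """Parabolic refinement agrees with exhaustive fine-lag correlation."""
        rng = np.random.default_rng(2)
        coarse = rng.uniform(0, 100, 48)
        x = np.arange(48.0)
        shifted = np.interp(x - 1.5, x, coarse)  # content moves +1.5 samples
        kym = make_kymograph([coarse, shifted])
        disp, _ = flow.estimate_frame_displacement(
            kym, max_lag=10.0, smooth_sigma=0.0, temporal_sigma=0.0
        )

        # oracle: exhaustive normalized correlation on a 100x upsampled lag grid
        fine = np.linspace(-5, 5, 1001)
        scores = []
        inner = x[8:-8]
        for lag in fine:
            a = np.interp(inner - lag, x, coarse)
            b = np.interp(inner, x, shifted)
            scores.append(np.corrcoef(a, b)[0, 1])
        oracle = fine[int(np.argmax(scores))]
        assert disp[0] == pytest.approx(oracle, abs=0.25)
        assert disp[0] == pytest.approx(1.5, abs=0.25)

    def test_constant_lines_give_zero_confidence(self):
        disp, conf = flow.estimate_frame_displacement(
            make_kymograph([np.ones(32), np.ones(32)])
        )
        assert disp[0] == 0.0
        assert conf[0] == 0.0

    def test_max_lag_validation(self):
        kym = make_kymograph(np.zeros((3, 16)))
        with pytest.raises(ValidationError):
            flow.estimate_frame_displacement(kym, max_lag=0.2)
        with pytest.raises(ValidationError):
            flow.estimate_frame_displacement(kym, max_lag=100.0)


class TestClassifyFlow:
    @pytest.mark.parametrize(
        "disp_um_frame,expected",
        [
            (1.25, "anterograde"),  # 300 um/s at 240 fps
            (-1.25, "retrograde"),
            (0.2, "no_flow"),  # 48 um/s below the 115 um/s threshold
        ],
    )
    def test_sign_and_threshold_rules(self, disp_um_frame, expected):
        labels = flow.classify_flow_frames(
            np.array([disp_um_frame]), np.array([0.9]), frame_rate=240.0,
            speed_threshold=115.0,
        )
        assert labels.label[0] == expected

    def test_low_confidence_forces_no_flow(self):
        labels = flow.classify_flow_frames(
            np.array([2.0]), np.array([0.1]), frame_rate=240.0,
            speed_threshold=115.0, confidence_floor=0.3,
        )
        assert labels.label[0] == "no_flow"

    def test_no_flow_fraction_monotone_in_threshold(self, bright_movie):
        movie, _, ann = bright_movie
        kym = flow.extract_kymograph(movie, ann)
        disp, conf = flow.estimate_frame_displacement(kym)
        previous = -1.0
        for threshold in (30.0, 80.0, 115.0, 200.0, 400.0):
            labels = flow.classify_flow_frames(
                disp, conf, movie.frame_rate, speed_threshold=threshold
            )
            frac = np.mean(labels.label == "no_flow")
            assert frac >= previous
            previous = frac

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            flow.classify_flow_frames(
                np.array([1.0]), np.array([1.0]), 240.0, speed_threshold=0.0
            )


class TestDetectCycles:
    def test_simulated_movie_recovers_period_and_rate(self, bright_movie, bright_config):
        movie, truth, ann = bright_movie
        cycles = flow.detect_cycles(movie, ann)
        assert cycles.period_frames == pytest.approx(truth.period_frames, rel=0.02)
        rate = flow.heart_rate_bpm(cycles, movie.frame_rate)
        assert rate == pytest.approx(bright_config.beat_frequency * 60.0, rel=0.02)

    def test_constant_movie_has_no_periodicity(self, bright_config):
        ann = synthetic_annotation(bright_config)
        pixels = np.full((240, *bright_config.image_size), 7.0, dtype=np.float32)
        movie = MovieStack(pixels=pixels, frame_rate=240.0, pixel_width=1.92)
        with pytest.raises(NoPeriodicityError):
            flow.detect_cycles(movie, ann)

    def test_boundaries_near_true_diastole_frames(self, bright_movie):
        # diastole is a plateau of the diameter trace, so individual peak
        # positions carry ~10% of-period jitter; that only moves frames
        # between adjacent cycles when counting class fractions
        movie, truth, ann = bright_movie
        cycles = flow.detect_cycles(movie, ann)
        tolerance = 0.1 * truth.period_frames
        for boundary in cycles.boundaries[1:-1]:
            assert np.min(np.abs(truth.cycle_boundaries - boundary)) <= tolerance


class TestComputeProfile:
    def _labels(self, classes):
        n = len(classes)
        return flow.FrameFlowLabels(
            displacement=np.zeros(n), confidence=np.ones(n),
            label=np.asarray(classes, dtype="U11"),
            speed_threshold=115.0, frame_rate=240.0,
        )

    def test_single_cycle_percentages_count_frame_pairs(self):
        classes = ["anterograde"] * 70 + ["retrograde"] * 20 + ["no_flow"] * 10
        cycles = flow.CycleSet(boundaries=np.array([0, 100]), period_frames=100.0)
        profile = flow.compute_flow_profile(self._labels(classes), cycles, n_cycles=1)
        np.testing.assert_allclose(profile.per_cycle[0], [70.0, 20.0, 10.0])

    def test_average_over_three_cycles_is_arithmetic_mean(self):
        classes = (
            ["anterograde"] * 60 + ["retrograde"] * 30 + ["no_flow"] * 10
            + ["anterograde"] * 70 + ["retrograde"] * 20 + ["no_flow"] * 10
            + ["anterograde"] * 80 + ["retrograde"] * 10 + ["no_flow"] * 10
        )
        cycles = flow.CycleSet(boundaries=np.array([0, 100, 200, 300]),
                               period_frames=100.0)
        profile = flow.compute_flow_profile(self._labels(classes), cycles)
        np.testing.assert_allclose(profile.averaged, [70.0, 20.0, 10.0])

    def test_percentages_always_sum_to_100(self, bright_movie):
        movie, _, ann = bright_movie
        profile = flow.analyze_movie(movie, ann)
        for triple in profile.per_cycle:
            assert triple.sum() == pytest.approx(100.0, abs=1e-9)
        assert profile.averaged.sum() == pytest.approx(100.0, abs=1e-9)

    def test_insufficient_cycles_rejected(self):
        cycles = flow.CycleSet(boundaries=np.array([0, 100]), period_frames=100.0)
        with pytest.raises(InsufficientCyclesError):
            flow.compute_flow_profile(self._labels(["no_flow"] * 100), cycles, n_cycles=3)


class TestEndToEnd:
    def test_full_pipeline_recovers_schedule(self, bright_movie, bright_config):
        movie, truth, ann = bright_movie
        profile = flow.analyze_movie(movie, ann)
        assert np.abs(profile.averaged - truth.true_fractions).max() < 5.0
        assert profile.heart_rate == pytest.approx(
            bright_config.beat_frequency * 60.0, rel=0.02
        )

    def test_orientation_reversal_swaps_directions_exactly(self, bright_movie):
        movie, _, ann = bright_movie
        cycles = flow.detect_cycles(movie, ann)
        forward = flow.analyze_movie(movie, ann, cycles=cycles)
        reverse = flow.analyze_movie(movie, ann.reversed(), cycles=cycles)
        np.testing.assert_array_equal(forward.averaged, reverse.averaged[[1, 0, 2]])


class TestSummarize:
    def _profile(self, antero):
        rest = 100.0 - antero
        triple = np.array([antero, rest * 0.7, rest * 0.3])
        return flow.FlowProfile(per_cycle=triple[None, :], averaged=triple,
                                heart_rate=150.0, n_cycles_used=1)

    def test_known_values(self):
        summary = flow.summarize_profiles([self._profile(v) for v in (60, 70, 80)])
        row = summary[summary["flow_class"] == "anterograde"].iloc[0]
        assert row["median"] == 70.0
        assert row["mean"] == 70.0

    def test_single_profile_degenerate(self):
        summary = flow.summarize_profiles([self._profile(55.0)])
        row = summary[summary["flow_class"] == "anterograde"].iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 55.0

    def test_quartiles_match_hand_computed_tukey_hinges(self):
        # 5 values: median in both halves -> Q1 = median(10,20,30), Q3 = median(30,40,50)
        summary = flow.summarize_profiles(
            [self._profile(v) for v in (10, 20, 30, 40, 50)]
        )
        row = summary[summary["flow_class"] == "anterograde"].iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (20.0, 30.0, 40.0)
        # 4 values: halves (1,2) and (3,4)
        summary = flow.summarize_profiles([self._profile(v) for v in (1, 2, 3, 4)])
        row = summary[summary["flow_class"] == "anterograde"].iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (1.5, 2.5, 3.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            flow.summarize_profiles([])
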