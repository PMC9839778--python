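import numpy as np
import pytest

from beatkit import gcamp4d as g4d
from beatkit.errors import NoPeriodicityError, ValidationError
from beatkit.io import MovieStack
from beatkit.synthetic import (
    HeartSimConfig,
    simulate_gcamp_plane_series,
    synthetic_annotation,
)
from beatkit.validation import circular_distance


def gcamp_config(**overrides):
    base = dict(
        image_size=(96, 128), fluorescence_mode=True, frame_rate=50.0,
        n_frames=100, beat_frequency=2.5, peristalsis_phase_lag=0.0,
        noise_sd=6.0, seed=11,
    )
    base.update(overrides)
    return HeartSimConfig(**base)


@pytest.fixture(scope="module")
def small_series():
    config = gcamp_config()
    planes, truth = simulate_gcamp_plane_series(config, 16, 12.0, "random")
    return config, g4d.PlaneSeries(planes=planes, z_step=12.0), truth


class TestCommonPeriod:
    def test_recovers_beat_period(self, small_series):
        _, series, truth = small_series
        period, flagged = g4d.estimate_common_period(series)
        assert period == pytest.approx(20.0, rel=0.02)  # 50 fps / 2.5 Hz
        assert not flagged.any()

    def test_noise_plane_flagged_without_shifting_median(self, small_series):
        _, series, _ = small_series
        rng = np.random.default_rng(0)
        noisy = [
            MovieStack(pixels=p.pixels.copy(), frame_rate=p.frame_rate,
                       pixel_width=p.pixel_width)
            for p in series.planes
        ]
        noisy[5].pixels = rng.normal(50, 5, noisy[5].pixels.shape).astype(np.float32)
        period, flagged = g4d.estimate_common_period(
            g4d.PlaneSeries(planes=noisy, z_step=series.z_step)
        )
        assert flagged[5]
        assert period == pytest.approx(20.0, rel=0.02)

    def test_constant_planes_rejected(self):
        planes = [
            MovieStack(pixels=np.full((60, 16, 16), 3.0, dtype=np.float32),
                       frame_rate=50.0, pixel_width=1.92)
            for _ in range(4)
        ]
        with pytest.raises(NoPeriodicityError):
            g4d.estimate_common_period(g4d.PlaneSeries(planes=planes, z_step=4.0))


class TestPhaseOffsets:
    def test_zero_offsets_estimated_near_zero(self):
        config = gcamp_config(seed=21)
        planes, _ = simulate_gcamp_plane_series(
            config, 8, 24.0, phase_offsets=np.zeros(8)
        )
        series = g4d.PlaneSeries(planes=planes, z_step=24.0)
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        err = circular_distance(offsets.offset, 0.0, period)
        assert np.all(err <= 1.0)

    def test_constructed_circular_shift_recovered(self):
        config = gcamp_config(seed=31)
        planes, _ = simulate_gcamp_plane_series(
            config, 2, 80.0, phase_offsets=np.zeros(2)
        )
        base = planes[0]
        shifted = MovieStack(
            pixels=np.roll(base.pixels, 7, axis=0),
            frame_rate=base.frame_rate, pixel_width=base.pixel_width,
        )
        series = g4d.PlaneSeries(planes=[base, shifted], z_step=80.0)
        offsets = g4d.estimate_phase_offsets(series, 20.0)
        other = 1 - offsets.reference_plane
        # plane order may pick either as reference; the relative lag is 7
        expected = 7.0 if other == 1 else 13.0
        assert circular_distance(offsets.offset[other], expected, 20.0) <= 0.5

    def test_known_random_offsets_recovered(self, small_series):
        _, series, truth = small_series
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        expected = (
            truth.per_plane_phase_offset[offsets.reference_plane]
            - truth.per_plane_phase_offset
        ) % period
        err = circular_distance(offsets.offset, expected, period)
        assert np.all(err[~offsets.unalignable] <= 1.0)

    def test_realignment_is_idempotent(self, small_series):
        _, series, _ = small_series
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        aligned = g4d.assemble_and_project(series, offsets)
        realigned_planes = [
            MovieStack(pixels=aligned.volume[:, z], frame_rate=series.frame_rate,
                       pixel_width=series.planes[0].pixel_width)
            for z in range(aligned.volume.shape[1])
        ]
        second = g4d.estimate_phase_offsets(
            g4d.PlaneSeries(planes=realigned_planes, z_step=series.z_step), period
        )
        err = circular_distance(second.offset[~second.unalignable], 0.0, period)
        assert np.all(err <= 1.0)


class TestAssembly:
    def test_zero_offsets_keep_input(self, small_series):
        _, series, _ = small_series
        offsets = g4d.PhaseOffsets(
            offset=np.zeros(series.n_planes), reference_plane=0,
            period_frames=20.0, unalignable=np.zeros(series.n_planes, dtype=bool),
        )
        aligned = g4d.assemble_and_project(series, offsets)
        np.testing.assert_array_equal(aligned.volume[:, 3], series.planes[3].pixels)

    def test_single_usable_plane_projection_is_that_plane(self, small_series):
        _, series, _ = small_series
        unalignable = np.ones(series.n_planes, dtype=bool)
        unalignable[2] = False
        offsets = g4d.PhaseOffsets(
            offset=np.zeros(series.n_planes), reference_plane=2,
            period_frames=20.0, unalignable=unalignable,
        )
        aligned = g4d.assemble_and_project(series, offsets)
        np.testing.assert_array_equal(aligned.projection, series.planes[2].pixels)

    def test_projection_dominates_every_plane(self, small_series):
        _, series, _ = small_series
        offsets = g4d.PhaseOffsets(
            offset=np.zeros(series.n_planes), reference_plane=0,
            period_frames=20.0, unalignable=np.zeros(series.n_planes, dtype=bool),
        )
        aligned = g4d.assemble_and_project(series, offsets)
        for z in range(aligned.volume.shape[1]):
            assert np.all(aligned.projection >= aligned.volume[:, z])

    def test_all_flagged_rejected(self, small_series):
        _, series, _ = small_series
        offsets = g4d.PhaseOffsets(
            offset=np.zeros(series.n_planes), reference_plane=0,
            period_frames=20.0, unalignable=np.ones(series.n_planes, dtype=bool),
        )
        with pytest.raises(ValidationError):
            g4d.assemble_and_project(series, offsets)


class TestCardiacState:
    def _aligned(self, config, series, truth):
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        return g4d.assemble_and_project(series, offsets), offsets, period

    def test_diastole_systole_half_period_apart(self, small_series):
        config, series, truth = small_series
        aligned, _, period = self._aligned(config, series, truth)
        ann = synthetic_annotation(config)
        dia, sys_ = g4d.select_cardiac_state(aligned, ann)
        assert circular_distance(dia - sys_, period / 2, period) <= 1.5

    def test_selected_states_match_truth(self, small_series):
        config, series, truth = small_series
        aligned, offsets, period = self._aligned(config, series, truth)
        ann = synthetic_annotation(config)
        dia, sys_ = g4d.select_cardiac_state(aligned, ann)
        o_ref = truth.per_plane_phase_offset[offsets.reference_plane]
        assert circular_distance((dia + o_ref) % period, truth.diastole_frame, period) <= 1.0
        assert circular_distance((sys_ + o_ref) % period, truth.systole_frame, period) <= 1.0

    def test_flat_projection_rejected(self, small_series):
        config, series, _ = small_series
        ann = synthetic_annotation(config)
        aligned = g4d.AlignedVolumeSeries(
            volume=np.zeros((40, 2, *config.image_size), dtype=np.float32),
            projection=np.zeros((40, *config.image_size), dtype=np.float32),
            plane_indices=np.array([0, 1]),
            frame_rate=50.0, pixel_width=1.92, z_step=12.0,
        )
        with pytest.raises(NoPeriodicityError):
            g4d.select_cardiac_state(aligned, ann)


class TestCalciumProfile:
    def test_uniform_projection_has_flat_normalized_profile(self, small_series):
        config, series, _ = small_series
        ann = synthetic_annotation(config)
        aligned = g4d.AlignedVolumeSeries(
            volume=np.full((4, 1, *config.image_size), 50.0, dtype=np.float32),
            projection=np.full((4, *config.image_size), 50.0, dtype=np.float32),
            plane_indices=np.array([0]),
            frame_rate=50.0, pixel_width=1.92, z_step=12.0,
        )
        table = g4d.calcium_profile(aligned, ann, 0)
        inside = table["pixel_count"] > 0
        np.testing.assert_allclose(table.loc[inside, "normalized_intensity"], 1.0, atol=1e-9)

    def test_av_enrichment_peak_recovered(self, small_series):
        from beatkit.midline import detect_av_enrichment

        config, series, truth = small_series
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        aligned = g4d.assemble_and_project(series, offsets)
        ann = synthetic_annotation(config)
        dia, _ = g4d.select_cardiac_state(aligned, ann)
        table = g4d.calcium_profile(aligned, ann, dia)
        result = detect_av_enrichment(table)
        assert result["enriched"]
        # 12 um z-steps scallop the projection; the 4 um-step batteries in
        # the acceptance tests pin the ratio to 10%
        assert result["ratio"] == pytest.approx(config.av_enrichment, rel=0.15)
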