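"""Ground-truthed validation batteries for the full pipeline.

Each battery simulates a deterministic family of acquisitions spanning the
study conditions (flow schedules with anterograde 50-90%, retrograde
5-40%, no-flow 5-20%, speeds 50-600 um/s, noise up to 20% of the
brightfield contrast; 50-plane calcium series at period 20 frames with
noise up to 15%), runs the corresponding analysis end to end, and reports
per-run errors against the generator's ground truth. The batteries back
both the acceptance test suite and ``scripts/acceptance.py``.

The flow classification threshold is set per movie to half that movie's
slowest scheduled speed (floor 25 um/s): a threshold must sit below the
slowest true flow speed to be able to separate slow flow from no-flow.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import flow as flow_mod
from . import gcamp4d as g4d
from . import midline as midline_mod
from .synthetic import (
    HeartSimConfig,
    simulate_brightfield_movie,
    simulate_expression_stack,
    simulate_gcamp_plane_series,
    synthetic_annotation,
)


def circular_distance(a, b, period: float):
    """Distance between frame indices modulo the beat period."""
    return np.abs(((np.asarray(a) - np.asarray(b) + period / 2) % period) - period / 2)


def flow_battery_config(index: int, n_movies: int = 20, base_seed: int = 0) -> HeartSimConfig:
    """Deterministic brightfield config #index spanning the condition ranges.

    Anterograde fraction sweeps 50-90%, no-flow 5-20%, speeds 50-600 um/s
    (independently for the two directions), noise 0-20% of the
    lumen-to-wall contrast, beat frequency 2.2-3.0 Hz; each movie holds
    about 6.5 beats at 240 frames/s.
    """
    grid = lambda lo, hi, k: np.linspace(lo, hi, n_movies)[k % n_movies]
    antero = grid(50, 90, index)
    noflow = grid(5, 20, index * 7)
    retro = max(100.0 - antero - noflow, 5.0)
    total = antero + retro + noflow
    antero, retro, noflow = (100 * antero / total, 100 * retro / total, 100 * noflow / total)
    v_antero = grid(50, 600, index * 3)
    v_retro = grid(600, 50, index * 5)
    noise_frac = grid(0.0, 0.20, index * 11)
    beat = grid(2.2, 3.0, index * 13)
    schedule = (
        ((0.0, antero / 100), "anterograde", v_antero),
        ((antero / 100, (antero + retro) / 100), "retrograde", v_retro),
        (((antero + retro) / 100, 1.0), "no_flow", 0.0),
    )
    return HeartSimConfig(
        flow_schedule=schedule,
        noise_sd=noise_frac * 120.0,  # 120 = lumen-to-wall contrast
        beat_frequency=beat,
        n_frames=int(round(6.5 * 240.0 / beat)),
        seed=base_seed + index,
    )


def run_flow_battery(n_movies: int = 20, base_seed: int = 0) -> pd.DataFrame:
    """Simulate and analyze ``n_movies`` brightfield movies end to end.

    Returns one row per movie with the true and recovered flow fractions,
    the maximal fraction error (percentage points), and the relative
    heart-rate error.
    """
    rows = []
    for i in range(n_movies):
        config = flow_battery_config(i, n_movies, base_seed)
        movie, truth = simulate_brightfield_movie(config)
        annotation = synthetic_annotation(config)
        min_speed = min(v for (_, _), cls, v in config.schedule_entries() if v > 0)
        threshold = max(0.5 * min_speed, 25.0)
        profile = flow_mod.analyze_movie(movie, annotation, speed_threshold=threshold)
        true_rate = config.beat_frequency * 60.0
        rows.append(
            {
                "movie": i,
                "true_anterograde": truth.true_fractions[0],
                "true_retrograde": truth.true_fractions[1],
                "true_no_flow": truth.true_fractions[2],
                "est_anterograde": profile.averaged[0],
                "est_retrograde": profile.averaged[1],
                "est_no_flow": profile.averaged[2],
                "max_fraction_error": float(
                    np.abs(profile.averaged - truth.true_fractions).max()
                ),
                "heart_rate_bpm": profile.heart_rate,
                "true_heart_rate_bpm": true_rate,
                "heart_rate_rel_error": abs(profile.heart_rate - true_rate) / true_rate,
            }
        )
    return pd.DataFrame(rows)


def run_orientation_equivariance(seed: int = 0) -> float:
    """Maximal deviation from an exact anterograde/retrograde swap.

    The same movie is profiled with the annotation in both orientations
    over one fixed cycle set; returns the largest absolute difference (in
    percentage points) between the forward percentages and the swapped
    reversed ones. Should be 0 to machine precision.
    """
    config = HeartSimConfig(seed=seed)
    movie, _ = simulate_brightfield_movie(config)
    annotation = synthetic_annotation(config)
    cycles = flow_mod.detect_cycles(movie, annotation)
    forward = flow_mod.analyze_movie(movie, annotation, cycles=cycles)
    reverse = flow_mod.analyze_movie(movie, annotation.reversed(), cycles=cycles)
    swapped = reverse.averaged[[1, 0, 2]]
    return float(np.abs(forward.averaged - swapped).max())


def run_midline_battery(n_hearts: int = 10) -> pd.DataFrame:
    """Midline equidistance and diameter recovery on simulated hearts."""
    from .geometry import point_polyline_distance
    from .synthetic import _TubeGeometry

    rows = []
    for k in range(n_hearts):
        config = HeartSimConfig(
            seed=k,
            chamber_radii=(25.0 - 0.8 * k, 22.0 + 0.5 * k, 8.0 + 0.2 * k),
        )
        annotation = synthetic_annotation(config)
        midline = midline_mod.build_midline(annotation)
        grid = midline_mod.resample_segments(midline, 100)
        diameters = midline_mod.measure_diameter(annotation, grid)
        equid = []
        for i in range(grid.n_segments):
            da = point_polyline_distance(grid.centers[i], annotation.wall_a)
            db = point_polyline_distance(grid.centers[i], annotation.wall_b)
            if np.isfinite(diameters[i]):
                equid.append(
                    abs(da - db) * config.pixel_width / diameters[i]
                )
        _, true_diam = _TubeGeometry(config).true_diameter(0.0)
        rel = np.abs(diameters - true_diam) / true_diam
        rows.append(
            {
                "heart": k,
                "n_segments": grid.n_segments,
                "max_equidistance_error": float(np.max(equid)),
                "max_diameter_error_interior": float(np.nanmax(rel[4:-4])),
            }
        )
    return pd.DataFrame(rows)


def run_enrichment_battery(
    enrichments=(1.0, 1.5, 2.0), n_replicates: int = 4, base_seed: int = 0
) -> pd.DataFrame:
    """Expression-stack AV-enrichment recovery with replicate averaging.

    For each enrichment level, ``n_replicates`` stacks are simulated,
    profiled on the maximum z-projection, aggregated per segment, and
    tested for an AV peak; mirrors profile averaging across larvae.
    """
    rows = []
    for enrichment in enrichments:
        tables = []
        for rep in range(n_replicates):
            config = HeartSimConfig(
                fluorescence_mode=True,
                frame_rate=50.0,
                n_frames=16,
                seed=base_seed + rep,
            )
            shape = np.ones(100)
            shape[45:55] = enrichment
            stack, _ = simulate_expression_stack(config, shape)
            annotation = synthetic_annotation(config)
            tables.append(
                midline_mod.measure_intensity_profile(
                    stack.pixels.max(axis=0), annotation
                )
            )
        aggregate = midline_mod.aggregate_profiles(tables)
        result = midline_mod.detect_av_enrichment(aggregate)
        rows.append(
            {
                "true_enrichment": enrichment,
                "measured_ratio": result["ratio"],
                "relative_error": abs(result["ratio"] - enrichment) / enrichment,
                "enriched_called": result["enriched"],
            }
        )
    return pd.DataFrame(rows)


def run_gcamp_battery(n_runs: int = 10, base_seed: int = 500) -> pd.DataFrame:
    """Phase-offset and cardiac-state recovery on 50-plane calcium series.

    Noise sweeps 0-15% of the endocardial signal across runs; every run
    reports how many planes were recovered within one frame (mod period)
    and the circular error of the selected diastole/systole frames.
    """
    rows = []
    for k in range(n_runs):
        noise = np.linspace(0.0, 0.15, n_runs)[k] * 120.0
        config = HeartSimConfig(
            fluorescence_mode=True,
            frame_rate=50.0,
            n_frames=100,
            beat_frequency=2.5,
            peristalsis_phase_lag=0.0,
            noise_sd=noise,
            seed=base_seed + k,
        )
        planes, truth = simulate_gcamp_plane_series(config, 50, 4.0, "random")
        series = g4d.PlaneSeries(planes=planes, z_step=4.0)
        period, _ = g4d.estimate_common_period(series)
        offsets = g4d.estimate_phase_offsets(series, period)
        true = truth.per_plane_phase_offset
        expected = (true[offsets.reference_plane] - true) % period
        errors = circular_distance(offsets.offset, expected, period)
        ok = int((errors[~offsets.unalignable] <= 1.0).sum())

        aligned = g4d.assemble_and_project(series, offsets)
        annotation = synthetic_annotation(config)
        diastole, systole = g4d.select_cardiac_state(aligned, annotation)
        o_ref = true[offsets.reference_plane]
        dia_err = float(
            circular_distance((diastole + o_ref) % period, truth.diastole_frame, period)
        )
        sys_err = float(
            circular_distance((systole + o_ref) % period, truth.systole_frame, period)
        )
        rows.append(
            {
                "run": k,
                "noise_sd": noise,
                "period_frames": period,
                "planes_within_1_frame": ok,
                "n_planes": series.n_planes,
                "diastole_error_frames": dia_err,
                "systole_error_frames": sys_err,
            }
        )
    return pd.DataFrame(rows)
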