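"""Retrospective phase alignment and 4D assembly of plane-wise calcium movies.

A beating heart imaged one optical plane at a time yields movies whose
acquisition phase is unknown per plane. Because the rhythm is stable over
the acquisition, each plane's mean-intensity trace is periodic with a
common period; the traces are folded to that period and circularly
registered plane-to-plane, starting from the plane with the strongest
temporal modulation and propagating outward to its neighbors. Planes are
then circularly shifted by the negated offset, stacked into a T x Z x Y x X
volume, and maximum-projected over z. Atrial diastole and systole frames
are picked from the atrial diameter trace measured on the projection.

Offset convention: ``offset[p]`` is the number of frames by which plane p's
waveform lags the reference plane; realignment shifts plane p circularly by
``-round(offset[p])`` frames. ``offset[reference_plane] == 0``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import NoPeriodicityError, ValidationError
from .io import HeartAnnotation, MovieStack
from .midline import build_midline, measure_intensity_profile, resample_segments
from .flow import atrial_diameter_trace
from .periodicity import estimate_period, parabolic_peak, refine_period_fourier

N_PHASE_BINS = 100
MIN_ALIGN_CORRELATION = 0.2


@dataclass
class PlaneSeries:
    """Ordered per-plane movies (ventral-most first) with a common z-step."""

    planes: list
    z_step: float

    def __post_init__(self):
        if len(self.planes) < 2:
            raise ValidationError("a plane series needs at least 2 planes")
        shapes = {p.pixels.shape for p in self.planes}
        rates = {p.frame_rate for p in self.planes}
        if len(shapes) != 1 or len(rates) != 1:
            raise ValidationError("all planes must share T, Y, X and frame rate")
        if not self.z_step > 0:
            raise ValidationError("z_step must be positive")

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def frame_rate(self) -> float:
        return self.planes[0].frame_rate

    @property
    def n_frames(self) -> int:
        return self.planes[0].pixels.shape[0]

    def mean_traces(self) -> np.ndarray:
        return np.stack([p.pixels.mean(axis=(1, 2)) for p in self.planes])

    def activity_traces(self, variance_quantile: float = 0.9) -> np.ndarray:
        """Per-plane intensity trace over the most modulated pixels.

        The plain image mean dilutes the beating signal with static
        background; averaging only the pixels in the top temporal-variance
        decile concentrates the trace on the moving endocardial glow and
        multiplies the modulation-to-noise ratio severalfold.
        """
        out = []
        for p in self.planes:
            px = p.pixels.astype(np.float32)
            var = px.var(axis=0)
            mask = var >= np.quantile(var, variance_quantile)
            out.append(px[:, mask].mean(axis=1))
        return np.stack(out)


@dataclass
class PhaseOffsets:
    """Estimated per-plane phase offsets (frames, in [0, period))."""

    offset: np.ndarray
    reference_plane: int
    period_frames: float
    unalignable: np.ndarray  # bool per plane

    def __post_init__(self):
        if abs(self.offset[self.reference_plane]) > 1e-9:
            raise ValidationError("reference plane must have offset 0")


@dataclass
class AlignedVolumeSeries:
    """Phase-aligned volume (T x Z x Y x X) and its maximum z-projection."""

    volume: np.ndarray
    projection: np.ndarray
    plane_indices: np.ndarray  # original plane index per z slot
    frame_rate: float
    pixel_width: float
    z_step: float


def estimate_common_period(series: PlaneSeries) -> tuple[float, np.ndarray]:
    """Common beat period (frames) across planes; flags deviant planes.

    The period is estimated per plane from the autocorrelation of its
    activity trace; the common value is the median over the ten most
    modulated planes, refined on the periodogram. Planes that are
    aperiodic or deviate more than 10% from the common period are flagged.
    Raises if more than half the planes are aperiodic.
    """
    traces = series.activity_traces()
    periods = np.full(series.n_planes, np.nan)
    for i, trace in enumerate(traces):
        try:
            periods[i] = estimate_period(trace)
        except NoPeriodicityError:
            pass
    valid = np.isfinite(periods)
    if valid.sum() <= series.n_planes / 2:
        raise NoPeriodicityError("more than half the planes show no periodicity")
    strongest = np.argsort(traces.var(axis=1))[::-1]
    refined = []
    for p in strongest:
        if np.isfinite(periods[p]):
            refined.append(refine_period_fourier(traces[p], periods[p]))
        if len(refined) == 10:
            break
    common = float(np.median(refined))
    flagged = ~valid | (np.abs(periods - common) > 0.1 * common)
    return common, flagged


def _fold_trace(trace: np.ndarray, period: float, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Average waveform over one period, interpolated onto n_bins phases."""
    t = np.arange(len(trace), dtype=float)
    phase = (t / period) % 1.0
    order = np.argsort(phase, kind="stable")
    ph, val = phase[order], np.asarray(trace, dtype=float)[order]
    # average duplicate phases, then interpolate circularly onto bin centers
    uniq, inverse = np.unique(np.round(ph, 9), return_inverse=True)
    sums = np.bincount(inverse, weights=val)
    counts = np.bincount(inverse)
    prof = sums / counts
    centers = (np.arange(n_bins) + 0.5) / n_bins
    ext_ph = np.concatenate([uniq - 1.0, uniq, uniq + 1.0])
    ext_val = np.concatenate([prof, prof, prof])
    return np.interp(centers, ext_ph, ext_val)


def _circular_shift_estimate(profile: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """(shift in bins, peak correlation) aligning `profile` to `reference`.

    Positive shift means the profile lags the reference by that many bins.
    """
    a = profile - profile.mean()
    b = reference - reference.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, 0.0
    n = len(a)
    corr = np.array([np.dot(np.roll(a, -k), b) for k in range(n)]) / (na * nb)
    best = int(np.argmax(corr))
    # parabolic refinement on the circular correlation
    left, mid, right = corr[(best - 1) % n], corr[best], corr[(best + 1) % n]
    denom = left - 2 * mid + right
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))
    return (best + delta) % n, float(mid)


def estimate_phase_offsets(
    series: PlaneSeries, period_frames: float, n_refine_passes: int = 2
) -> PhaseOffsets:
    """Per-plane phase offsets by neighbor-propagated circular registration.

    Each plane's activity trace is folded to the common period (100 phase
    bins, circularly smoothed); the reference is the plane with maximal
    temporal variance; alignment propagates outward to adjacent planes,
    each registered against the running average of the already-aligned
    folded profiles, and is then refined in ``n_refine_passes`` passes
    against the grand aligned average. Planes whose peak folded-trace
    correlation falls below 0.2 are flagged unalignable.
    """
    traces = series.activity_traces()
    folded = np.stack(
        [
            gaussian_filter1d(_fold_trace(t, period_frames), 2.0, mode="wrap")
            for t in traces
        ]
    )
    ref = int(np.argmax(traces.var(axis=1)))
    n = series.n_planes

    shifts = np.zeros(n)  # in phase bins
    unalignable = np.zeros(n, dtype=bool)
    aligned_sum = folded[ref].copy()
    n_aligned = 1
    order = sorted(range(n), key=lambda p: (abs(p - ref), p))
    for p in order:
        if p == ref:
            continue
        shift_bins, peak = _circular_shift_estimate(folded[p], aligned_sum / n_aligned)
        if peak < MIN_ALIGN_CORRELATION:
            unalignable[p] = True
            continue
        shifts[p] = shift_bins
        aligned_sum += np.roll(folded[p], -int(round(shift_bins)))
        n_aligned += 1

    for _ in range(n_refine_passes):
        grand = folded[ref].copy()
        count = 1
        for p in range(n):
            if p != ref and not unalignable[p]:
                grand += np.roll(folded[p], -int(round(shifts[p])))
                count += 1
        grand /= count
        for p in range(n):
            if p == ref:
                continue
            shift_bins, peak = _circular_shift_estimate(folded[p], grand)
            if peak < MIN_ALIGN_CORRELATION:
                unalignable[p] = True
                continue
            unalignable[p] = False
            shifts[p] = shift_bins

    offsets = (shifts / N_PHASE_BINS) * period_frames % period_frames
    offsets[ref] = 0.0
    return PhaseOffsets(
        offset=offsets,
        reference_plane=ref,
        period_frames=period_frames,
        unalignable=unalignable,
    )


def assemble_and_project(series: PlaneSeries, offsets: PhaseOffsets) -> AlignedVolumeSeries:
    """Circularly shift each plane by -round(offset) and stack into 4D.

    Flagged planes are dropped; the projection is the per-pixel maximum
    over z. Integer-frame shifts are used (no temporal interpolation).
    """
    keep = np.flatnonzero(~offsets.unalignable)
    if len(keep) == 0:
        raise ValidationError("all planes are flagged unalignable")
    shifted = [
        np.roll(series.planes[p].pixels, -int(round(offsets.offset[p])), axis=0)
        for p in keep
    ]
    volume = np.stack(shifted, axis=1)  # (T, Z, Y, X)
    return AlignedVolumeSeries(
        volume=volume,
        projection=volume.max(axis=1),
        plane_indices=keep,
        frame_rate=series.frame_rate,
        pixel_width=series.planes[0].pixel_width,
        z_step=series.z_step,
    )


def select_cardiac_state(
    aligned: AlignedVolumeSeries, annotation: HeartAnnotation
) -> tuple[int, int]:
    """(diastole_frame, systole_frame) from the projected atrial diameter.

    The atrial diameter is measured per frame at the mid-atrium chord of
    the annotation (drawn on the projection); the trace is folded over the
    beat period so every cycle contributes, and diastole/systole are the
    frames nearest the maximum/minimum of the folded waveform within the
    first period.
    """
    trace = atrial_diameter_trace(
        aligned.projection, annotation, wall="bright_interior"
    )
    trace = gaussian_filter1d(trace, 1.0)
    if np.ptp(trace) < 1e-6 or np.std(trace) == 0:
        raise NoPeriodicityError("flat atrial diameter trace on the projection")
    period = refine_period_fourier(trace, estimate_period(trace))
    folded = gaussian_filter1d(_fold_trace(trace, period), 2.0, mode="wrap")
    t = len(trace)

    def to_frame(bin_index: int) -> int:
        phase = (bin_index + 0.5) / N_PHASE_BINS
        return int(round(phase * period)) % min(int(round(period)), t)

    return to_frame(int(np.argmax(folded))), to_frame(int(np.argmin(folded)))


def calcium_profile(
    aligned: AlignedVolumeSeries,
    annotation: HeartAnnotation,
    state_frame: int,
    n_segments: int = 100,
    rim_um: float | None = None,
) -> pd.DataFrame:
    """100-segment calcium profile at a chosen cardiac state.

    Delegates to the midline intensity profiler on the projection frame and
    adds ``normalized_intensity`` (per-segment mean divided by the
    whole-heart mean), the scale-free form of AV-canal enrichment.
    """
    frame = aligned.projection[state_frame]
    table = measure_intensity_profile(frame, annotation, n_segments=n_segments, rim_um=rim_um)
    mean = np.nanmean(table["mean_intensity"].to_numpy(dtype=float))
    table["normalized_intensity"] = table["mean_intensity"] / mean
    return table
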