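"""AV-canal blood-flow profiling from brightfield heart movies.

The readout is a kymograph: image intensity sampled along the heart midline
in a window centered on the AV canal, one line per frame, averaged across a
3-pixel-wide band normal to the midline. Blood cells appear as dark speckle
whose stripes slope with the flow; the per-frame displacement is estimated
by normalized cross-correlation between consecutive kymograph lines with
parabolic sub-sample refinement. Each frame pair is then classified as
anterograde (atrium to ventricle, positive), retrograde, or no-flow by a
speed threshold, and the percentages of each class are computed per beating
cycle and averaged over (by default) the first three complete cycles.

Cardiac cycles are detected from the atrial diameter trace: the movie is
sampled along fixed mid-atrium chords of the annotation, the dark wall band
is located on each side of the lumen per frame, and the beat period is read
from the autocorrelation of that trace (refined on the periodogram); cycle
boundaries sit at successive atrial-diastole (maximal diameter) peaks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import (
    gaussian_filter1d,
    map_coordinates,
    maximum_filter1d,
    median_filter,
)
from scipy.signal import find_peaks

from .errors import GeometryError, InsufficientCyclesError, NoPeriodicityError, ValidationError
from .geometry import interp_along
from .io import HeartAnnotation, MovieStack
from .midline import Midline, SegmentGrid, build_midline, measure_diameter, resample_segments
from .periodicity import estimate_period, parabolic_peak, refine_period_fourier

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
NO_FLOW = "no_flow"
FLOW_CLASSES = (ANTEROGRADE, RETROGRADE, NO_FLOW)


@dataclass
class Kymograph:
    """T x S intensity matrix along the AV-canal axis (atrium -> ventricle)."""

    values: np.ndarray
    sample_spacing: float  # um between samples
    frame_rate: float
    axis_direction: str = "atrium->ventricle positive"

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] < 8:
            raise ValidationError("kymograph needs at least 8 samples per line")
        if not self.sample_spacing > 0:
            raise ValidationError("sample_spacing must be positive")


@dataclass
class CycleSet:
    """Complete beating cycles delimited by atrial-diastole frames."""

    boundaries: np.ndarray  # strictly increasing frame indices
    period_frames: float

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.boundaries) < 2:
            raise ValidationError("need at least one complete cycle")
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValidationError("cycle boundaries must be strictly increasing")
        if not self.period_frames > 0:
            raise ValidationError("period must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1


@dataclass
class FrameFlowLabels:
    """Per frame-pair signed displacement (um/frame) and flow class."""

    displacement: np.ndarray
    confidence: np.ndarray
    label: np.ndarray  # unicode array over FLOW_CLASSES
    speed_threshold: float  # um/s
    frame_rate: float


@dataclass
class FlowProfile:
    """Per-cycle and cycle-averaged flow-class percentages plus heart rate."""

    per_cycle: np.ndarray  # (n_cycles, 3) percentages (antero, retro, no-flow)
    averaged: np.ndarray  # (3,)
    heart_rate: float  # beats per minute
    n_cycles_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "anterograde_pct": self.averaged[0],
                "retrograde_pct": self.averaged[1],
                "no_flow_pct": self.averaged[2],
                "heart_rate_bpm": self.heart_rate,
                "n_cycles_used": self.n_cycles_used,
            }
        )


# ---------------------------------------------------------------------------
# kymograph extraction


def extract_kymograph(
    movie: MovieStack,
    annotation: HeartAnnotation,
    window_halfwidth: float = 20.0,
    sample_spacing: float | None = None,
    midline: Midline | None = None,
) -> Kymograph:
    """Sample the movie along the midline around the AV canal, per frame.

    Intensity is taken at evenly spaced arc positions within +/- the window
    about the AV point and averaged across a 3-pixel band normal to the
    midline (bilinear interpolation). Sample index increases from the atrial
    to the ventricular side.
    """
    if midline is None:
        midline = build_midline(annotation)
    spacing = sample_spacing if sample_spacing is not None else movie.pixel_width / 2.0
    s_av = midline.av_arc_position
    if s_av - window_halfwidth < 0 or s_av + window_halfwidth > midline.total_length:
        raise GeometryError(
            "kymograph window extends past the heart ends "
            f"(AV at {s_av:.1f} um of {midline.total_length:.1f} um)"
        )
    n_samples = 2 * int(round(window_halfwidth / spacing)) + 1
    arcs = s_av + (np.arange(n_samples) - n_samples // 2) * spacing
    pos = interp_along(midline.points, midline.arc_position, arcs)
    tang = np.gradient(pos, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offsets = np.array([-1.0, 0.0, 1.0])  # 3-pixel band
    # coords: (band, sample, xy) -> map_coordinates wants (y, x)
    coords = pos[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    yx = np.stack([coords[..., 1].ravel(), coords[..., 0].ravel()])

    lines = np.empty((movie.n_frames, n_samples), dtype=float)
    for t in range(movie.n_frames):
        vals = map_coordinates(movie.pixels[t].astype(float), yx, order=1, mode="nearest")
        lines[t] = vals.reshape(len(offsets), n_samples).mean(axis=0)
    return Kymograph(values=lines, sample_spacing=spacing, frame_rate=movie.frame_rate)


# ---------------------------------------------------------------------------
# displacement estimation


def estimate_frame_displacement(
    kymograph: Kymograph,
    max_lag: float = 15.0,
    smooth_sigma: float = 1.0,
    temporal_sigma: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed displacement (um/frame) between consecutive kymograph lines.

    For each line pair the displacement is the argmax over integer sample
    lags of the Pearson correlation of the overlapping parts, refined to
    sub-sample precision by parabolic interpolation of the peak and its
    neighbors; confidence is the peak correlation. Zero-variance lines yield
    displacement 0 with confidence 0. ``smooth_sigma`` (samples) lightly
    low-passes each line first, which stabilizes the sub-sample refinement;
    ``temporal_sigma`` (frames) lightly low-passes the kymograph along time
    first, which suppresses the peak-locking bias that otherwise pulls
    slow (sub-sample per frame) displacements toward zero in noisy movies,
    at the cost of smearing schedule transitions by about one frame.

    Returns ``(displacement, confidence)``, each of length T-1. Positive
    displacement means motion toward the ventricle (anterograde).
    """
    X = kymograph.values.astype(float)
    spacing = kymograph.sample_spacing
    S = X.shape[1]
    L = int(max_lag / spacing)
    if L < 1:
        raise ValidationError("max_lag smaller than one sample spacing")
    if L >= S // 2:
        raise ValidationError("max_lag must be below half the kymograph window")
    if temporal_sigma > 0:
        X = gaussian_filter1d(X, temporal_sigma, axis=0, mode="nearest")
    if smooth_sigma > 0:
        X = gaussian_filter1d(X, smooth_sigma, axis=1, mode="nearest")

    n_pairs = X.shape[0] - 1
    lags = np.arange(-L, L + 1)
    corr = np.full((n_pairs, len(lags)), -np.inf)
    x, y = X[:-1], X[1:]
    for j, lag in enumerate(lags):
        a = max(0, lag)
        b = S + min(0, lag)
        xa = x[:, a - lag : b - lag]
        ya = y[:, a:b]
        xm = xa - xa.mean(axis=1, keepdims=True)
        ym = ya - ya.mean(axis=1, keepdims=True)
        denom = np.sqrt((xm * xm).sum(axis=1) * (ym * ym).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[:, j] = np.where(denom > 0, (xm * ym).sum(axis=1) / denom, 0.0)

    flat = (x.std(axis=1) == 0) | (y.std(axis=1) == 0)
    best = np.argmax(corr, axis=1)
    displacement = np.empty(n_pairs)
    confidence = np.empty(n_pairs)
    for i in range(n_pairs):
        pos, val = parabolic_peak(corr[i], best[i])
        displacement[i] = (pos - L) * spacing
        confidence[i] = min(max(val, 0.0), 1.0)
    displacement[flat] = 0.0
    confidence[flat] = 0.0
    return displacement, confidence


def classify_flow_frames(
    displacement: np.ndarray,
    confidence: np.ndarray,
    frame_rate: float,
    speed_threshold: float = 115.0,
    confidence_floor: float = 0.3,
) -> FrameFlowLabels:
    """Classify each frame pair as anterograde / retrograde / no-flow.

    A pair is no-flow when |displacement| * frame_rate is below
    ``speed_threshold`` (um/s) or when the correlation confidence falls
    below ``confidence_floor`` (motion unmeasurable); otherwise the sign of
    the displacement decides the direction.
    """
    if not speed_threshold > 0:
        raise ValidationError("speed_threshold must be positive")
    displacement = np.asarray(displacement, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    speed = np.abs(displacement) * frame_rate
    label = np.where(displacement > 0, ANTEROGRADE, RETROGRADE)
    label = np.where((speed < speed_threshold) | (confidence < confidence_floor),
                     NO_FLOW, label)
    return FrameFlowLabels(
        displacement=displacement,
        confidence=confidence,
        label=label.astype("U11"),
        speed_threshold=speed_threshold,
        frame_rate=frame_rate,
    )


# ---------------------------------------------------------------------------
# cycle detection


def chord_width_trace(
    pixels: np.ndarray,
    center: np.ndarray,
    normal: np.ndarray,
    halfwidth_px: float,
    pixel_width: float,
    wall: str = "dark",
    step_px: float = 0.5,
) -> np.ndarray:
    """Per-frame lumen width (um) along a fixed chord.

    ``wall='dark'`` (brightfield): the dark wall band on each side is the
    intensity minimum over the outer part of the half-chord (|t| beyond
    40% of the half-width); blood speckle cannot disturb this because it
    stays well inside the lumen, while the wall band always lies in the
    outer region for contraction amplitudes below 50%. The width is the
    distance between the two band minima. ``wall='bright_interior'``
    (fluorescence projections): the width is the span of the
    above-half-intensity samples of the bright tube interior against dim
    background, ignoring isolated short runs (smoothed noise).
    """
    if wall not in ("dark", "bright_interior"):
        raise ValidationError(f"unknown wall mode {wall!r}")
    n = int(halfwidth_px / step_px)
    ts = (np.arange(-n, n + 1)) * step_px
    pts = center[None, :] + ts[:, None] * normal[None, :]
    yx = np.stack([pts[:, 1], pts[:, 0]])
    widths = np.empty(pixels.shape[0])
    min_run = max(int(1.0 / (step_px * pixel_width) * 2.0), 3)  # ~2 um of pixels
    inner = int(np.ceil(0.4 * n))  # wall search: outer 60% of each half-chord

    for t in range(pixels.shape[0]):
        prof = map_coordinates(pixels[t].astype(float), yx, order=1, mode="nearest")
        prof = gaussian_filter1d(prof, 2.0)
        if wall == "dark":
            mid = n
            left, _ = parabolic_peak(-prof[: mid - inner + 1],
                                     int(np.argmin(prof[: mid - inner + 1])))
            seg = prof[mid + inner :]
            right, _ = parabolic_peak(-seg, int(np.argmin(seg)))
            widths[t] = (right + mid + inner - left) * step_px * pixel_width
        else:
            half = 0.5 * (prof.max() + prof.min())
            above = prof >= half
            edges = np.diff(above.astype(int))
            starts = list(np.flatnonzero(edges == 1) + 1)
            ends = list(np.flatnonzero(edges == -1) + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                ends.append(len(above))
            spans = [(s0, e0) for s0, e0 in zip(starts, ends) if e0 - s0 >= min_run]
            if not spans:
                widths[t] = np.nan
                continue
            widths[t] = (ts[spans[-1][1] - 1] - ts[spans[0][0]]) * pixel_width
    # fill detection dropouts by nearest valid neighbour
    bad = np.isnan(widths)
    if bad.all():
        raise NoPeriodicityError("chord width undetectable in every frame")
    if bad.any():
        idx = np.arange(len(widths))
        widths[bad] = np.interp(idx[bad], idx[~bad], widths[~bad])
    return widths


def atrial_diameter_trace(
    movie_pixels: np.ndarray,
    annotation: HeartAnnotation,
    grid: SegmentGrid | None = None,
    wall: str = "dark",
) -> np.ndarray:
    """Atrial diameter per frame around the mid-atrium segment.

    Five parallel chords centered on the mid-atrium segment are measured
    and combined by a per-frame median, so a blood cell crossing one chord
    cannot corrupt the reading; a short temporal median filter then removes
    single-frame detection outliers.
    """
    if grid is None:
        grid = resample_segments(build_midline(annotation), 100)
    i = grid.n_atrium // 2
    ref = measure_diameter(annotation, grid)
    ref_d = ref[i] if np.isfinite(ref[i]) else np.nanmedian(ref)
    # chord reaches ~50% past the annotated wall on each side, no further:
    # a longer chord would pick up other parts of the curved tube
    halfwidth_px = 0.75 * ref_d / annotation.pixel_width
    chord_idx = [j for j in range(i - 8, i + 9, 2) if 0 <= j < grid.n_atrium]
    traces = []
    for j in chord_idx:
        normal = np.array([-grid.tangents[j, 1], grid.tangents[j, 0]])
        traces.append(
            chord_width_trace(
                movie_pixels, grid.centers[j], normal, halfwidth_px,
                annotation.pixel_width, wall=wall,
            )
        )
    trace = np.median(np.stack(traces), axis=0)
    return median_filter(trace, size=5, mode="nearest")


def detect_cycles(
    movie: MovieStack,
    annotation: HeartAnnotation,
    grid: SegmentGrid | None = None,
    wall: str = "dark",
) -> CycleSet:
    """Detect complete beating cycles from the atrial-diameter signal.

    A coarse period comes from the first prominent autocorrelation peak of
    the detrended diameter trace and is refined on the highest usable
    autocorrelation harmonic (lag ~ m x period carries m-fold smaller
    relative error); boundaries are successive atrial-diastole
    (maximal-diameter) peaks.
    """
    trace = atrial_diameter_trace(movie.pixels, annotation, grid=grid, wall=wall)
    trace = gaussian_filter1d(trace, 2.0)
    coarse = estimate_period(trace)
    period = refine_period_fourier(trace, coarse)
    peaks, _ = find_peaks(
        trace, distance=max(int(0.7 * period), 1), prominence=0.3 * np.ptp(trace)
    )
    if len(peaks) < 2:
        raise NoPeriodicityError("fewer than two atrial-diastole peaks found")
    return CycleSet(boundaries=peaks, period_frames=period)





def heart_rate_bpm(cycles: CycleSet, frame_rate: float) -> float:
    """Heart rate in beats per minute from the detected period."""
    return frame_rate / cycles.period_frames * 60.0


# ---------------------------------------------------------------------------
# profile assembly


def compute_flow_profile(
    labels: FrameFlowLabels,
    cycles: CycleSet,
    n_cycles: int = 3,
) -> FlowProfile:
    """Percentages of each flow class per cycle, averaged over ``n_cycles``.

    Percentages are computed over frame pairs (motion is defined between
    frames); each per-cycle triple sums to 100 exactly.
    """
    if cycles.n_cycles < n_cycles:
        raise InsufficientCyclesError(
            f"need {n_cycles} complete cycles, found {cycles.n_cycles}"
        )
    per_cycle = np.empty((n_cycles, 3))
    for c in range(n_cycles):
        lo, hi = cycles.boundaries[c], cycles.boundaries[c + 1]
        hi = min(hi, len(labels.label))
        window = labels.label[lo:hi]
        if len(window) == 0:
            raise InsufficientCyclesError("cycle contains no frame pairs")
        for k, cls in enumerate(FLOW_CLASSES):
            per_cycle[c, k] = 100.0 * np.count_nonzero(window == cls) / len(window)
    return FlowProfile(
        per_cycle=per_cycle,
        averaged=per_cycle.mean(axis=0),
        heart_rate=heart_rate_bpm(cycles, labels.frame_rate),
        n_cycles_used=n_cycles,
    )


def analyze_movie(
    movie: MovieStack,
    annotation: HeartAnnotation,
    window_halfwidth: float = 20.0,
    max_lag: float = 15.0,
    speed_threshold: float = 115.0,
    confidence_floor: float = 0.3,
    n_cycles: int = 3,
    cycles: CycleSet | None = None,
) -> FlowProfile:
    """Full pipeline: kymograph -> displacement -> labels -> cycle profile."""
    kym = extract_kymograph(movie, annotation, window_halfwidth=window_halfwidth)
    disp, conf = estimate_frame_displacement(kym, max_lag=max_lag)
    disp = median_filter(disp, size=3, mode="nearest")
    labels = classify_flow_frames(
        disp, conf, movie.frame_rate,
        speed_threshold=speed_threshold, confidence_floor=confidence_floor,
    )
    if cycles is None:
        cycles = detect_cycles(movie, annotation)
    return compute_flow_profile(labels, cycles, n_cycles=n_cycles)


def _tukey_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Inclusive-median (Tukey hinge) quartiles."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2  # include the median point in both halves when n is odd
    return float(np.median(v[:half])), med, float(np.median(v[n - half:]))


def summarize_profiles(profiles: list[FlowProfile]) -> pd.DataFrame:
    """Group summary per flow class: min, Q1, median, Q3, max, mean.

    Quartiles follow the inclusive-median (Tukey hinge) convention, matching
    box-and-whisker plotting of small per-animal samples.
    """
    if len(profiles) == 0:
        raise ValidationError("summarize_profiles requires at least one profile")
    rows = []
    data = np.stack([p.averaged for p in profiles])
    for k, cls in enumerate(FLOW_CLASSES):
        v = data[:, k]
        q1, med, q3 = _tukey_quartiles(v)
        rows.append(
            {
                "flow_class": cls,
                "min": float(v.min()),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": float(v.max()),
                "mean": float(v.mean()),
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)
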