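"""Seeded, ground-truthed synthetic beating-heart movies and stacks.

The simulated organ is a two-chambered contracting tube in ventral view:
atrium on the right, ventricle on the left, joined by a narrow AV canal,
with an S-curved centerline in the image plane. Walls contract sinusoidally
at the beat frequency with an optional peristaltic phase lag along the tube.

Three acquisition modes are emulated:

* brightfield movies (bright lumen, darker wall band, dark advected blood
  speckle) whose per-cycle flow direction follows a configurable
  anterograde/retrograde/no-flow phase schedule;
* fluorescence plane series (endocardial wall glow, elevated at the AV
  canal) acquired plane by plane with an unknown phase offset per plane,
  the tube tilted in depth so every plane intersects it;
* static expression z-stacks whose wall fluorescence follows an arbitrary
  per-segment profile.

Every simulation returns a :class:`GroundTruth` carrying the values the
analysis modules are supposed to recover; identical config + seed yields
bit-identical output. Optics are deliberately simple (Gaussian wall glow,
Gaussian speckle, additive Gaussian noise): the generator provides geometry
and kinematics with known truth, not photorealism.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .io import HeartAnnotation, MovieStack, ZStack

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
NO_FLOW = "no_flow"

# geometry/rendering study conditions (um unless noted)
TUBE_LENGTH_UM = 200.0
BEND_UM = 15.0
WALL_THICKNESS_UM = 4.0
ATRIUM_S = 0.25
VENTRICLE_S = 0.75
CHAMBER_WIDTH_S = 0.16
CANAL_WIDTH_S = 0.06
BRIGHT_BG = 90.0
BRIGHT_LUMEN = 170.0
BRIGHT_WALL = 50.0
PARTICLE_DEPTH = 90.0
PARTICLE_SIGMA_PX = 1.5
FLUOR_BG = 10.0
FLUOR_BASE = 120.0
SIGMA_WALL_UM = 2.5
N_TRUTH_SEGMENTS = 100


@dataclass(frozen=True)
class HeartSimConfig:
    """Configuration of one simulated acquisition.

    ``chamber_radii`` is (atrium, ventricle, canal) in um. The
    ``flow_schedule`` is an ordered list of ``((lo, hi), flow_class,
    speed_um_s)`` whose phase intervals must partition [0, 1).
    """

    image_size: tuple[int, int] = (128, 160)  # (Y, X) pixels
    pixel_width: float = 1.92  # um per pixel
    frame_rate: float = 240.0  # frames per second
    n_frames: int = 480
    beat_frequency: float = 2.5  # Hz
    chamber_radii: tuple[float, float, float] = (25.0, 22.0, 8.0)
    wall_motion_amplitude: float = 0.25  # fraction of radius in [0, 0.5)
    peristalsis_phase_lag: float = 0.5  # radians from inflow to outflow
    flow_schedule: tuple = (
        ((0.0, 0.7), ANTEROGRADE, 300.0),
        ((0.7, 0.9), RETROGRADE, 300.0),
        ((0.9, 1.0), NO_FLOW, 0.0),
    )
    n_particles: int = 80
    noise_sd: float = 6.0
    fluorescence_mode: bool = False
    av_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.wall_motion_amplitude < 0.5:
            raise ConfigurationError("wall_motion_amplitude must be in [0, 0.5)")
        if self.period_frames < 4:
            raise ConfigurationError(
                f"beat period is {self.period_frames:.2f} frames; need >= 4"
            )
        if self.av_enrichment < 1.0:
            raise ConfigurationError("av_enrichment must be >= 1")
        sched = self.schedule_entries()
        pos = 0.0
        for (lo, hi), cls, speed in sched:
            if cls not in (ANTEROGRADE, RETROGRADE, NO_FLOW):
                raise ConfigurationError(f"unknown flow class {cls!r}")
            if abs(lo - pos) > 1e-9 or hi <= lo:
                raise ConfigurationError(
                    "flow_schedule phase intervals must partition [0, 1) "
                    "in order without gaps or overlap"
                )
            if speed < 0:
                raise ConfigurationError("schedule speeds must be non-negative")
            pos = hi
        if abs(pos - 1.0) > 1e-9:
            raise ConfigurationError("flow_schedule must end at phase 1.0")

    @property
    def period_frames(self) -> float:
        return self.frame_rate / self.beat_frequency

    def schedule_entries(self):
        out = []
        for entry in self.flow_schedule:
            if len(entry) == 3:
                (lo, hi), cls, speed = entry
            else:  # flat (lo, hi, cls, speed) form
                lo, hi, cls, speed = entry
            out.append(((float(lo), float(hi)), str(cls), float(speed)))
        return out

    def true_fractions(self) -> np.ndarray:
        """Percentages (anterograde, retrograde, no-flow) from the schedule."""
        frac = {ANTEROGRADE: 0.0, RETROGRADE: 0.0, NO_FLOW: 0.0}
        for (lo, hi), cls, _ in self.schedule_entries():
            frac[cls] += (hi - lo) * 100.0
        return np.array([frac[ANTEROGRADE], frac[RETROGRADE], frac[NO_FLOW]])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "HeartSimConfig":
        payload = dict(payload)
        for key in ("image_size", "chamber_radii"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "flow_schedule" in payload:
            payload["flow_schedule"] = tuple(
                ((e[0][0], e[0][1]), e[1], e[2]) if len(e) == 3 else tuple(e)
                for e in payload["flow_schedule"]
            )
        return cls(**payload)


@dataclass
class GroundTruth:
    """Everything the analysis stages are supposed to recover."""

    period_frames: float
    true_fractions: np.ndarray | None = None
    per_frame_flow_class: np.ndarray | None = None
    cycle_boundaries: np.ndarray | None = None
    per_plane_phase_offset: np.ndarray | None = None
    true_segment_intensity: np.ndarray | None = None
    true_diameter: np.ndarray | None = None
    segment_arc_um: np.ndarray | None = None
    diastole_frame: int | None = None
    systole_frame: int | None = None

    def __post_init__(self):
        if self.true_fractions is not None:
            self.true_fractions = np.asarray(self.true_fractions, dtype=float)
            if abs(self.true_fractions.sum() - 100.0) > 1e-9:
                raise ConfigurationError("true fractions must sum to 100")
        if self.cycle_boundaries is not None:
            self.cycle_boundaries = np.asarray(self.cycle_boundaries, dtype=int)
            if not np.all(np.diff(self.cycle_boundaries) > 0):
                raise ConfigurationError("cycle boundaries must be strictly increasing")

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# tube geometry


class _TubeGeometry:
    """Analytic S-curved two-chamber tube and its pixel-coordinate fields."""

    def __init__(self, config: HeartSimConfig, n_dense: int = 1201):
        self.config = config
        r_atr, r_ven, r_can = config.chamber_radii
        self.s = np.linspace(0.0, 1.0, n_dense)
        # ventral view: atrium (inflow, s=0) on the right, ventricle left
        x_um = (0.5 - self.s) * TUBE_LENGTH_UM
        y_um = BEND_UM * np.sin(2.0 * np.pi * self.s)
        ny, nx = config.image_size
        cx, cy = nx / 2.0, ny / 2.0
        self.points_px = np.column_stack(
            [cx + x_um / config.pixel_width, cy + y_um / config.pixel_width]
        )
        d = np.diff(self.points_px, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
        self.arc_px = np.concatenate([[0.0], np.cumsum(seg)])
        self.arc_um = self.arc_px * config.pixel_width
        self.length_um = float(self.arc_um[-1])

        tang = np.gradient(self.points_px, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        norm[norm == 0] = 1.0
        self.tangent = tang / norm[:, None]
        self.normal = np.column_stack([-self.tangent[:, 1], self.tangent[:, 0]])

    def radius0(self, s: np.ndarray) -> np.ndarray:
        r_atr, r_ven, r_can = self.config.chamber_radii
        return (
            r_can
            + (r_atr - r_can) * np.exp(-(((s - ATRIUM_S) / CHAMBER_WIDTH_S) ** 2))
            + (r_ven - r_can) * np.exp(-(((s - VENTRICLE_S) / CHAMBER_WIDTH_S) ** 2))
        )

    def lag(self, s: np.ndarray) -> np.ndarray:
        return self.config.peristalsis_phase_lag * s

    def gate(self, s: np.ndarray, t_seconds: float) -> np.ndarray:
        """Radial contraction factor g(s, t) in (0.5, 1]."""
        theta = 2.0 * np.pi * self.config.beat_frequency * t_seconds
        amp = self.config.wall_motion_amplitude
        return 1.0 - amp * (1.0 - np.cos(theta - self.lag(s))) / 2.0

    def radius(self, s: np.ndarray, t_seconds: float) -> np.ndarray:
        return self.radius0(s) * self.gate(s, t_seconds)

    def s_at_arc(self, arc_um: np.ndarray) -> np.ndarray:
        return np.interp(arc_um, self.arc_um, self.s)

    def position_px(self, s: np.ndarray) -> np.ndarray:
        x = np.interp(s, self.s, self.points_px[:, 0])
        y = np.interp(s, self.s, self.points_px[:, 1])
        return np.column_stack([x, y])

    def normal_at(self, s: np.ndarray) -> np.ndarray:
        nx = np.interp(s, self.s, self.normal[:, 0])
        ny = np.interp(s, self.s, self.normal[:, 1])
        n = np.column_stack([nx, ny])
        mag = np.hypot(n[:, 0], n[:, 1])
        mag[mag == 0] = 1.0
        return n / mag[:, None]

    def pixel_fields(self) -> tuple[np.ndarray, np.ndarray]:
        """(s_grid, signed distance grid in um) for every image pixel."""
        ny, nx = self.config.image_size
        xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        _, idx = cKDTree(self.points_px).query(pts)
        nearest = self.points_px[idx]
        delta = pts - nearest
        d_px = np.einsum("ij,ij->i", delta, self.normal[idx])
        s_grid = self.s[idx].reshape(ny, nx)
        d_grid = (d_px * self.config.pixel_width).reshape(ny, nx)
        return s_grid, d_grid

    # -- ground-truth geometry -------------------------------------------

    def truth_segments(self, n_segments: int = N_TRUTH_SEGMENTS):
        """Arc positions and s of segment centers, allocated per chamber."""
        l_av = self.length_um / 2.0  # AV canal at s = 0.5, symmetric S-curve
        n_atr = int(round(n_segments * l_av / self.length_um))
        n_atr = min(max(n_atr, 1), n_segments - 1)
        n_ven = n_segments - n_atr
        bounds = np.concatenate(
            [
                np.linspace(0.0, l_av, n_atr + 1),
                l_av + np.linspace(0.0, self.length_um - l_av, n_ven + 1)[1:],
            ]
        )
        centers = 0.5 * (bounds[:-1] + bounds[1:])
        return centers, self.s_at_arc(centers), bounds

    def true_diameter(self, t_seconds: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        arc, s, _ = self.truth_segments()
        return arc, 2.0 * self.radius(s, t_seconds)

    def annotation(self, n_vertices: int = 160, t_seconds: float = 0.0) -> HeartAnnotation:
        """Wall traces at time ``t_seconds`` (the frame the user annotates)."""
        arc = np.linspace(0.0, self.length_um, n_vertices)
        s = self.s_at_arc(arc)
        center = self.position_px(s)
        normal = self.normal_at(s)
        r_px = self.radius(s, t_seconds) / self.config.pixel_width
        wall_a = center + normal * r_px[:, None]
        wall_b = center - normal * r_px[:, None]
        marker = int(np.argmin(np.abs(arc - self.length_um / 2.0)))
        return HeartAnnotation(
            wall_a=wall_a,
            wall_b=wall_b,
            av_marker_a=marker,
            av_marker_b=marker,
            pixel_width=self.config.pixel_width,
        )

    def depth_um(self) -> float:
        """Simulated dorsoventral extent available for plane series."""
        return 8.0 * self.config.chamber_radii[0]

    def z_center(self, s: np.ndarray) -> np.ndarray:
        """Tube center depth: tilted from ventral (s=0) to dorsal (s=1)."""
        depth = self.depth_um()
        pad = 0.5 * self.config.chamber_radii[0]
        return pad + (depth - 2.0 * pad) * s


def synthetic_annotation(config: HeartSimConfig, n_vertices: int = 160) -> HeartAnnotation:
    """Wall annotation of the simulated heart at frame 0."""
    return _TubeGeometry(config).annotation(n_vertices=n_vertices)


# ---------------------------------------------------------------------------
# schedules and phase bookkeeping


def _schedule_lookup(config: HeartSimConfig, phase: np.ndarray):
    """(class per phase, signed arc speed um/s per phase)."""
    cls = np.empty(phase.shape, dtype="U11")
    speed = np.zeros(phase.shape)
    for (lo, hi), c, v in config.schedule_entries():
        inside = (phase >= lo) & (phase < hi)
        cls[inside] = c
        speed[inside] = v if c == ANTEROGRADE else (-v if c == RETROGRADE else 0.0)
    return cls, speed


def _diastole_frames(config: HeartSimConfig, geom: _TubeGeometry) -> tuple[int, int, np.ndarray]:
    """(diastole frame, systole frame, diastole peaks) in absolute frames.

    Diastole is the frame of maximal atrial cross-section; with the phase
    convention used here that is where cos(theta - lag(s_atrium)) = 1.
    """
    period = config.period_frames
    lag_a = float(geom.lag(np.array([ATRIUM_S]))[0])
    dia = (lag_a / (2.0 * np.pi)) * period % period
    sys = (dia + period / 2.0) % period
    peaks = np.round(dia + np.arange(0, config.n_frames) * period).astype(int)
    peaks = peaks[peaks < config.n_frames]
    return int(round(dia)) % int(round(period)), int(round(sys)), peaks


# ---------------------------------------------------------------------------
# brightfield simulation


def simulate_brightfield_movie(config: HeartSimConfig) -> tuple[MovieStack, GroundTruth]:
    """Brightfield movie of the contracting tube with advected blood speckle.

    Dark Gaussian particles move along the tube centerline following the
    flow schedule within each cycle; walls contract sinusoidally with the
    configured peristaltic lag; Gaussian noise is added last.
    """
    if config.fluorescence_mode:
        raise ConfigurationError("brightfield simulation requires fluorescence_mode off")
    rng = np.random.default_rng(config.seed)
    geom = _TubeGeometry(config)
    ny, nx = config.image_size
    s_grid, d_grid = geom.pixel_fields()
    r0_grid = geom.radius0(s_grid)
    lag_grid = geom.lag(s_grid)
    amp = config.wall_motion_amplitude
    omega = 2.0 * np.pi * config.beat_frequency

    # particles: arc parameter in [0,1), fixed fractional normal offset
    p_s = rng.uniform(0.0, 1.0, config.n_particles)
    p_u = rng.uniform(-0.75, 0.75, config.n_particles)

    frames = np.empty((config.n_frames, ny, nx), dtype=np.float32)
    phases = (np.arange(config.n_frames) * config.beat_frequency / config.frame_rate) % 1.0
    frame_class, frame_speed = _schedule_lookup(config, phases)
    half = int(np.ceil(4 * PARTICLE_SIGMA_PX))
    win = np.arange(-half, half + 1)

    for f in range(config.n_frames):
        t = f / config.frame_rate
        g = 1.0 - amp * (1.0 - np.cos(omega * t - lag_grid)) / 2.0
        r_t = r0_grid * g
        absd = np.abs(d_grid)
        s_in = np.clip((r_t - absd) / 1.0 + 0.5, 0.0, 1.0)
        s_out = np.clip((r_t + WALL_THICKNESS_UM - absd) / 1.0 + 0.5, 0.0, 1.0)
        img = (
            BRIGHT_BG * (1.0 - s_out)
            + BRIGHT_WALL * (s_out - s_in)
            + BRIGHT_LUMEN * s_in
        )

        # splat particles (dark spots) at their current positions
        g_p = 1.0 - amp * (1.0 - np.cos(omega * t - geom.lag(p_s))) / 2.0
        centers = geom.position_px(p_s) + (
            geom.normal_at(p_s)
            * (p_u * geom.radius0(p_s) * g_p / config.pixel_width)[:, None]
        )
        for cx_p, cy_p in centers:
            ix, iy = int(round(cx_p)), int(round(cy_p))
            xs = ix + win
            ys = iy + win
            ok_x = (xs >= 0) & (xs < nx)
            ok_y = (ys >= 0) & (ys < ny)
            if not ok_x.any() or not ok_y.any():
                continue
            gx = np.exp(-((xs[ok_x] - cx_p) ** 2) / (2 * PARTICLE_SIGMA_PX**2))
            gy = np.exp(-((ys[ok_y] - cy_p) ** 2) / (2 * PARTICLE_SIGMA_PX**2))
            img[np.ix_(ys[ok_y], xs[ok_x])] -= PARTICLE_DEPTH * np.outer(gy, gx)

        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        frames[f] = img

        # advect for the next frame (particle count is conserved: wrap)
        p_s = (p_s + frame_speed[f] / geom.length_um / config.frame_rate) % 1.0

    dia, sys_, peaks = _diastole_frames(config, geom)
    arc, diam = geom.true_diameter(0.0)
    truth = GroundTruth(
        period_frames=config.period_frames,
        true_fractions=config.true_fractions(),
        per_frame_flow_class=frame_class,
        cycle_boundaries=peaks if len(peaks) >= 2 else np.array([0, config.n_frames - 1]),
        true_diameter=diam,
        segment_arc_um=arc,
        diastole_frame=dia,
        systole_frame=sys_,
    )
    movie = MovieStack(
        pixels=frames,
        frame_rate=config.frame_rate,
        pixel_width=config.pixel_width,
        origin_label="beatkit-synthetic-brightfield",
    )
    return movie, truth


# ---------------------------------------------------------------------------
# fluorescence rendering (shared by plane series and expression stacks)


def _fluor_frame(rho_grid, r_t, a_grid, noise_sd, rng):
    img = FLUOR_BG + a_grid * np.exp(-((rho_grid - r_t) ** 2) / (2.0 * SIGMA_WALL_UM**2))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img.astype(np.float32)


def simulate_gcamp_plane_series(
    config: HeartSimConfig,
    n_planes: int = 50,
    z_step: float = 4.0,
    phase_offsets="random",
) -> tuple[list[MovieStack], GroundTruth]:
    """Plane-by-plane fluorescence movies with unknown per-plane phase.

    The tube is tilted in depth (ventral inflow first); plane p images depth
    ``p * z_step``. Each plane's acquisition starts at its phase offset in
    frames: frame f of plane p shows the heart at absolute frame f + o_p.
    Endocardial wall glow is elevated ``av_enrichment``-fold at the canal.
    """
    if not config.fluorescence_mode:
        raise ConfigurationError("plane-series simulation requires fluorescence_mode on")
    if n_planes < 2:
        raise ConfigurationError("need at least 2 planes")
    rng = np.random.default_rng(config.seed)
    geom = _TubeGeometry(config)
    if n_planes * z_step > geom.depth_um() + 1e-9:
        raise ConfigurationError(
            f"{n_planes} planes x {z_step} um exceed the simulated heart depth "
            f"({geom.depth_um():.0f} um)"
        )
    period = config.period_frames
    if isinstance(phase_offsets, str) and phase_offsets == "random":
        offsets = rng.integers(0, max(int(round(period)), 1), n_planes).astype(float)
    else:
        offsets = np.asarray(phase_offsets, dtype=float)
        if offsets.shape != (n_planes,):
            raise ConfigurationError("phase_offsets must have one entry per plane")
        offsets = offsets % period

    s_grid, d_grid = geom.pixel_fields()
    r0_grid = geom.radius0(s_grid)
    lag_grid = geom.lag(s_grid)
    a_grid = FLUOR_BASE * (
        1.0
        + (config.av_enrichment - 1.0)
        * np.exp(-(((s_grid - 0.5) / CANAL_WIDTH_S) ** 2))
    )
    zc_grid = geom.z_center(s_grid)
    amp = config.wall_motion_amplitude
    omega = 2.0 * np.pi * config.beat_frequency

    planes = []
    for p in range(n_planes):
        z_p = p * z_step
        rho = np.hypot(d_grid, z_p - zc_grid)
        frames = np.empty((config.n_frames, *config.image_size), dtype=np.float32)
        for f in range(config.n_frames):
            t = (f + offsets[p]) / config.frame_rate
            g = 1.0 - amp * (1.0 - np.cos(omega * t - lag_grid)) / 2.0
            frames[f] = _fluor_frame(rho, r0_grid * g, a_grid, config.noise_sd, rng)
        planes.append(
            MovieStack(
                pixels=frames,
                frame_rate=config.frame_rate,
                pixel_width=config.pixel_width,
                origin_label=f"beatkit-synthetic-gcamp-plane{p:02d}",
            )
        )

    dia, sys_, _ = _diastole_frames(config, geom)
    arc, diam = geom.true_diameter(0.0)
    truth = GroundTruth(
        period_frames=period,
        per_plane_phase_offset=offsets,
        true_diameter=diam,
        segment_arc_um=arc,
        diastole_frame=dia,
        systole_frame=sys_,
    )
    return planes, truth


def simulate_expression_stack(
    config: HeartSimConfig,
    profile_shape: np.ndarray,
    z_step: float = 4.0,
) -> tuple[ZStack, GroundTruth]:
    """Static (stopped-heart) z-stack with a per-segment wall-intensity profile.

    ``profile_shape`` is a non-negative multiplier per midline segment
    (length 100); rendered wall fluorescence along the tube follows it.
    """
    profile_shape = np.asarray(profile_shape, dtype=float)
    if profile_shape.shape != (N_TRUTH_SEGMENTS,):
        raise ConfigurationError(
            f"profile_shape must have {N_TRUTH_SEGMENTS} entries"
        )
    if np.any(profile_shape < 0):
        raise ConfigurationError("profile_shape multipliers must be non-negative")
    rng = np.random.default_rng(config.seed)
    geom = _TubeGeometry(config)
    s_grid, d_grid = geom.pixel_fields()
    r0_grid = geom.radius0(s_grid)
    r_t = r0_grid * geom.gate(s_grid, 0.0)

    _, _, bounds = geom.truth_segments()
    arc_grid = np.interp(s_grid, geom.s, geom.arc_um)
    seg_grid = np.clip(
        np.searchsorted(bounds, arc_grid, side="right") - 1, 0, N_TRUTH_SEGMENTS - 1
    )
    a_grid = FLUOR_BASE * profile_shape[seg_grid]
    zc_grid = geom.z_center(s_grid)

    z_lo = float(zc_grid.min() - geom.config.chamber_radii[0])
    z_hi = float(zc_grid.max() + geom.config.chamber_radii[0])
    n_planes = int(np.floor((z_hi - z_lo) / z_step)) + 1
    planes = np.empty((n_planes, *config.image_size), dtype=np.float32)
    for p in range(n_planes):
        rho = np.hypot(d_grid, (z_lo + p * z_step) - zc_grid)
        planes[p] = _fluor_frame(rho, r_t, a_grid, config.noise_sd, rng)

    arc, diam = geom.true_diameter(0.0)
    truth = GroundTruth(
        period_frames=config.period_frames,
        true_segment_intensity=FLUOR_BASE * profile_shape,
        true_diameter=diam,
        segment_arc_um=arc,
    )
    stack = ZStack(pixels=planes, z_step=z_step, pixel_width=config.pixel_width)
    return stack, truth


# ---------------------------------------------------------------------------
# nucleus detections (valve-counting oracle data)


def simulate_nucleus_detections(
    n_nuclei: int,
    seed: int,
    n_planes: int = 12,
    image_size: tuple[int, int] = (128, 160),
    pixel_width: float = 1.92,
    z_step: float = 1.0,
    link_radius_um: float = 3.0,
    jitter_um: float = 1.0,
    span_planes: tuple[int, int] = (2, 3),
) -> tuple[np.ndarray, int]:
    """Planted nucleus detections spanning a few adjacent planes each.

    Nuclei are placed with pairwise xy separation of at least 2.5x the link
    radius so that greedy chain linking and connected-component counting
    agree; returns ``(points (N, 3) of x, y, plane), true_count``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_size
    sep_px = 2.5 * link_radius_um / pixel_width
    centers = []
    attempts = 0
    while len(centers) < n_nuclei and attempts < 20000:
        attempts += 1
        cand = np.array([rng.uniform(5, nx - 5), rng.uniform(5, ny - 5)])
        if all(np.hypot(*(cand - c)) >= sep_px for c in centers):
            centers.append(cand)
    points = []
    for c in centers:
        span = int(rng.integers(span_planes[0], span_planes[1] + 1))
        start = int(rng.integers(0, max(n_planes - span, 1)))
        for dp in range(span):
            jitter = rng.uniform(-jitter_um, jitter_um, 2) / pixel_width
            points.append([c[0] + jitter[0], c[1] + jitter[1], start + dp])
    return np.asarray(points, dtype=float), len(centers)
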