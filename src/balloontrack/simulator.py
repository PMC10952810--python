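"""Closed-loop digital phantom: a virtual vessel phantom with a moving
Gd-bright balloon, rendered as saturation-prepared slice stacks.

The simulator stands in for the scanner: it honors whatever slice
prescriptions the controller requests and returns magnitude images plus
per-measurement ground truth. The signal model is deliberately simple —
saturation recovery after a reduced-flip-angle saturation pulse,

    S = m0 * (1 - (1 - cos(alpha)) * exp(-ts / T1)),

which captures the one thing the tracker consumes: short-T1 Gd solution
stays bright under partial saturation while blood and tissue are
attenuated. Fat is additionally scaled by a residual factor emulating
chemical-shift-selective fat suppression. Noise is Rician (magnitude of
a complex Gaussian), as in magnitude MR images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import controller as _controller
from . import detection as _detection
from .core import ImageStack, Mode, ShimBox, SlicePrescription, TrackingParams
from .session import SessionLog, SessionRecord

__all__ = [
    "TissueClass",
    "Sphere",
    "Box",
    "Phantom",
    "Trajectory",
    "GroundTruth",
    "psat_signal",
    "sphere_slab_overlap",
    "render_slice",
    "acquire",
    "run_closed_loop",
    "default_phantom",
    "decoy_phantom",
    "make_trajectory",
]


@dataclass(frozen=True)
class TissueClass:
    """Equilibrium signal and longitudinal relaxation of one tissue."""

    label: str
    m0: float
    t1: float  # ms

    def __post_init__(self) -> None:
        if self.m0 < 0 or self.t1 <= 0:
            raise ValueError("require m0 >= 0 and t1 > 0")


# Default contrast, in noise-sigma units at the Runtime working point
# (alpha 40 deg, ts 300 ms): balloon ~64, blood ~10, myocardium ~9,
# i.e. a balloon/blood CNR of ~54, the regime reported for 1.5 T pSAT
# imaging of a 1% Gd balloon. Blood must sit well below theta_run times
# the dimmest accepted balloon peak (a half-slab balloon at ~32), or the
# adaptive threshold would pull the vessel above threshold and merge the
# balloon into one oversized blood region.
BALLOON = TissueClass("balloon", m0=64.2, t1=50.0)
BLOOD = TissueClass("blood", m0=12.4, t1=1500.0)
MYOCARDIUM = TissueClass("myocardium", m0=11.0, t1=1100.0)
FAT = TissueClass("fat", m0=150.0, t1=300.0)
BACKGROUND = TissueClass("background", m0=0.0, t1=1000.0)


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float
    tissue: TissueClass

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center, dtype=float)
        return (d * d).sum(axis=-1) <= self.radius * self.radius


@dataclass(frozen=True)
class Box:
    lower: np.ndarray
    upper: np.ndarray
    tissue: TissueClass

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        return np.all((pts >= lo) & (pts <= hi), axis=-1)


@dataclass(frozen=True)
class FatShell:
    """Bright fat near the FOV edge: |x| or |z| in [inner, outer]."""

    inner: float = 150.0
    outer: float = 222.0
    tissue: TissueClass = FAT

    def contains(self, pts: np.ndarray) -> np.ndarray:
        m = np.maximum(np.abs(pts[..., 0]), np.abs(pts[..., 2]))
        return (m >= self.inner) & (m <= self.outer)


@dataclass(frozen=True, eq=False)
class Phantom:
    """Virtual vessel phantom: a blood-filled tube the balloon travels
    through, embedded in soft tissue with an optional chamber and an
    optional fat shell near the FOV edge."""

    vessel_path: np.ndarray  # (k, 3) polyline, mm
    vessel_radius: float
    shim_box: ShimBox
    chambers: tuple = ()
    fat_shell: Optional[FatShell] = None
    balloon_radius: float = 5.0
    noise_sigma: float = 1.0
    balloon_tissue: TissueClass = BALLOON
    blood_tissue: TissueClass = BLOOD
    background_tissue: TissueClass = MYOCARDIUM
    fat_residual: float = 0.1
    ts_ms: float = 300.0

    def __post_init__(self) -> None:
        path = np.asarray(self.vessel_path, dtype=float)
        if path.ndim != 2 or path.shape[1] != 3 or len(path) < 2:
            raise ValueError("vessel_path must be a (k>=2, 3) polyline")
        object.__setattr__(self, "vessel_path", path)
        if self.vessel_radius <= 0 or self.balloon_radius <= 0:
            raise ValueError("radii must be positive")
        if not self.shim_box.contains(path).all():
            raise ValueError("vessel path must lie inside the shim box")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vessel_path, axis=0), axis=1)

    @property
    def path_length(self) -> float:
        return float(self.segment_lengths.sum())

    def point_at(self, arclength: float) -> np.ndarray:
        """Balloon center at a given arc length along the vessel path."""
        s = float(np.clip(arclength, 0.0, self.path_length))
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(self.vessel_path) - 2)
        seg = self.segment_lengths[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return (1 - t) * self.vessel_path[i] + t * self.vessel_path[i + 1]

    def validate_balloon(self, params: TrackingParams, margin: float = 2.0) -> None:
        if self.balloon_radius > params.r_max - margin:
            raise ValueError(
                f"balloon radius {self.balloon_radius} too close to the "
                f"size-filter bound r_max={params.r_max} (margin {margin})"
            )


def psat_signal(m0: float, t1: float, alpha: float, ts: float):
    """Saturation-recovery signal after a partial-saturation pulse.

    ``alpha`` in degrees, ``ts`` (recovery time) and ``t1`` in ms.
    Monotone increasing in ts; decreasing in alpha on [0, 90] deg.
    """
    if np.any(np.asarray(t1) <= 0) or np.any(np.asarray(ts) < 0):
        raise ValueError("require t1 > 0 and ts >= 0")
    return m0 * (1.0 - (1.0 - np.cos(np.deg2rad(alpha))) * np.exp(-ts / t1))


def sphere_slab_overlap(
    center_z: float, radius: float, slab_lo: float, slab_hi: float
) -> float:
    """Fraction of a sphere's volume inside the slab [slab_lo, slab_hi]."""
    if radius <= 0 or slab_lo >= slab_hi:
        raise ValueError("require radius > 0 and slab_lo < slab_hi")
    r = radius

    def vol_below(z: float) -> float:
        h = np.clip(z - (center_z - r), 0.0, 2.0 * r)
        return math.pi * h * h * (3.0 * r - h) / 3.0

    total = 4.0 / 3.0 * math.pi * r**3
    return float((vol_below(slab_hi) - vol_below(slab_lo)) / total)


def _dist_to_polyline(pts: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Min distance from each point (..., 3) to a polyline (k, 3)."""
    a = path[:-1]  # (k-1, 3)
    d = path[1:] - a
    seg_len2 = (d * d).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    # broadcast: pts (..., 1, 3) against segments (k-1, 3)
    rel = pts[..., None, :] - a
    t = np.clip((rel * d).sum(axis=-1) / seg_len2, 0.0, 1.0)
    diff = rel - t[..., None] * d
    dist2 = (diff * diff).sum(axis=-1)
    return np.sqrt(dist2.min(axis=-1))


def _vessel_mask(phantom: Phantom, prescription: SlicePrescription) -> np.ndarray:
    """In-vessel pixel mask on the slab center plane, with the polyline
    prefiltered to segments that can come within vessel_radius of it."""
    pts = prescription.pixel_grid_world()
    n = prescription.normal
    z0 = float(prescription.center @ n)
    path = phantom.vessel_path
    dz = np.abs(path @ n - z0)
    # plane distance is linear along a segment, so its minimum sits at an
    # endpoint unless the segment straddles the plane
    reach = phantom.vessel_radius + 1e-9
    straddle = ((path[:-1] @ n - z0) * (path[1:] @ n - z0)) <= 0
    keep = (np.minimum(dz[:-1], dz[1:]) <= reach) | straddle
    if not keep.any():
        return np.zeros(pts.shape[:2], dtype=bool)
    out = np.zeros(pts.shape[:2], dtype=bool)
    for i in np.flatnonzero(keep):
        out |= _dist_to_polyline(pts, path[i: i + 2]) <= phantom.vessel_radius
    return out


# Cache of the static (vessel + chambers + fat + background, noiseless)
# rendering per prescription geometry and flip angle; slice prescriptions
# recur heavily across a session. Bounded FIFO to keep memory flat.
_STATIC_CACHE: dict = {}
_STATIC_CACHE_MAX = 512


def _geometry_key(phantom: Phantom, p: SlicePrescription, alpha: float) -> tuple:
    return (
        id(phantom), float(alpha), p.matrix, p.fov, p.thickness,
        p.center.tobytes(), p.normal.tobytes(),
        p.axis_u.tobytes(), p.axis_v.tobytes(),
    )


def _static_base(
    phantom: Phantom, prescription: SlicePrescription, alpha: float
) -> np.ndarray:
    key = _geometry_key(phantom, prescription, alpha)
    hit = _STATIC_CACHE.get(key)
    if hit is not None:
        return hit
    ts = phantom.ts_ms
    pts = prescription.pixel_grid_world()
    img = np.full(
        pts.shape[:2],
        psat_signal(phantom.background_tissue.m0, phantom.background_tissue.t1,
                    alpha, ts),
        dtype=float,
    )
    if phantom.fat_shell is not None:
        fat = phantom.fat_shell.tissue
        val = psat_signal(fat.m0 * phantom.fat_residual, fat.t1, alpha, ts)
        img[phantom.fat_shell.contains(pts)] = val
    for body in phantom.chambers:
        val = psat_signal(body.tissue.m0, body.tissue.t1, alpha, ts)
        img[body.contains(pts)] = val
    img[_vessel_mask(phantom, prescription)] = psat_signal(
        phantom.blood_tissue.m0, phantom.blood_tissue.t1, alpha, ts
    )
    if len(_STATIC_CACHE) >= _STATIC_CACHE_MAX:
        _STATIC_CACHE.pop(next(iter(_STATIC_CACHE)))
    _STATIC_CACHE[key] = img
    return img


def render_slice(
    phantom: Phantom,
    balloon_center,
    prescription: SlicePrescription,
    alpha: float,
    seed,
    noise_sigma: Optional[float] = None,
) -> np.ndarray:
    """Render one magnitude slice of the phantom.

    Tissue is sampled at each pixel's world position on the slab center
    plane; the balloon is painted as a disk of the sphere's in-slab
    cross-section radius, scaled by the sphere/slab volume-overlap
    fraction (partial-volume dimming). Deterministic for a fixed seed.
    """
    balloon_center = np.asarray(balloon_center, dtype=float)
    ts = phantom.ts_ms
    img = _static_base(phantom, prescription, alpha).copy()

    # balloon: partial-volume painting
    lo, hi = prescription.slab_bounds()
    bz = float(balloon_center @ prescription.normal)
    r = phantom.balloon_radius
    if bz + r > lo and bz - r < hi:
        overlap = sphere_slab_overlap(bz, r, lo, hi)
        if overlap > 0:
            if lo <= bz <= hi:
                r_cross = r
            else:
                d_edge = min(abs(bz - lo), abs(bz - hi))
                r_cross = math.sqrt(max(r * r - d_edge * d_edge, 0.0))
            if r_cross > 0:
                row_b, col_b = prescription.world_to_pixel(balloon_center)
                sp = prescription.pixel_spacing
                idx = np.arange(prescription.matrix, dtype=float)
                rr, cc = np.meshgrid(idx, idx, indexing="ij")
                inplane = (
                    ((rr - row_b) * sp) ** 2 + ((cc - col_b) * sp) ** 2
                ) <= r_cross * r_cross
                bval = overlap * psat_signal(
                    phantom.balloon_tissue.m0, phantom.balloon_tissue.t1, alpha, ts
                )
                img[inplane] = np.maximum(img[inplane], bval)

    sigma = phantom.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0.0, sigma, img.shape)
        g2 = rng.normal(0.0, sigma, img.shape)
        img = np.hypot(img + g1, g2)
    return img


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Balloon motion script: arc-length position along the vessel path
    per measurement, plus flagged leap events (instant displacements
    larger than the Runtime stack's through-plane span)."""

    arclengths: np.ndarray
    leap_measurements: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "arclengths", np.asarray(self.arclengths, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.arclengths)

    def position(self, phantom: Phantom, measurement_index: int) -> np.ndarray:
        return phantom.point_at(self.arclengths[measurement_index])

    def is_leap(self, measurement_index: int) -> bool:
        return measurement_index in self.leap_measurements

    def validate(self, phantom: Phantom, params: TrackingParams) -> None:
        """Non-leap consecutive displacements must respect d_disp_max."""
        pos = np.stack(
            [self.position(phantom, k) for k in range(len(self))]
        )
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for k, s in enumerate(step, start=1):
            if k not in self.leap_measurements and s > params.d_disp_max + 1e-9:
                raise ValueError(
                    f"unflagged displacement {s:.1f} mm at measurement {k} "
                    f"exceeds d_disp_max={params.d_disp_max}"
                )


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """True balloon state for one measurement."""

    balloon_center: np.ndarray
    overlaps: np.ndarray  # per acquired slice, volume-overlap fraction
    is_leap: bool = False

    @property
    def max_overlap(self) -> float:
        return float(self.overlaps.max()) if len(self.overlaps) else 0.0


def _slice_seed(seed: int, measurement_index: int, slice_index: int):
    return np.random.SeedSequence([int(seed), measurement_index, slice_index])


def acquire(
    phantom: Phantom,
    trajectory: Trajectory,
    request: "_controller.StackRequest",
    measurement_index: int,
    seed: int,
    params: TrackingParams,
) -> tuple[ImageStack, GroundTruth]:
    """Acquire one measurement: render every requested slice at the
    balloon's current position; deterministic given the seed."""
    center = trajectory.position(phantom, measurement_index)
    alpha = params.alpha_cal if request.mode is Mode.CALIBRATION else params.alpha_run
    images = []
    overlaps = []
    for i, p in enumerate(request.prescriptions):
        images.append(
            render_slice(phantom, center, p, alpha,
                         _slice_seed(seed, measurement_index, i))
        )
        lo, hi = p.slab_bounds()
        overlaps.append(
            sphere_slab_overlap(float(center @ p.normal),
                                phantom.balloon_radius, lo, hi)
        )
    stack = ImageStack(
        intensities=np.stack(images),
        prescriptions=request.prescriptions,
        mode_tag=request.mode,
    )
    truth = GroundTruth(
        balloon_center=center,
        overlaps=np.asarray(overlaps),
        is_leap=trajectory.is_leap(measurement_index),
    )
    return stack, truth


def run_closed_loop(
    phantom: Phantom,
    trajectory: Trajectory,
    params: TrackingParams,
    geometry: Optional["_controller.TrackerGeometry"] = None,
    n_measurements: Optional[int] = None,
    seed: int = 0,
    latency: int = 1,
) -> SessionLog:
    """Exercise the full framework: controller -> acquire -> detect -> step.

    The prescription emitted after measurement ``k`` takes effect at
    measurement ``k + latency`` (default 1). Fully reproducible from the
    seed; same seed gives a bit-identical session log.
    """
    if geometry is None:
        geometry = _controller.TrackerGeometry()
    if n_measurements is None:
        n_measurements = len(trajectory)
    if n_measurements > len(trajectory):
        raise ValueError("trajectory shorter than n_measurements")
    if latency < 1:
        raise ValueError("latency must be >= 1")
    phantom.validate_balloon(params)

    log = SessionLog(params=params)
    state, request = _controller.initial_request(geometry, params)
    from collections import deque

    pending = deque([request] * latency)
    for k in range(n_measurements):
        eff = pending.popleft()
        stack, truth = acquire(phantom, trajectory, eff, k, seed, params)
        ctx = _detection.DetectionContext(
            mode=eff.mode,
            params=params,
            shim_box=phantom.shim_box,
            prev_position=state.last_position,
        )
        det = _detection.detect_balloon(stack, ctx)
        state, nxt = _controller.step(state, eff, det, params, geometry)
        pending.append(nxt)
        central = eff.prescriptions[eff.central_index if eff.mode is Mode.RUNTIME
                                    else len(eff.prescriptions) // 2]
        log.append(
            SessionRecord(
                measurement_index=k,
                mode=eff.mode,
                central_offset=float(central.center @ central.normal),
                found=det.found,
                slice_index=det.region.slice_index if det.found else -1,
                position=(None if not det.found
                          else np.asarray(det.position_world)),
                peak=det.region.peak_intensity if det.found else float("nan"),
                lost_count=state.lost_count,
                true_center=truth.balloon_center,
                max_overlap=truth.max_overlap,
                is_leap=truth.is_leap,
            )
        )
    return log


# ----------------------------------------------------------------------
# Phantom presets and trajectory scenarios


def _default_path(n_vertices: int = 41) -> np.ndarray:
    """A smooth 3D vessel course inside the shim box, with substantial
    through-plane (y) excursion so slice following is exercised."""
    t = np.linspace(0.0, 1.0, n_vertices)
    x = -100.0 + 200.0 * t
    y = 38.0 * np.sin(1.8 * np.pi * t)
    z = -100.0 + 200.0 * t + 25.0 * np.sin(3.0 * np.pi * t)
    return np.column_stack([x, y, z])


def default_shim_box() -> ShimBox:
    return ShimBox(lower=(-130.0, -55.0, -130.0), upper=(130.0, 55.0, 130.0))


def default_phantom(noise_sigma: float = 1.0) -> Phantom:
    """The standard virtual vessel phantom.

    The vessel tube radius (9 mm) deliberately exceeds the balloon-radius
    bound, so bare vessel cross-sections fail the size/shape filter when
    the adaptive threshold drops in balloon-absent frames.
    """
    return Phantom(
        vessel_path=_default_path(),
        vessel_radius=9.0,
        shim_box=default_shim_box(),
        chambers=(
            Sphere(center=np.array([-40.0, 10.0, 60.0]), radius=30.0,
                   tissue=BLOOD),
        ),
        fat_shell=FatShell(),
        balloon_radius=5.0,
        noise_sigma=noise_sigma,
    )


def decoy_phantom(noise_sigma: float = 1.0) -> Phantom:
    """Phantom for false-positive stress tests: every hyperintense
    structure other than the balloon violates the size/shape bound
    (wide vessel, large bright chamber, broad fat shell)."""
    return Phantom(
        vessel_path=_default_path(),
        vessel_radius=12.0,
        shim_box=default_shim_box(),
        chambers=(
            Sphere(center=np.array([-40.0, 10.0, 60.0]), radius=35.0,
                   tissue=BLOOD),
            Box(lower=np.array([30.0, -30.0, -90.0]),
                upper=np.array([90.0, 30.0, -40.0]), tissue=BLOOD),
        ),
        fat_shell=FatShell(),
        balloon_radius=5.0,
        noise_sigma=noise_sigma,
    )


def _leap_target(phantom: Phantom, s_from: float, min_dy: float = 40.0) -> float:
    """First arc length whose through-plane (y) coordinate differs from
    the current one by at least ``min_dy`` — guarantees the balloon
    leaves the three-slice Runtime span."""
    y0 = phantom.point_at(s_from)[1]
    total = phantom.path_length
    for s in np.linspace(0.0, total, 400):
        if abs(phantom.point_at(s)[1] - y0) >= min_dy:
            return float(s)
    raise ValueError("phantom path has insufficient through-plane range")


def make_trajectory(
    scenario: str,
    phantom: Phantom,
    n_measurements: int,
    params: TrackingParams,
    speed: float = 4.0,
    start: float = 30.0,
    seed: int = 0,
) -> Trajectory:
    """Named balloon-motion scenarios.

    - ``stationary``: balloon fixed at ``start`` mm arc length.
    - ``crawl``: constant ``speed`` mm per measurement along the vessel,
      reflecting at the path ends; respects the displacement bound.
    - ``leap``: crawl with one scripted through-plane leap at the
      midpoint.
    - ``phantom99``: 99 measurements with two scripted leaps, emulating
      a navigation run in which the catheter is twice deliberately moved
      beyond the Runtime stack's through-plane range.
    """
    if scenario == "phantom99":
        n_measurements = 99
    if speed > params.d_disp_max:
        raise ValueError("crawl speed must respect d_disp_max")
    total = phantom.path_length

    def reflect(s: float) -> float:
        period = 2.0 * total
        s = s % period
        return s if s <= total else period - s

    if scenario == "stationary":
        arcs = np.full(n_measurements, start)
        leaps: set[int] = set()
    elif scenario == "crawl":
        arcs = np.array([reflect(start + speed * k) for k in range(n_measurements)])
        leaps = set()
    elif scenario in ("leap", "phantom99"):
        leap_at = ([n_measurements // 2] if scenario == "leap"
                   else [40, 75])
        arcs = np.empty(n_measurements)
        leaps = set(leap_at)
        s = start
        direction = 1.0
        for k in range(n_measurements):
            if k in leaps:
                s = _leap_target(phantom, s)
            arcs[k] = s
            s_next = s + direction * speed
            if s_next > total or s_next < 0.0:
                direction = -direction
                s_next = s + direction * speed
            s = s_next
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    traj = Trajectory(arclengths=arcs, leap_measurements=frozenset(leaps))
    traj.validate(phantom, params)
    return traj
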