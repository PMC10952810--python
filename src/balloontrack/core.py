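"""Shared geometry, tracking parameters, and data contracts.

World coordinates are a right-handed patient-style frame in millimeters.
Every module interface exchanges millimeters; pixel indices appear only
inside the detection pipeline. Pixel indexing is 0-based and the pixel
``(i, j)`` center maps to continuous coordinates ``(i, j)``. A slice slab
is the half-open interval ``[c·n - t/2, c·n + t/2)`` along its normal, so
contiguous slices partition space without overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "Mode",
    "TrackingParams",
    "SlicePrescription",
    "ImageStack",
    "ShimBox",
    "Region",
    "Detection",
    "pixel_to_world",
    "world_in_shimbox",
]

_ORTHO_TOL = 1e-9


class Mode(str, enum.Enum):
    """Acquisition mode of a stack or of the tracker."""

    CALIBRATION = "CALIBRATION"
    RUNTIME = "RUNTIME"


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class TrackingParams:
    """User-adjustable parameters of the tracking framework.

    Attributes
    ----------
    d_cal, d_run
        Calibration / Runtime slice thickness in mm.
    n_cal
        Number of Calibration slices (10-20); the fixed stack covers the
        anatomy of interest for (re)localization without a prior position.
    n_run
        Number of Runtime slices; odd, so a central slice exists.
    alpha_run, alpha_cal
        Partial-saturation flip angles in degrees. 90 deg (Calibration)
        fully saturates tissue so only the short-T1 Gd balloon stays
        bright; 30-50 deg (Runtime) preserves anatomical context.
    beta_fat
        Fat-saturation angle in degrees.
    theta_cal, theta_run
        Binarization thresholds as fractions of the stack maximum.
    r_max
        Upper bound on the balloon radius, mm; drives the size/shape
        filter (area <= pi*r_max^2, max extent from COM <= r_max).
    d_disp_max
        Maximum plausible inter-measurement balloon displacement, mm;
        drives the temporal-consistency filter.
    lost_limit
        Consecutive lost Runtime measurements tolerated before the
        tracker falls back to Calibration (switch fires when the count
        exceeds this value).
    """

    d_cal: float = 10.0
    d_run: float = 10.0
    n_cal: int = 12
    n_run: int = 3
    alpha_run: float = 40.0
    alpha_cal: float = 90.0
    beta_fat: float = 90.0
    theta_cal: float = 0.90
    theta_run: float = 0.40
    r_max: float = 8.0
    d_disp_max: float = 14.0
    lost_limit: int = 5

    def __post_init__(self) -> None:
        for name in ("d_cal", "d_run", "r_max", "d_disp_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("theta_cal", "theta_run"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (10 <= int(self.n_cal) <= 20):
            raise ValueError("n_cal must be an integer in [10, 20]")
        if int(self.n_run) < 1 or int(self.n_run) % 2 == 0:
            raise ValueError("n_run must be a positive odd integer")
        if int(self.lost_limit) < 0:
            raise ValueError("lost_limit must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingParams":
        """Build from a flat key/value mapping; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown tracking parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True, eq=False)
class SlicePrescription:
    """An oriented slab in world mm: the unit the controller repositions.

    ``axis_u`` spans image rows, ``axis_v`` spans image columns; the
    in-plane pixel grid is centered on ``center`` (pixel
    ``((matrix-1)/2, (matrix-1)/2)`` maps to the slice center).
    """

    center: np.ndarray
    normal: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    thickness: float
    fov: float = 450.0
    matrix: int = 160

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        for name in ("normal", "axis_u", "axis_v"):
            v = _as_vec3(getattr(self, name), name)
            object.__setattr__(self, name, v)
        if not (self.thickness > 0 and self.fov > 0 and int(self.matrix) > 0):
            raise ValueError("thickness, fov and matrix must be positive")
        frame = np.stack([self.axis_u, self.axis_v, self.normal])
        gram = frame @ frame.T
        if not np.allclose(gram, np.eye(3), atol=_ORTHO_TOL, rtol=0.0):
            raise ValueError("axis_u, axis_v, normal must be mutually orthonormal")

    @property
    def pixel_spacing(self) -> float:
        """In-plane pixel size, mm (fov / matrix)."""
        return self.fov / self.matrix

    def pixel_to_world(self, row, col) -> np.ndarray:
        """Map continuous pixel coordinates to world mm (on the slice plane)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        if not (np.all(np.isfinite(row)) and np.all(np.isfinite(col))):
            raise ValueError("pixel coordinates must be finite")
        c = (self.matrix - 1) / 2.0
        sp = self.pixel_spacing
        du = (row - c) * sp
        dv = (col - c) * sp
        return (
            self.center
            + np.multiply.outer(du, self.axis_u)
            + np.multiply.outer(dv, self.axis_v)
        )

    def world_to_pixel(self, pt) -> tuple[float, float]:
        """Inverse of :meth:`pixel_to_world` for the in-plane component."""
        pt = _as_vec3(pt, "pt")
        c = (self.matrix - 1) / 2.0
        sp = self.pixel_spacing
        d = pt - self.center
        return (float(d @ self.axis_u) / sp + c, float(d @ self.axis_v) / sp + c)

    def normal_offset(self, pt) -> float:
        """Signed through-plane distance of a world point from the slice plane."""
        pt = _as_vec3(pt, "pt")
        return float((pt - self.center) @ self.normal)

    def slab_bounds(self) -> tuple[float, float]:
        """Half-open slab interval [lo, hi) along the normal, in mm."""
        z = float(self.center @ self.normal)
        return z - self.thickness / 2.0, z + self.thickness / 2.0

    def pixel_grid_world(self) -> np.ndarray:
        """World coordinates of every pixel center, shape (matrix, matrix, 3).

        Computed once per prescription and cached (prescriptions are
        immutable).
        """
        cached = getattr(self, "_grid_cache", None)
        if cached is None:
            idx = np.arange(self.matrix, dtype=float)
            rr, cc = np.meshgrid(idx, idx, indexing="ij")
            c = (self.matrix - 1) / 2.0
            sp = self.pixel_spacing
            cached = (
                self.center
                + ((rr - c) * sp)[..., None] * self.axis_u
                + ((cc - c) * sp)[..., None] * self.axis_v
            )
            object.__setattr__(self, "_grid_cache", cached)
        return cached


def pixel_to_world(p: SlicePrescription, row, col) -> np.ndarray:
    """Functional alias for :meth:`SlicePrescription.pixel_to_world`."""
    return p.pixel_to_world(row, col)


@dataclass(frozen=True)
class ShimBox:
    """Axis-aligned world-mm box restricting detection to the anatomy of
    interest (rejects spurious FOV-edge / fat signal)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", _as_vec3(self.lower, "lower"))
        object.__setattr__(self, "upper", _as_vec3(self.upper, "upper"))
        if not np.all(self.lower < self.upper):
            raise ValueError("shim box requires lower < upper componentwise")

    def contains(self, pts) -> np.ndarray:
        """Closed-box membership test; broadcasts over leading axes."""
        pts = np.asarray(pts, dtype=float)
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=-1)


def world_in_shimbox(pt, box: ShimBox) -> bool:
    """True iff ``pt`` lies inside the closed shim box."""
    return bool(box.contains(_as_vec3(pt, "pt")))


@dataclass(eq=False)
class ImageStack:
    """Ordered set of contiguous slices with per-slice prescriptions."""

    intensities: np.ndarray
    prescriptions: tuple[SlicePrescription, ...]
    mode_tag: Mode

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.prescriptions = tuple(self.prescriptions)
        self.mode_tag = Mode(self.mode_tag)
        n = len(self.prescriptions)
        if n == 0:
            raise ValueError("stack must contain at least one slice")
        m = self.prescriptions[0].matrix
        if self.intensities.shape != (n, m, m):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{n} slices of matrix {m}"
            )
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")
        p0 = self.prescriptions[0]
        for k, p in enumerate(self.prescriptions[1:], start=1):
            if not np.allclose(p.normal, p0.normal, atol=1e-9):
                raise ValueError("all slices must share the same normal")
            expect = self.prescriptions[k - 1].center + p.thickness * p.normal
            if not np.allclose(p.center, expect, atol=1e-6):
                raise ValueError(
                    "slices must be contiguous (centers spaced by thickness "
                    "along the shared normal)"
                )

    def __len__(self) -> int:
        return len(self.prescriptions)


@dataclass(eq=False)
class Region:
    """A contiguous hyperintense region in one slice."""

    slice_index: int
    pixels: np.ndarray  # (k, 2) int array of (row, col)
    area_mm2: float
    com_inplane: tuple[float, float]
    com_world: np.ndarray
    peak_intensity: float
    mean_intensity: float

    def first_pixel_rank(self) -> int:
        """Row-major rank of the region's first pixel (deterministic tie-break)."""
        rows = self.pixels[:, 0]
        cols = self.pixels[:, 1]
        return int(np.min(rows * np.iinfo(np.int32).max + cols))


@dataclass(eq=False)
class Detection:
    """The per-measurement balloon estimate."""

    found: bool
    region: Optional[Region] = None
    position_world: Optional[np.ndarray] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.found != (self.region is not None and self.position_world is not None):
            raise ValueError("found must match presence of region and position")
        if self.position_world is not None:
            self.position_world = _as_vec3(self.position_world, "position_world")

    @classmethod
    def not_found(cls, degenerate: bool = False) -> "Detection":
        return cls(found=False, degenerate=degenerate)
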