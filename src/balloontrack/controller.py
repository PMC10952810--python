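"""Two-mode acquisition state machine with slice following.

The tracker starts in Calibration mode (a fixed stack of thin slices
covering the anatomy). Once the balloon is found, it switches to Runtime
mode: a small odd stack of contiguous slices initially centered on the
balloon. If the balloon is then detected in an outer slice, the stack is
shifted by exactly one slice thickness toward that slice; if it is lost
for more than ``lost_limit`` consecutive Runtime measurements, the
tracker falls back to Calibration and re-localizes without a prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import Mode, SlicePrescription, TrackingParams, _as_vec3

__all__ = [
    "TrackerGeometry",
    "TrackerState",
    "StackRequest",
    "initial_request",
    "position_runtime_stack",
    "step",
    "force_calibration",
]


def _unit(v, name: str) -> np.ndarray:
    v = _as_vec3(v, name)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"{name} must be nonzero")
    return v / n


@dataclass(frozen=True)
class TrackerGeometry:
    """Configured slice orientations, in world mm.

    The Calibration stack is fixed at ``cal_center`` along ``cal_normal``
    (coronal by default, anterior-posterior being the smallest body
    dimension). Runtime slices keep the configured in-plane placement
    and orientation; only their through-plane offset follows the balloon.
    """

    cal_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cal_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    cal_axis_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    cal_axis_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    run_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    run_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    run_axis_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    run_axis_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    fov: float = 450.0
    matrix: int = 160

    def __post_init__(self) -> None:
        object.__setattr__(self, "cal_center", _as_vec3(self.cal_center, "cal_center"))
        object.__setattr__(self, "run_center", _as_vec3(self.run_center, "run_center"))
        for name in ("cal_normal", "cal_axis_u", "cal_axis_v",
                     "run_normal", "run_axis_u", "run_axis_v"):
            object.__setattr__(self, name, _unit(getattr(self, name), name))
        for frame in (("cal_axis_u", "cal_axis_v", "cal_normal"),
                      ("run_axis_u", "run_axis_v", "run_normal")):
            m = np.stack([getattr(self, n) for n in frame])
            if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
                raise ValueError(f"{frame} must be mutually orthonormal")


@dataclass(frozen=True)
class TrackerState:
    """Mutable-by-replacement tracker state between measurements."""

    mode: Mode = Mode.CALIBRATION
    lost_count: int = 0
    runtime_offset: Optional[float] = None
    last_position: Optional[np.ndarray] = None
    measurement_index: int = 0

    def __post_init__(self) -> None:
        if self.mode is Mode.RUNTIME and self.runtime_offset is None:
            raise ValueError("RUNTIME state requires a runtime_offset")


@dataclass(frozen=True)
class StackRequest:
    """What the scanner (or simulator) is asked to acquire next."""

    mode: Mode
    prescriptions: tuple[SlicePrescription, ...]

    def __post_init__(self) -> None:
        if self.mode is Mode.RUNTIME and len(self.prescriptions) % 2 == 0:
            raise ValueError("Runtime request needs an odd slice count")

    @property
    def central_index(self) -> int:
        return len(self.prescriptions) // 2


def _contiguous_prescriptions(
    central_center: np.ndarray,
    normal: np.ndarray,
    axis_u: np.ndarray,
    axis_v: np.ndarray,
    n_slices: int,
    thickness: float,
    fov: float,
    matrix: int,
) -> tuple[SlicePrescription, ...]:
    mid = (n_slices - 1) / 2.0
    return tuple(
        SlicePrescription(
            center=central_center + (i - mid) * thickness * normal,
            normal=normal,
            axis_u=axis_u,
            axis_v=axis_v,
            thickness=thickness,
            fov=fov,
            matrix=matrix,
        )
        for i in range(n_slices)
    )


def calibration_request(
    geometry: TrackerGeometry, params: TrackingParams
) -> StackRequest:
    """The fixed Calibration stack: n_cal contiguous slices about cal_center."""
    return StackRequest(
        mode=Mode.CALIBRATION,
        prescriptions=_contiguous_prescriptions(
            geometry.cal_center,
            geometry.cal_normal,
            geometry.cal_axis_u,
            geometry.cal_axis_v,
            params.n_cal,
            params.d_cal,
            geometry.fov,
            geometry.matrix,
        ),
    )


def initial_request(
    geometry: TrackerGeometry, params: TrackingParams
) -> tuple[TrackerState, StackRequest]:
    """Start a session: Calibration mode, no prior position."""
    state = TrackerState(mode=Mode.CALIBRATION, lost_count=0,
                         runtime_offset=None, last_position=None,
                         measurement_index=0)
    return state, calibration_request(geometry, params)


def _runtime_request(
    runtime_offset: float, geometry: TrackerGeometry, params: TrackingParams
) -> StackRequest:
    n = geometry.run_normal
    base = geometry.run_center - float(geometry.run_center @ n) * n
    central = base + runtime_offset * n
    return StackRequest(
        mode=Mode.RUNTIME,
        prescriptions=_contiguous_prescriptions(
            central, n, geometry.run_axis_u, geometry.run_axis_v,
            params.n_run, params.d_run, geometry.fov, geometry.matrix,
        ),
    )


def position_runtime_stack(
    balloon_pos, geometry: TrackerGeometry, params: TrackingParams
) -> tuple[StackRequest, float]:
    """Place the Runtime stack so the balloon sits at the central slab's
    mid-plane; in-plane placement is taken from the configured geometry."""
    balloon_pos = _as_vec3(balloon_pos, "balloon_pos")
    offset = float(balloon_pos @ geometry.run_normal)
    return _runtime_request(offset, geometry, params), offset


def step(
    state: TrackerState,
    request: StackRequest,
    detection,
    params: TrackingParams,
    geometry: TrackerGeometry,
) -> tuple[TrackerState, StackRequest]:
    """Advance the state machine by one measurement.

    ``detection`` must have been produced from ``request``. Transitions
    are keyed on the acquired request's mode, which equals the state's
    mode at the default one-measurement feedback latency; with a longer
    configured latency, stale acquisitions are then handled uniformly.
    """
    mode = request.mode
    k = state.measurement_index + 1

    if mode is Mode.CALIBRATION:
        if detection.found:
            next_request, offset = position_runtime_stack(
                detection.position_world, geometry, params
            )
            new_state = TrackerState(
                mode=Mode.RUNTIME, lost_count=0, runtime_offset=offset,
                last_position=np.array(detection.position_world, dtype=float),
                measurement_index=k,
            )
            return new_state, next_request
        new_state = replace(state, mode=Mode.CALIBRATION, lost_count=0,
                            measurement_index=k)
        return new_state, calibration_request(geometry, params)

    # Runtime measurement
    if detection.found:
        rel = detection.region.slice_index - request.central_index
        offset = state.runtime_offset
        if offset is None:  # stale-latency edge: recover offset from request
            central = request.prescriptions[request.central_index]
            offset = float(central.center @ geometry.run_normal)
        if rel == 0:
            next_request = request  # identical prescriptions, bitwise
        else:
            offset = offset + math.copysign(params.d_run, rel)
            next_request = _runtime_request(offset, geometry, params)
        new_state = TrackerState(
            mode=Mode.RUNTIME, lost_count=0, runtime_offset=offset,
            last_position=np.array(detection.position_world, dtype=float),
            measurement_index=k,
        )
        return new_state, next_request

    lost = state.lost_count + 1
    if lost > params.lost_limit:
        new_state = TrackerState(
            mode=Mode.CALIBRATION, lost_count=0, runtime_offset=None,
            last_position=None, measurement_index=k,
        )
        return new_state, calibration_request(geometry, params)
    new_state = replace(state, lost_count=lost, measurement_index=k)
    return new_state, request


def force_calibration(
    state: TrackerState, geometry: TrackerGeometry, params: TrackingParams
) -> tuple[TrackerState, StackRequest]:
    """Manual override (the operator's pedal): drop to Calibration now."""
    new_state = TrackerState(
        mode=Mode.CALIBRATION, lost_count=0, runtime_offset=None,
        last_position=None, measurement_index=state.measurement_index,
    )
    return new_state, calibration_request(geometry, params)
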