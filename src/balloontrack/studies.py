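"""Canned simulation studies mirroring the phantom evaluation protocol.

Each study runs the full pipeline from scratch — phantom, trajectory,
closed loop (or generated stacks), detection, outcome classification —
and reports a pooled metric. Per-session seeds are derived from one base
seed, so every study is reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .controller import TrackerGeometry, position_runtime_stack
from .core import Mode, TrackingParams
from .detection import DetectionContext, detect_balloon
from .evaluation import Outcome, add_outcomes, detection_accuracy
from .simulator import (
    Trajectory,
    acquire,
    decoy_phantom,
    default_phantom,
    make_trajectory,
    run_closed_loop,
)

__all__ = [
    "derive_seed",
    "calibration_accuracy_study",
    "runtime_accuracy_study",
    "false_positive_study",
]


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-session seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), index])
               .generate_state(1)[0] % (2**31))


def _session_logs(base_seed, n_sessions, n_measurements, scenarios, params,
                  phantom):
    """Closed-loop logs over a deterministic spread of trajectories."""
    length = phantom.path_length
    for i in range(n_sessions):
        seed = derive_seed(base_seed, i)
        scenario = scenarios[i % len(scenarios)]
        start = 15.0 + (i * 17.0) % max(length - 30.0, 1.0)
        speed = 2.0 + 0.25 * (i % 9)  # <= 4 mm/measurement
        traj = make_trajectory(scenario, phantom, n_measurements, params,
                               speed=speed, start=start)
        yield run_closed_loop(phantom, traj, params,
                              n_measurements=n_measurements, seed=seed)


def calibration_accuracy_study(
    base_seed: int,
    n_sessions: int = 20,
    n_measurements: int = 30,
    params: TrackingParams | None = None,
) -> dict:
    """Pooled percentage of Calibration-mode measurements with a correct
    detection, over clean closed-loop sessions (stationary or slow
    balloon inside the calibration volume, default noise)."""
    params = params or TrackingParams()
    phantom = default_phantom()
    n_correct = n_cal = 0
    for log in _session_logs(base_seed, n_sessions, n_measurements,
                             ("stationary", "crawl"), params, phantom):
        df = add_outcomes(log, phantom.balloon_radius, params)
        cal = df[df["mode"] == Mode.CALIBRATION.value]
        n_cal += len(cal)
        n_correct += int((cal["outcome"] == Outcome.TP.value).sum())
    return {"value": 100.0 * n_correct / n_cal, "n": n_cal}


def runtime_accuracy_study(
    base_seed: int,
    n_sessions: int = 20,
    n_measurements: int = 99,
    params: TrackingParams | None = None,
) -> dict:
    """Pooled Runtime detection accuracy, 100*(TP+TN)/N, over crawl
    sessions whose trajectories respect the displacement bound and stay
    within the three-slice capture range (no leaps)."""
    params = params or TrackingParams()
    phantom = default_phantom()
    frames = []
    for log in _session_logs(base_seed, n_sessions, n_measurements,
                             ("crawl",), params, phantom):
        df = add_outcomes(log, phantom.balloon_radius, params)
        frames.append(df[df["mode"] == Mode.RUNTIME.value])
    pooled = pd.concat(frames, ignore_index=True)
    return {
        "value": detection_accuracy(pooled, Mode.RUNTIME),
        "n": len(pooled),
    }


def false_positive_study(
    base_seed: int,
    n_seeds: int = 10,
    n_measurements: int = 20,
    params: TrackingParams | None = None,
) -> dict:
    """False-positive rate among Runtime measurements whose balloon has
    leapt beyond the stack's through-plane range, on a phantom whose
    other hyperintense structures all violate the size/shape bound."""
    params = params or TrackingParams()
    phantom = decoy_phantom()
    geometry = TrackerGeometry()
    length = phantom.path_length
    n_fp = n_total = 0
    for i in range(n_seeds):
        seed = derive_seed(base_seed, 1000 + i)
        rng = np.random.default_rng(seed)
        # balloon positions: anywhere along the vessel
        arcs = rng.uniform(0.05, 0.95, n_measurements) * length
        traj = Trajectory(arclengths=arcs,
                          leap_measurements=frozenset(range(n_measurements)))
        for k in range(n_measurements):
            balloon = traj.position(phantom, k)
            # stack placed where the catheter previously was: displaced
            # through-plane so the balloon is absent from every slab
            span = (params.n_run * params.d_run) / 2.0
            shift = (span + phantom.balloon_radius + 10.0) * (
                1.0 if balloon[1] < 0 else -1.0
            )
            prev = balloon + np.array([0.0, shift, 0.0])
            request, _ = position_runtime_stack(prev, geometry, params)
            stack, truth = acquire(phantom, traj, request, k, seed, params)
            assert truth.max_overlap == 0.0
            ctx = DetectionContext(mode=Mode.RUNTIME, params=params,
                                   shim_box=phantom.shim_box,
                                   prev_position=prev)
            det = detect_balloon(stack, ctx)
            n_total += 1
            n_fp += int(det.found)  # absent + found = false positive
    return {"value": 100.0 * n_fp / n_total, "n": n_total}
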