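"""Stack-series and configuration I/O.

Each measurement is stored as one NIfTI volume (float32, axes row x col
x slice) plus a JSON geometry sidecar of the same stem, because the
stack geometry changes between measurements. The sidecar is the
authoritative geometry record: per-slice center plus the shared normal,
in-plane axes, thickness, FOV, matrix and mode. Round trips are lossless
at 32-bit float precision for intensities and 1e-9 for geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import nibabel as nib
import numpy as np
import yaml

from .core import ImageStack, Mode, SlicePrescription, TrackingParams

__all__ = [
    "write_stack",
    "read_stack",
    "write_stack_series",
    "read_stack_series",
    "RunConfig",
]


def _affine(p0: SlicePrescription) -> np.ndarray:
    sp = p0.pixel_spacing
    c = (p0.matrix - 1) / 2.0
    origin = p0.center - c * sp * p0.axis_u - c * sp * p0.axis_v
    aff = np.eye(4)
    aff[:3, 0] = sp * p0.axis_u
    aff[:3, 1] = sp * p0.axis_v
    aff[:3, 2] = p0.thickness * p0.normal
    aff[:3, 3] = origin
    return aff


def _sidecar(stack: ImageStack) -> dict:
    p0 = stack.prescriptions[0]
    return {
        "mode": stack.mode_tag.value,
        "normal": p0.normal.tolist(),
        "axis_u": p0.axis_u.tolist(),
        "axis_v": p0.axis_v.tolist(),
        "thickness": p0.thickness,
        "fov": p0.fov,
        "matrix": p0.matrix,
        "centers": [p.center.tolist() for p in stack.prescriptions],
    }


def write_stack(stack: ImageStack, path) -> None:
    """Write one measurement as ``<stem>.nii`` + ``<stem>.json``."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    data = np.moveaxis(stack.intensities.astype(np.float32), 0, -1)
    nib.save(nib.Nifti1Image(data, _affine(stack.prescriptions[0])), path)
    path.with_suffix(".json").write_text(json.dumps(_sidecar(stack), indent=1))


def read_stack(path) -> ImageStack:
    """Read one measurement; raises when the sidecar is missing or the
    geometry is inconsistent."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"geometry sidecar missing for measurement {path.stem!r}: "
            f"expected {sidecar_path}"
        )
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(path)
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    prescriptions = tuple(
        SlicePrescription(
            center=np.array(c, dtype=float),
            normal=np.array(meta["normal"], dtype=float),
            axis_u=np.array(meta["axis_u"], dtype=float),
            axis_v=np.array(meta["axis_v"], dtype=float),
            thickness=float(meta["thickness"]),
            fov=float(meta["fov"]),
            matrix=int(meta["matrix"]),
        )
        for c in meta["centers"]
    )  # SlicePrescription validates orthonormality; ImageStack contiguity
    if data.shape[0] != len(prescriptions):
        raise ValueError(
            f"measurement {path.stem!r}: image has {data.shape[0]} slices "
            f"but sidecar lists {len(prescriptions)} centers"
        )
    return ImageStack(
        intensities=np.asarray(data, dtype=float),
        prescriptions=prescriptions,
        mode_tag=Mode(meta["mode"]),
    )


def _series_paths(directory: Path) -> list[Path]:
    return sorted(directory.glob("meas_*.nii"))


def write_stack_series(stacks: Iterable[ImageStack], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, stack in enumerate(stacks):
        p = directory / f"meas_{k:04d}.nii"
        write_stack(stack, p)
        paths.append(p)
    return paths


def read_stack_series(directory) -> list[ImageStack]:
    directory = Path(directory)
    paths = _series_paths(directory)
    if not paths:
        raise FileNotFoundError(f"no meas_*.nii stacks under {directory}")
    return [read_stack(p) for p in paths]


@dataclass
class RunConfig:
    """Full, serializable description of one simulated tracking run."""

    params: TrackingParams = field(default_factory=TrackingParams)
    phantom: str = "default"
    scenario: str = "crawl"
    trajectory_csv: Optional[str] = None
    n_measurements: int = 99
    seed: int = 0
    latency: int = 1
    noise_sigma: float = 1.0
    speed: float = 4.0
    start: float = 30.0
    outdir: Optional[str] = None

    _SCALARS = (
        "phantom", "scenario", "trajectory_csv", "n_measurements", "seed",
        "latency", "noise_sigma", "speed", "start", "outdir",
    )

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._SCALARS}
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls._SCALARS) - {"params"}
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        params = TrackingParams.from_dict(d.pop("params", {}))
        return cls(params=params, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
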