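import numpy as np
import pytest

from balloontrack.core import (
    ImageStack,
    Mode,
    ShimBox,
    SlicePrescription,
    TrackingParams,
)

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def params():
    return TrackingParams()


@pytest.fixture(scope="session")
def big_box():
    return ShimBox(lower=(-500.0, -500.0, -500.0), upper=(500.0, 500.0, 500.0))


def coronal_prescription(
    y_center=0.0, thickness=10.0, fov=112.5, matrix=40
) -> SlicePrescription:
    """Small coronal slice (rows along +x, cols along +z, normal +y) with
    the paper-resolution pixel spacing fov/matrix = 2.8125 mm."""
    return SlicePrescription(
        center=np.array([0.0, y_center, 0.0]),
        normal=EY,
        axis_u=EX,
        axis_v=EZ,
        thickness=thickness,
        fov=fov,
        matrix=matrix,
    )


def make_stack(slices, mode=Mode.RUNTIME, y0=0.0, thickness=10.0,
               fov=112.5, matrix=40) -> ImageStack:
    """Build an ImageStack from a list of 2D arrays (contiguous coronal
    slices starting at y0)."""
    slices = [np.asarray(s, dtype=float) for s in slices]
    prescriptions = tuple(
        coronal_prescription(y0 + k * thickness, thickness, fov, matrix)
        for k in range(len(slices))
    )
    return ImageStack(
        intensities=np.stack(slices), prescriptions=prescriptions, mode_tag=mode
    )


def disk_image(matrix, row, col, radius_px, value, background=0.0):
    img = np.full((matrix, matrix), float(background))
    rr, cc = np.meshgrid(np.arange(matrix), np.arange(matrix), indexing="ij")
    img[(rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2] = value
    return img
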