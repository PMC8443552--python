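import math

import numpy as np
import pytest

from lvstrain.contours import CineStudy, ContourPolygon, Layer, SliceFrame, Timepoint
from lvstrain.phantom import PhantomSpec, generate_phantom_study


def circle_polygon(radius: float, n_points: int, layer=Layer.ENDOCARDIUM) -> ContourPolygon:
    theta = 2 * math.pi * np.arange(n_points) / n_points
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return ContourPolygon(pts, layer, closed=True)


def square_polygon(side: float = 1.0, layer=Layer.ENDOCARDIUM) -> ContourPolygon:
    pts = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    return ContourPolygon(pts, layer, closed=True)


def stack_study(
    areas_series,  # list (per slice) of per-frame square side lengths
    thickness_mm=8.0,
    dt_ms=40.0,
    subject_id="stack",
    timepoint=Timepoint.BASELINE,
    weight_kg=62.5,
):
    """Build a study of square contours with prescribed per-frame sides."""
    short_axis = []
    for i, sides in enumerate(areas_series):
        cine = []
        for k, side in enumerate(sides):
            pts = np.array([[0, 0], [side, 0], [side, side], [0, side]], float)
            cine.append(
                SliceFrame(
                    slice_index=i,
                    z_mm=i * thickness_mm,
                    thickness_mm=thickness_mm,
                    frame_index=k,
                    time_ms=k * dt_ms,
                    contours={Layer.ENDOCARDIUM: ContourPolygon(pts, Layer.ENDOCARDIUM)},
                )
            )
        short_axis.append(cine)
    return CineStudy(subject_id, timepoint, weight_kg, short_axis)


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom_study(PhantomSpec())


@pytest.fixture(scope="session")
def infarct_phantom():
    return generate_phantom_study(PhantomSpec.infarcted_apex())
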