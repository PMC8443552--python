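"""Slice areas, ventricular volumes, ejection fraction and remodelling.

The blood-pool volume at each frame is the sum over short-axis slices of
(endocardial contour area) x (slice thickness) -- a Simpson-style disc
summation with no partial-slice correction.  Derived metrics: LVEF,
allometric body surface area BSA = 0.0734 * weight^0.656 (m^2, weight in
kg), the indexed end-systolic volume LVESVi = LVESV / BSA, and the
left-ventricular remodelling (LVR) classification: >= 10% change in both
EDV and ESV relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import CineStudy, ContourPolygon, Layer
from .errors import DataError, GeometryError, ParameterError

__all__ = [
    "VolumeSeries",
    "FunctionMetrics",
    "polygon_area",
    "volume_series",
    "end_diastolic_frame",
    "body_surface_area",
    "function_metrics",
]

BSA_COEFFICIENT = 0.0734
BSA_EXPONENT = 0.656
REMODELLING_THRESHOLD = 0.10


@dataclass(frozen=True)
class VolumeSeries:
    """Per-frame blood-pool volume with end-diastolic/systolic frames."""

    volumes_ml: np.ndarray
    times_ms: np.ndarray
    ed_frame: int
    es_frame: int

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ml, dtype=float)
        t = np.asarray(self.times_ms, dtype=float)
        if np.any(v <= 0):
            raise DataError("non-positive blood-pool volume")
        object.__setattr__(self, "volumes_ml", v)
        object.__setattr__(self, "times_ms", t)

    @property
    def edv_ml(self) -> float:
        return float(self.volumes_ml[self.ed_frame])

    @property
    def esv_ml(self) -> float:
        return float(self.volumes_ml[self.es_frame])


@dataclass(frozen=True)
class FunctionMetrics:
    """Global-function summary for one study (one subject-timepoint)."""

    lvedv_ml: float
    lvesv_ml: float
    lvef_pct: float
    bsa_m2: float
    lvesvi_ml_per_m2: float
    remodelling: bool | None = None


def polygon_area(polygon: ContourPolygon) -> float:
    """Absolute shoelace area of a closed contour, mm^2."""
    if not polygon.closed:
        raise GeometryError("area requires a closed polygon")
    pts = polygon.points
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


def volume_series(study: CineStudy, layer: Layer = Layer.ENDOCARDIUM) -> VolumeSeries:
    """Disc-summation volume at every frame, mm^3 converted to ml.

    Every slice must carry the requested layer on every frame; a missing
    contour raises :class:`DataError` naming the slice and frame.
    """
    layer = Layer(layer)
    n_frames = study.n_frames
    volumes = np.zeros(n_frames)
    for cine in study.short_axis:
        thickness = cine[0].thickness_mm
        for frame in cine:
            poly = frame.contour(layer)  # DataError names slice/frame
            volumes[frame.frame_index] += polygon_area(poly) * thickness
    volumes /= 1000.0  # mm^3 -> ml
    times = study.frame_times_ms
    ed = int(np.argmax(volumes))
    es = int(np.argmin(volumes))
    return VolumeSeries(volumes_ml=volumes, times_ms=times, ed_frame=ed, es_frame=es)


def end_diastolic_frame(study: CineStudy) -> int:
    """Reference-frame rule: the frame of maximal endocardial blood-pool
    volume; falls back to frame 0 when volumes cannot be computed."""
    try:
        return volume_series(study, Layer.ENDOCARDIUM).ed_frame
    except DataError:
        return 0


def body_surface_area(weight_kg: float) -> float:
    """Porcine allometric BSA (m^2) from body mass (kg)."""
    if weight_kg <= 0:
        raise ParameterError("weight_kg must be > 0")
    return BSA_COEFFICIENT * weight_kg ** BSA_EXPONENT


def function_metrics(
    vols: VolumeSeries,
    weight_kg: float,
    baseline: FunctionMetrics | None = None,
) -> FunctionMetrics:
    """LVEF, BSA, LVESVi and (vs a baseline) the LVR classification.

    Remodelling is True iff *both* EDV and ESV changed by at least 10%
    relative to their baseline values (inclusive threshold); None when no
    baseline is supplied.
    """
    edv, esv = vols.edv_ml, vols.esv_ml
    if edv <= esv:
        raise DataError(f"EDV ({edv:.1f} ml) must exceed ESV ({esv:.1f} ml)")
    lvef = 100.0 * (edv - esv) / edv
    bsa = body_surface_area(weight_kg)
    remodelling: bool | None = None
    if baseline is not None:
        d_edv = abs(edv - baseline.lvedv_ml) / baseline.lvedv_ml
        d_esv = abs(esv - baseline.lvesv_ml) / baseline.lvesv_ml
        remodelling = bool(
            d_edv >= REMODELLING_THRESHOLD and d_esv >= REMODELLING_THRESHOLD
        )
    return FunctionMetrics(
        lvedv_ml=edv,
        lvesv_ml=esv,
        lvef_pct=lvef,
        bsa_m2=bsa,
        lvesvi_ml_per_m2=esv / bsa,
        remodelling=remodelling,
    )
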