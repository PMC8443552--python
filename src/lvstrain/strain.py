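"""Perimeter-based circumferential and longitudinal strain.

Strain of a traced myocardial border is the fractional change of its
length relative to end-diastole, eps = (L - L0) / L0; strain rate is the
forward difference of border length between successive cine frames,
normalised by L0 and the inter-frame interval (s^-1).  Slices are grouped
into apex / mid / base regions; regional curves are pointwise means over
member slices and the global circumferential curve is the mean over all
7-9 slices.  The identical pipeline runs on endocardial and epicardial
borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .contours import CineStudy, ContourPolygon, Layer
from .errors import (
    AggregationError,
    DataError,
    GeometryError,
    ParameterError,
    TimingError,
)

__all__ = [
    "Region",
    "Direction",
    "PerimeterSeries",
    "StrainCurve",
    "RegionPartition",
    "PeakRecord",
    "border_length",
    "perimeter_series",
    "strain_curve",
    "strain_rate_curve",
    "partition_regions",
    "aggregate_strain",
    "slice_strain_curves",
    "longitudinal_strain",
    "peak_value",
]


class Region(str, Enum):
    APEX = "apex"
    MID = "mid"
    BASE = "base"


class Direction(str, Enum):
    CIRCUMFERENTIAL = "circumferential"
    LONGITUDINAL = "longitudinal"


def border_length(polygon: ContourPolygon) -> float:
    """Border length in mm: segment sum, plus the wrap segment if closed."""
    pts = polygon.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if polygon.closed:
        total += float(np.linalg.norm(pts[0] - pts[-1]))
    return total


@dataclass(frozen=True)
class PerimeterSeries:
    """Per-frame border lengths for one slice and layer, with ED reference."""

    slice_index: int
    layer: Layer
    lengths_mm: np.ndarray
    times_ms: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths_mm, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        if lengths.shape != times.shape or lengths.ndim != 1:
            raise ParameterError("lengths and times must be equal-length 1-D arrays")
        if np.any(lengths <= 0):
            raise GeometryError(f"slice {self.slice_index}: non-positive border length")
        if not 0 <= self.reference_frame < len(lengths):
            raise ParameterError(
                f"reference_frame {self.reference_frame} outside 0..{len(lengths) - 1}"
            )
        object.__setattr__(self, "lengths_mm", lengths)
        object.__setattr__(self, "times_ms", times)

    @property
    def l0_mm(self) -> float:
        """End-diastolic reference length L0."""
        return float(self.lengths_mm[self.reference_frame])


@dataclass(frozen=True)
class StrainCurve:
    """Per-frame strain (dimensionless) or strain rate (s^-1) with scope tags.

    ``scope`` is ``("slice", i)``, ``("region", Region)`` or ``("global", None)``.
    """

    values: np.ndarray
    times_ms: np.ndarray
    scope: tuple[str, object]
    direction: Direction
    layer: Layer
    is_rate: bool = False
    reference_frame: int | None = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        if values.shape != times.shape:
            raise ParameterError("values and times must have equal length")
        if not self.is_rate:
            if np.any(values <= -1.0):
                raise GeometryError("strain below -1 implies non-physical length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times_ms", times)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of slice indices to contiguous apex / mid / base blocks."""

    assignment: Mapping[int, Region]

    def members(self, region: Region) -> list[int]:
        return sorted(i for i, r in self.assignment.items() if r is Region(region))

    def region_of(self, slice_index: int) -> Region:
        return self.assignment[slice_index]


@dataclass(frozen=True)
class PeakRecord:
    """A signed peak of a strain or strain-rate curve."""

    value: float
    frame_index: int
    convention: str


def perimeter_series(
    study: CineStudy,
    slice_index: int,
    layer: Layer,
    reference_frame: int = 0,
) -> PerimeterSeries:
    """Measure per-frame border lengths of one short-axis slice."""
    cine = study.slice_cine(slice_index)
    lengths = np.array([border_length(f.contour(layer)) for f in cine])
    times = np.array([f.time_ms for f in cine])
    return PerimeterSeries(slice_index, Layer(layer), lengths, times, reference_frame)


def strain_curve(series: PerimeterSeries) -> StrainCurve:
    """eps_n = (L_n - L0) / L0, exactly zero at the reference frame."""
    l0 = series.l0_mm
    if l0 <= 0:
        raise GeometryError("reference length L0 must be > 0")
    values = (series.lengths_mm - l0) / l0
    values[series.reference_frame] = 0.0
    return StrainCurve(
        values=values,
        times_ms=series.times_ms,
        scope=("slice", series.slice_index),
        direction=Direction.CIRCUMFERENTIAL,
        layer=series.layer,
        is_rate=False,
        reference_frame=series.reference_frame,
    )


def strain_rate_curve(series: PerimeterSeries) -> StrainCurve:
    """Forward-difference strain rate between successive frames, in s^-1.

    rate_n = (L_{n+1} - L_n) / (L0 * dt_n), with dt_n in seconds; the
    n-th value is timestamped at the midpoint of its interval, so the
    curve has (frames - 1) samples.
    """
    if len(series.lengths_mm) < 2:
        raise ParameterError("strain rate needs at least 2 frames")
    dt_ms = np.diff(series.times_ms)
    if np.any(dt_ms <= 0):
        raise TimingError(f"slice {series.slice_index}: non-increasing frame times")
    l0 = series.l0_mm
    rate = np.diff(series.lengths_mm) / (l0 * dt_ms / 1000.0)
    mid_times = series.times_ms[:-1] + dt_ms / 2.0
    return StrainCurve(
        values=rate,
        times_ms=mid_times,
        scope=("slice", series.slice_index),
        direction=Direction.CIRCUMFERENTIAL,
        layer=series.layer,
        is_rate=True,
        reference_frame=None,
    )


def partition_regions(slice_indices: Sequence[int]) -> RegionPartition:
    """Split an ordered apex->base slice list into three contiguous regions.

    Block sizes are as equal as possible; remainder slices go to the apex
    block first, then mid (so 7 -> 3/2/2, 8 -> 3/3/2, 9 -> 3/3/3).
    """
    indices = list(slice_indices)
    n = len(indices)
    if n < 3:
        raise ParameterError(f"need >= 3 slices to partition, got {n}")
    base_size, rem = divmod(n, 3)
    sizes = [base_size + (1 if rem >= 1 else 0),
             base_size + (1 if rem == 2 else 0),
             base_size]
    assignment: dict[int, Region] = {}
    cursor = 0
    for region, size in zip((Region.APEX, Region.MID, Region.BASE), sizes):
        for i in indices[cursor:cursor + size]:
            assignment[i] = region
        cursor += size
    return RegionPartition(assignment)


def _check_compatible(curves: Sequence[StrainCurve]) -> None:
    first = curves[0]
    for c in curves[1:]:
        if (c.direction, c.layer, c.is_rate) != (first.direction, first.layer, first.is_rate):
            raise AggregationError("cannot aggregate curves with mixed direction/layer/kind")
        if len(c) != len(first) or not np.allclose(c.times_ms, first.times_ms):
            raise AggregationError("cannot aggregate curves on different time bases")


def aggregate_strain(
    curves: Mapping[int, StrainCurve],
    partition: RegionPartition | None = None,
    scope: str | Region = "global",
) -> StrainCurve:
    """Pointwise mean of per-slice curves over a region or over all slices.

    ``scope='global'`` averages every curve (the global CS of a 7-9 slice
    stack); a :class:`Region` scope averages the partition's member slices.
    """
    if not curves:
        raise AggregationError("no curves to aggregate")
    if scope == "global":
        members = sorted(curves)
        out_scope = ("global", None)
    else:
        region = Region(scope)
        if partition is None:
            raise AggregationError("region aggregation requires a partition")
        members = [i for i in partition.members(region) if i in curves]
        if not members:
            raise AggregationError(f"no curves for region {region.value}")
        out_scope = ("region", region)
    selected = [curves[i] for i in members]
    _check_compatible(selected)
    mean = np.mean([c.values for c in selected], axis=0)
    first = selected[0]
    return StrainCurve(
        values=mean,
        times_ms=first.times_ms,
        scope=out_scope,
        direction=first.direction,
        layer=first.layer,
        is_rate=first.is_rate,
        reference_frame=first.reference_frame,
    )


def slice_strain_curves(
    study: CineStudy,
    layer: Layer,
    reference_frame: int = 0,
    is_rate: bool = False,
) -> dict[int, StrainCurve]:
    """Circumferential strain (or rate) curve for every short-axis slice."""
    out: dict[int, StrainCurve] = {}
    for cine in study.short_axis:
        series = perimeter_series(study, cine[0].slice_index, layer, reference_frame)
        out[cine[0].slice_index] = (
            strain_rate_curve(series) if is_rate else strain_curve(series)
        )
    return out


def longitudinal_strain(
    study: CineStudy,
    layer: Layer,
    reference_frame: int = 0,
    is_rate: bool = False,
) -> StrainCurve:
    """Global longitudinal strain from the 4-chamber long-axis border.

    Open-polyline border lengths per frame feed the same eps = (L - L0)/L0
    (or forward-difference rate) computation as the short-axis pipeline.
    """
    if not study.long_axis:
        raise DataError("study has no long-axis series")
    layer = Layer(layer)
    lengths = []
    times = []
    for frame in study.long_axis:
        lengths.append(border_length(frame.contour(layer)))
        times.append(frame.time_ms)
    series = PerimeterSeries(0, layer, np.array(lengths), np.array(times), reference_frame)
    curve = strain_rate_curve(series) if is_rate else strain_curve(series)
    return replace(curve, scope=("global", None), direction=Direction.LONGITUDINAL)


def peak_value(curve: StrainCurve, convention: str = "most_negative") -> PeakRecord:
    """Extract the peak of a curve; ties break to the earliest frame.

    Default convention ``most_negative`` matches peak systolic shortening
    for both strain and strain rate; ``most_positive`` and
    ``largest_magnitude`` are also available.
    """
    if len(curve) == 0:
        raise ParameterError("empty curve has no peak")
    v = curve.values
    if convention == "most_negative":
        idx = int(np.argmin(v))
    elif convention == "most_positive":
        idx = int(np.argmax(v))
    elif convention == "largest_magnitude":
        idx = int(np.argmax(np.abs(v)))
    else:
        raise ParameterError(f"unknown peak convention {convention!r}")
    return PeakRecord(value=float(v[idx]), frame_index=idx, convention=convention)
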