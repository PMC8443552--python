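"""Contour-study data model and file input/output.

A cine contour study is a per-subject, per-timepoint collection of
short-axis slices (apex -> base) by cardiac frames, each frame carrying
closed endocardial and epicardial polygons in planar millimetres, plus a
four-chamber long-axis series whose borders are open polylines.  Two
interchangeable on-disk dialects are defined: a nested JSON document and
a long-form CSV.  Coordinates round-trip repr-faithfully.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box
from shapely.geometry.polygon import orient as _shapely_orient
from shapely.ops import unary_union

from .errors import (
    DataError,
    GeometryError,
    ParameterError,
    StudyFormatError,
    StudyValidationError,
    TimingError,
)

__all__ = [
    "Layer",
    "Timepoint",
    "ContourPolygon",
    "SliceFrame",
    "CineStudy",
    "ValidationIssue",
    "ValidationReport",
    "read_contour_study",
    "write_contour_study",
    "resample_contour",
    "smooth_contour",
    "extract_contour_from_mask",
    "validate_study",
]


class Layer(str, Enum):
    """Myocardial border layer."""

    ENDOCARDIUM = "endocardium"
    EPICARDIUM = "epicardium"


class Timepoint(str, Enum):
    """Study timepoint relative to infarction."""

    BASELINE = "baseline"
    ACUTE = "acute"
    CHRONIC = "chronic"


@dataclass(frozen=True)
class ContourPolygon:
    """A traced myocardial border in one imaging plane.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (x, y) coordinates in mm.  Closed rings are
        stored *without* repeating the first point; closure is implied
        by `closed`.
    layer
        Which border this is (endocardium or epicardium).
    closed
        True for short-axis rings, False for long-axis border polylines.
    """

    points: np.ndarray
    layer: Layer
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(f"contour points must be (n, 2), got {pts.shape}")
        minimum = 3 if self.closed else 2
        if len(pts) < minimum:
            raise GeometryError(
                f"{'closed' if self.closed else 'open'} contour needs >= "
                f"{minimum} points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise GeometryError("contour contains non-finite coordinates")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise GeometryError("contour has consecutive identical points")
        if self.closed and np.all(pts[0] == pts[-1]):
            raise GeometryError(
                "closed contour must not repeat its first point (closure is implied)"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "layer", Layer(self.layer))

    def __len__(self) -> int:
        return len(self.points)

    def is_simple(self) -> bool:
        """True if a closed ring does not self-intersect (open: always True)."""
        if not self.closed:
            return True
        return _ShapelyPolygon(self.points).is_valid


@dataclass(frozen=True)
class SliceFrame:
    """One imaging plane at one cardiac frame, with its traced borders."""

    slice_index: int
    z_mm: float
    thickness_mm: float
    frame_index: int
    time_ms: float
    contours: Mapping[Layer, ContourPolygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise StudyValidationError(
                f"slice {self.slice_index}: thickness_mm must be > 0"
            )
        if self.time_ms < 0:
            raise StudyValidationError(
                f"slice {self.slice_index} frame {self.frame_index}: time_ms < 0"
            )
        object.__setattr__(
            self, "contours", {Layer(k): v for k, v in dict(self.contours).items()}
        )

    def contour(self, layer: Layer) -> ContourPolygon:
        try:
            return self.contours[Layer(layer)]
        except KeyError:
            raise DataError(
                f"slice {self.slice_index} frame {self.frame_index}: "
                f"no {Layer(layer).value} contour"
            ) from None


@dataclass
class CineStudy:
    """A subject x timepoint grid of contoured slice-frames.

    ``short_axis[i][k]`` is slice ``i`` (0 = apex) at frame ``k``;
    ``long_axis[k]`` is the 4-chamber view at frame ``k``.
    """

    subject_id: str
    timepoint: Timepoint
    weight_kg: float
    short_axis: list[list[SliceFrame]]
    long_axis: list[SliceFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)
        if self.weight_kg <= 0:
            raise StudyValidationError("weight_kg must be > 0")
        if not self.short_axis:
            raise StudyValidationError("study has no short-axis slices")
        n_frames = len(self.short_axis[0])
        for cine in self.short_axis:
            if len(cine) != n_frames:
                raise StudyValidationError(
                    f"slice {cine[0].slice_index if cine else '?'} has "
                    f"{len(cine)} frames, expected {n_frames}"
                )
            times = [f.time_ms for f in cine]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise TimingError(
                    f"slice {cine[0].slice_index}: frame times not strictly increasing"
                )

    @property
    def n_slices(self) -> int:
        return len(self.short_axis)

    @property
    def n_frames(self) -> int:
        return len(self.short_axis[0])

    @property
    def frame_times_ms(self) -> np.ndarray:
        """Common frame time base (taken from the first slice)."""
        return np.array([f.time_ms for f in self.short_axis[0]], dtype=float)

    def slice_cine(self, slice_index: int) -> list[SliceFrame]:
        for cine in self.short_axis:
            if cine and cine[0].slice_index == slice_index:
                return cine
        raise DataError(f"no slice with index {slice_index}")


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    slice_index: int | None
    frame_index: int | None
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_study`; empty ``errors`` <=> analyzable."""

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def codes(self) -> set[str]:
        return {e.code for e in self.errors}


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "subject_id",
    "timepoint",
    "weight_kg",
    "view",
    "slice_index",
    "z_mm",
    "thickness_mm",
    "frame_index",
    "time_ms",
    "layer",
    "point_index",
    "x_mm",
    "y_mm",
]

#: long-axis frames carry no real through-plane geometry; placeholders keep
#: the SliceFrame invariants satisfied.
_LONG_AXIS_Z = 0.0
_LONG_AXIS_THICKNESS = 1.0


def _frame_to_json(frame: SliceFrame) -> dict:
    rec: dict = {"frame_index": frame.frame_index, "time_ms": frame.time_ms}
    for layer, poly in frame.contours.items():
        rec[layer.value] = [[float(x), float(y)] for x, y in poly.points]
    return rec


def _frame_from_json(
    rec: dict, slice_index: int, z_mm: float, thickness_mm: float, closed: bool
) -> SliceFrame:
    contours = {}
    for layer in Layer:
        if layer.value in rec:
            contours[layer] = ContourPolygon(
                np.asarray(rec[layer.value], dtype=float), layer, closed=closed
            )
    return SliceFrame(
        slice_index=slice_index,
        z_mm=float(z_mm),
        thickness_mm=float(thickness_mm),
        frame_index=int(rec["frame_index"]),
        time_ms=float(rec["time_ms"]),
        contours=contours,
    )


def study_to_json_dict(study: CineStudy) -> dict:
    """Serialise a study to the nested JSON dialect (plain dict)."""
    doc: dict = {
        "subject_id": study.subject_id,
        "timepoint": study.timepoint.value,
        "weight_kg": study.weight_kg,
        "short_axis": [
            {
                "slice_index": cine[0].slice_index,
                "z_mm": cine[0].z_mm,
                "thickness_mm": cine[0].thickness_mm,
                "frames": [_frame_to_json(f) for f in cine],
            }
            for cine in study.short_axis
        ],
    }
    if study.long_axis:
        doc["long_axis"] = {"frames": [_frame_to_json(f) for f in study.long_axis]}
    return doc


def study_from_json_dict(doc: dict) -> CineStudy:
    try:
        short_axis = [
            [
                _frame_from_json(
                    rec,
                    int(s["slice_index"]),
                    float(s["z_mm"]),
                    float(s["thickness_mm"]),
                    closed=True,
                )
                for rec in s["frames"]
            ]
            for s in doc["short_axis"]
        ]
        long_axis = [
            _frame_from_json(
                rec, 0, _LONG_AXIS_Z, _LONG_AXIS_THICKNESS, closed=False
            )
            for rec in doc.get("long_axis", {}).get("frames", [])
        ]
        return CineStudy(
            subject_id=str(doc["subject_id"]),
            timepoint=Timepoint(doc["timepoint"]),
            weight_kg=float(doc["weight_kg"]),
            short_axis=short_axis,
            long_axis=long_axis,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise StudyFormatError(f"malformed study document: {exc}") from exc


def read_contour_study(path: str | Path, format: str | None = None) -> CineStudy:
    """Read a cine contour study from JSON or long-form CSV.

    ``format`` defaults to the file extension.  Invariants are enforced on
    construction; a violation raises :class:`StudyValidationError` (or
    :class:`TimingError`) naming the offending slice/frame.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise StudyFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        return study_from_json_dict(doc)
    if fmt == "csv":
        return _read_csv(path)
    raise ParameterError(f"unknown study format {fmt!r} (expected json or csv)")


def write_contour_study(
    study: CineStudy, path: str | Path, format: str | None = None
) -> Path:
    """Write a study in the JSON or CSV dialect (UTF-8, LF, repr-faithful)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(study_to_json_dict(study), fh, indent=1)
            fh.write("\n")
        return path
    if fmt == "csv":
        _write_csv(study, path)
        return path
    raise ParameterError(f"unknown study format {fmt!r} (expected json or csv)")


def _write_csv(study: CineStudy, path: Path) -> None:
    def rows(view: str, frame: SliceFrame) -> Iterable[list]:
        for layer, poly in frame.contours.items():
            for j, (x, y) in enumerate(poly.points):
                yield [
                    study.subject_id,
                    study.timepoint.value,
                    repr(study.weight_kg),
                    view,
                    frame.slice_index,
                    repr(frame.z_mm),
                    repr(frame.thickness_mm),
                    frame.frame_index,
                    repr(frame.time_ms),
                    layer.value,
                    j,
                    repr(float(x)),
                    repr(float(y)),
                ]

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_COLUMNS)
        for cine in study.short_axis:
            for frame in cine:
                writer.writerows(rows("short_axis", frame))
        for frame in study.long_axis:
            writer.writerows(rows("long_axis", frame))


def _read_csv(path: Path) -> CineStudy:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_COLUMNS) - set(reader.fieldnames):
            raise StudyFormatError(f"{path}: missing CSV columns")
        records = list(reader)
    if not records:
        raise StudyFormatError(f"{path}: empty study file")

    meta = records[0]
    # group points: (view, slice, frame, layer) -> list[(point_index, x, y)]
    groups: dict[tuple, list[tuple[int, float, float]]] = {}
    frame_meta: dict[tuple, dict] = {}
    for lineno, rec in enumerate(records, start=2):
        try:
            key = (
                rec["view"],
                int(rec["slice_index"]),
                int(rec["frame_index"]),
                rec["layer"],
            )
            groups.setdefault(key, []).append(
                (int(rec["point_index"]), float(rec["x_mm"]), float(rec["y_mm"]))
            )
            frame_meta[key[:3]] = {
                "z_mm": float(rec["z_mm"]),
                "thickness_mm": float(rec["thickness_mm"]),
                "time_ms": float(rec["time_ms"]),
            }
        except (KeyError, ValueError) as exc:
            raise StudyFormatError(f"{path}: bad record at line {lineno}: {exc}") from exc

    def build_frames(view: str) -> dict[int, dict[int, SliceFrame]]:
        per_slice: dict[int, dict[int, SliceFrame]] = {}
        keys = {k[:3] for k in groups if k[0] == view}
        for view_, si, fi in sorted(keys):
            contours = {}
            for layer in Layer:
                pts = groups.get((view_, si, fi, layer.value))
                if pts:
                    pts = sorted(pts)
                    contours[layer] = ContourPolygon(
                        np.array([(x, y) for _, x, y in pts]),
                        layer,
                        closed=(view == "short_axis"),
                    )
            fm = frame_meta[(view_, si, fi)]
            per_slice.setdefault(si, {})[fi] = SliceFrame(
                slice_index=si,
                z_mm=fm["z_mm"],
                thickness_mm=fm["thickness_mm"],
                frame_index=fi,
                time_ms=fm["time_ms"],
                contours=contours,
            )
        return per_slice

    sax = build_frames("short_axis")
    lax = build_frames("long_axis")
    short_axis = [
        [frames[fi] for fi in sorted(frames)] for _, frames in sorted(sax.items())
    ]
    long_axis = (
        [lax[0][fi] for fi in sorted(lax[0])] if lax else []
    )
    return CineStudy(
        subject_id=meta["subject_id"],
        timepoint=Timepoint(meta["timepoint"]),
        weight_kg=float(meta["weight_kg"]),
        short_axis=short_axis,
        long_axis=long_axis,
    )


# ---------------------------------------------------------------------------
# geometric utilities
# ---------------------------------------------------------------------------

def _vertex_arc_lengths(points: np.ndarray, closed: bool) -> np.ndarray:
    """Cumulative arc length at each vertex (plus the wrap point if closed)."""
    pts = points
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)]), pts


def resample_contour(polygon: ContourPolygon, n_points: int) -> ContourPolygon:
    """Resample a contour to ``n_points`` equally spaced in arc length.

    The walk starts at the first stored vertex, so vertices lying on
    multiples of the new spacing are reproduced exactly.  Closed-ness is
    preserved; for open polylines the final point is the original endpoint.
    """
    if n_points < 8:
        raise ParameterError(f"n_points must be >= 8, got {n_points}")
    s, pts = _vertex_arc_lengths(polygon.points, polygon.closed)
    total = s[-1]
    if polygon.closed:
        targets = np.arange(n_points) * total / n_points
    else:
        targets = np.linspace(0.0, total, n_points)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return ContourPolygon(np.column_stack([x, y]), polygon.layer, polygon.closed)


def smooth_contour(polygon: ContourPolygon, window: int = 5) -> ContourPolygon:
    """Circular (closed) or reflective (open) moving-average point smoothing.

    A light low-pass filter for jittery traced contours; window is the odd
    number of points averaged.  Perimeter-noise inflation on raw points is
    the main bias this mitigates (see the methods note).
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd positive integer")
    if window == 1:
        return polygon
    pts = polygon.points
    half = window // 2
    if polygon.closed:
        ext = np.vstack([pts[-half:], pts, pts[:half]])
    else:
        ext = np.vstack([pts[:1].repeat(half, axis=0), pts, pts[-1:].repeat(half, axis=0)])
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(ext[:, 0], kernel, mode="valid"), np.convolve(ext[:, 1], kernel, mode="valid")]
    )
    return ContourPolygon(sm, polygon.layer, polygon.closed)


def extract_contour_from_mask(
    mask: np.ndarray, pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
) -> ContourPolygon:
    """Trace the outer boundary of a binary mask as a closed polygon in mm.

    The polygon follows pixel *edges* (the crack boundary), so shoelace area
    equals pixel count x pixel area exactly for hole-free masks.  The mask
    must contain exactly one 4-connected foreground component; holes trigger
    a warning and the outer boundary is returned.  Column index maps to x,
    row index to y; orientation is counter-clockwise in (x, y).
    """
    from scipy import ndimage

    mask = np.asarray(mask).astype(bool)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        raise DataError("mask has no foreground component")
    if n_comp > 1:
        raise DataError(f"mask has {n_comp} 4-connected components, expected 1")
    if np.any(ndimage.binary_fill_holes(mask) & ~mask):
        warnings.warn("mask contains holes; returning outer boundary only", stacklevel=2)

    dy, dx = 1.0, 1.0  # work in pixel units, scale at the end
    cells = [
        _shapely_box(c, r, c + dx, r + dy)
        for r, c in zip(*np.nonzero(mask))
    ]
    merged = unary_union(cells)
    if merged.geom_type != "Polygon":  # pragma: no cover - guarded by labelling
        raise DataError("mask boundary is not a single polygon")
    ring = _shapely_orient(_ShapelyPolygon(merged.exterior), sign=1.0).exterior
    coords = np.asarray(ring.coords)[:-1]  # drop repeated closing point
    sx, sy = float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1])
    coords = coords * np.array([sx, sy])
    return ContourPolygon(coords, Layer.ENDOCARDIUM, closed=True)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_study(study: CineStudy, time_tolerance_ms: float = 1.0) -> ValidationReport:
    """Check structural and geometric invariants; report, never raise.

    Error codes: ``FRAME_COUNT``, ``TIME_ORDER``, ``TIME_BASE``, ``Z_ORDER``,
    ``LAYER_GAP``, ``NON_SIMPLE``, ``THICKNESS``.
    """
    report = ValidationReport()

    n_frames = study.n_frames
    ref_times = study.frame_times_ms
    z_prev = None
    for cine in study.short_axis:
        si = cine[0].slice_index
        if len(cine) != n_frames:
            report.errors.append(
                ValidationIssue("FRAME_COUNT", si, None,
                                f"slice {si} has {len(cine)} frames, expected {n_frames}")
            )
        times = np.array([f.time_ms for f in cine])
        if np.any(np.diff(times) <= 0):
            report.errors.append(
                ValidationIssue("TIME_ORDER", si, None, f"slice {si} times not increasing")
            )
        elif len(times) == n_frames and np.max(np.abs(times - ref_times)) > time_tolerance_ms:
            report.errors.append(
                ValidationIssue("TIME_BASE", si, None,
                                f"slice {si} frame times deviate from common base")
            )
        if cine[0].thickness_mm <= 0:
            report.errors.append(
                ValidationIssue("THICKNESS", si, None, f"slice {si} non-positive thickness")
            )
        if z_prev is not None and cine[0].z_mm <= z_prev:
            report.errors.append(
                ValidationIssue("Z_ORDER", si, None,
                                f"slice {si} z_mm {cine[0].z_mm} not above previous {z_prev}")
            )
        z_prev = cine[0].z_mm

        # layers present on frame 0 must be present on every frame
        layers0 = set(cine[0].contours)
        for frame in cine[1:]:
            missing = layers0 - set(frame.contours)
            for layer in sorted(missing, key=lambda l: l.value):
                report.errors.append(
                    ValidationIssue("LAYER_GAP", si, frame.frame_index,
                                    f"slice {si} frame {frame.frame_index} missing {layer.value}")
                )
        for frame in cine:
            for layer, poly in frame.contours.items():
                if not poly.is_simple():
                    report.errors.append(
                        ValidationIssue("NON_SIMPLE", si, frame.frame_index,
                                        f"slice {si} frame {frame.frame_index} "
                                        f"{layer.value} self-intersects")
                    )
    return report
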