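"""Ground-truthed synthetic inputs: a deforming-ventricle cine contour
phantom and a paired infarct/remote proteome with planted associations.

The cine phantom is a truncated half-ellipsoid left ventricle sliced
short-axis from apex to base.  Each slice's endocardial radius follows

    r(z, t) = r_ED(z) * (1 + eps_region(z) * g(t))

with g a raised-cosine systolic bump (0 at end-diastole, 1 at end-systole,
0 through diastole), so the circumferential strain of slice i at frame k
is exactly ``eps_region(i) * g(t_k)`` by construction, independent of the
contour point count (the inscribed-polygon chord factor cancels in the
strain ratio).  The epicardium sits one wall thickness outward with a
reduced deformation amplitude; the long-axis border is a half-ellipse
polyline scaled by ``1 + eps_la * g(t)``.  Optional i.i.d. Gaussian point
jitter emulates tracing noise.

The synthetic proteome plants a small set of proteins with an exact
infarct/remote ratio and an exact R^2 against a per-subject mechanical
covariate; all remaining proteins are independent log-normal pairs with
expected ratio 1.  Generators are pure functions of their spec (seed
included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .contours import CineStudy, ContourPolygon, Layer, SliceFrame, Timepoint
from .errors import SpecError
from .proteomics import AbundanceTable
from .strain import Region, partition_regions

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ProteomeSpec",
    "PlantedProtein",
    "generate_phantom_study",
    "generate_synthetic_proteome",
    "half_ellipsoid_study",
]

HEALTHY_REGION_STRAIN = {"apex": -0.375, "mid": -0.35, "base": -0.33}
INFARCT_APEX_STRAIN = -0.18


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the deforming-LV contour phantom.

    Region peak strains default to healthy endocardial magnitudes
    (apex -0.375, mid -0.35, base -0.33); the infarct scenario prescribes
    apex -0.18 with mid/base unchanged.  ``epicardial_amplitude_factor``
    scales endocardial amplitudes for the epicardial border (epicardial
    shortening is smaller; the factor is a free parameter, default 0.6).
    """

    n_slices: int = 9
    n_frames: int = 25
    cycle_ms: float = 600.0
    equatorial_radius_mm: float = 25.0
    long_semi_axis_mm: float = 80.0
    slice_thickness_mm: float = 8.0
    wall_thickness_mm: float = 10.0
    region_peak_strain: Mapping[str, float] = field(
        default_factory=lambda: dict(HEALTHY_REGION_STRAIN)
    )
    long_axis_peak_strain: float = -0.22
    epicardial_amplitude_factor: float = 0.6
    systole_fraction: float = 0.4
    points_per_contour: int = 100
    noise_sd_mm: float = 0.0
    weight_kg: float = 62.5
    subject_id: str = "phantom"
    timepoint: Timepoint = Timepoint.BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 8:
            raise SpecError("n_frames must be >= 8")
        if not 0 < self.systole_fraction < 1:
            raise SpecError("systole_fraction must be in (0, 1)")
        for region, eps in self.region_peak_strain.items():
            if not -1.0 < eps <= 0.0:
                raise SpecError(f"{region} peak strain {eps} outside (-1, 0]")
        if not -1.0 < self.long_axis_peak_strain <= 0.0:
            raise SpecError("long-axis peak strain outside (-1, 0]")
        if self.n_slices * self.slice_thickness_mm > self.long_semi_axis_mm:
            raise SpecError("slice stack extends beyond the ellipsoid apex-base axis")
        if self.points_per_contour < 8:
            raise SpecError("points_per_contour must be >= 8")
        if self.noise_sd_mm < 0:
            raise SpecError("noise_sd_mm must be >= 0")

    @classmethod
    def healthy(cls, **overrides) -> "PhantomSpec":
        return cls(**overrides)

    @classmethod
    def infarcted_apex(cls, apex_strain: float = INFARCT_APEX_STRAIN, **overrides) -> "PhantomSpec":
        peaks = dict(HEALTHY_REGION_STRAIN)
        peaks["apex"] = apex_strain
        overrides.setdefault("timepoint", Timepoint.ACUTE)
        overrides.setdefault("subject_id", "phantom")
        return cls(region_peak_strain=peaks, **overrides)


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth accompanying a phantom study (noise-free laws)."""

    times_ms: np.ndarray
    g: np.ndarray  # systolic activation profile, 0..1
    slice_peak_strain: dict[int, float]  # endocardial eps_region per slice
    region_peak_strain: dict[str, float]
    global_peak_strain: float
    long_axis_peak_strain: float
    epicardial_amplitude_factor: float
    slice_radii_ed_mm: np.ndarray
    volumes_ml: np.ndarray  # exact disc (pi r^2) volume per frame
    edv_ml: float
    esv_ml: float
    lvef_pct: float
    systole_ms: float

    def slice_strain(self, slice_index: int) -> np.ndarray:
        """Endocardial strain curve of one slice, eps_i * g(t)."""
        return self.slice_peak_strain[slice_index] * self.g

    def region_strain(self, region: str) -> np.ndarray:
        return self.region_peak_strain[str(Region(region).value)] * self.g

    def global_strain(self) -> np.ndarray:
        return np.mean(
            [eps for eps in self.slice_peak_strain.values()], axis=0
        ) * self.g

    def strain_rate(self, peak_strain: float) -> np.ndarray:
        """Analytic d eps/dt (s^-1) sampled at frame times (not midpoints)."""
        t = self.times_ms
        ts = self.systole_ms
        rate = np.zeros_like(t)
        mask = t < ts
        rate[mask] = peak_strain * (math.pi / ts) * np.sin(2 * math.pi * t[mask] / ts) * 1000.0
        return rate


def _activation(times_ms: np.ndarray, cycle_ms: float, systole_fraction: float) -> np.ndarray:
    ts = systole_fraction * cycle_ms
    g = np.zeros_like(times_ms, dtype=float)
    mask = times_ms < ts
    g[mask] = np.sin(math.pi * times_ms[mask] / ts) ** 2
    return g


def _ellipsoid_radius(z_mm: np.ndarray, a_mm: float, c_mm: float) -> np.ndarray:
    """Short-axis radius of an apex-at-z=0 half ellipsoid at height z."""
    frac = (c_mm - np.asarray(z_mm, float)) / c_mm
    return a_mm * np.sqrt(np.clip(1.0 - frac**2, 0.0, None))


def _circle(radius: float, n_points: int, rng: np.random.Generator | None,
            noise_sd: float) -> np.ndarray:
    theta = 2 * math.pi * np.arange(n_points) / n_points
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    if rng is not None and noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return pts


def generate_phantom_study(spec: PhantomSpec) -> tuple[CineStudy, PhantomTruth]:
    """Build the deforming-LV contour study plus its analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    h = spec.slice_thickness_mm
    z = (np.arange(spec.n_slices) + 0.5) * h
    r_ed = _ellipsoid_radius(z, spec.equatorial_radius_mm, spec.long_semi_axis_mm)
    times = np.arange(spec.n_frames) * spec.cycle_ms / spec.n_frames
    g = _activation(times, spec.cycle_ms, spec.systole_fraction)

    partition = partition_regions(range(spec.n_slices))
    eps_slice = {
        i: float(spec.region_peak_strain[partition.region_of(i).value])
        for i in range(spec.n_slices)
    }

    short_axis: list[list[SliceFrame]] = []
    for i in range(spec.n_slices):
        cine = []
        for k in range(spec.n_frames):
            scale = 1.0 + eps_slice[i] * g[k]
            endo = ContourPolygon(
                _circle(r_ed[i] * scale, spec.points_per_contour, rng, spec.noise_sd_mm),
                Layer.ENDOCARDIUM,
            )
            epi_scale = 1.0 + spec.epicardial_amplitude_factor * eps_slice[i] * g[k]
            epi = ContourPolygon(
                _circle((r_ed[i] + spec.wall_thickness_mm) * epi_scale,
                        spec.points_per_contour, rng, spec.noise_sd_mm),
                Layer.EPICARDIUM,
            )
            cine.append(
                SliceFrame(
                    slice_index=i,
                    z_mm=float(z[i]),
                    thickness_mm=h,
                    frame_index=k,
                    time_ms=float(times[k]),
                    contours={Layer.ENDOCARDIUM: endo, Layer.EPICARDIUM: epi},
                )
            )
        short_axis.append(cine)

    # long-axis 4-chamber border: half-ellipse open polyline, uniformly scaled
    theta = np.linspace(0.0, math.pi, spec.points_per_contour)
    base_curve = np.column_stack(
        [spec.equatorial_radius_mm * np.cos(theta),
         -spec.long_semi_axis_mm * np.sin(theta)]
    )
    long_axis = []
    for k in range(spec.n_frames):
        contours = {}
        for layer, amp, offset in (
            (Layer.ENDOCARDIUM, 1.0, 0.0),
            (Layer.EPICARDIUM, spec.epicardial_amplitude_factor, spec.wall_thickness_mm),
        ):
            scale = 1.0 + amp * spec.long_axis_peak_strain * g[k]
            curve = (base_curve + offset * np.array([0.0, -1.0])) * scale
            if spec.noise_sd_mm > 0:
                curve = curve + rng.normal(0.0, spec.noise_sd_mm, curve.shape)
            contours[layer] = ContourPolygon(curve, layer, closed=False)
        long_axis.append(
            SliceFrame(
                slice_index=0, z_mm=0.0, thickness_mm=1.0,
                frame_index=k, time_ms=float(times[k]), contours=contours,
            )
        )

    study = CineStudy(
        subject_id=spec.subject_id,
        timepoint=spec.timepoint,
        weight_kg=spec.weight_kg,
        short_axis=short_axis,
        long_axis=long_axis,
    )

    scales = 1.0 + np.array([eps_slice[i] for i in range(spec.n_slices)])[:, None] * g[None, :]
    volumes = (math.pi * (r_ed[:, None] * scales) ** 2 * h).sum(axis=0) / 1000.0
    region_eps = {r.value: float(spec.region_peak_strain[r.value]) for r in Region}
    truth = PhantomTruth(
        times_ms=times,
        g=g,
        slice_peak_strain=eps_slice,
        region_peak_strain=region_eps,
        global_peak_strain=float(np.mean(list(eps_slice.values()))),
        long_axis_peak_strain=spec.long_axis_peak_strain,
        epicardial_amplitude_factor=spec.epicardial_amplitude_factor,
        slice_radii_ed_mm=r_ed,
        volumes_ml=volumes,
        edv_ml=float(volumes.max()),
        esv_ml=float(volumes.min()),
        lvef_pct=float(100.0 * (volumes.max() - volumes.min()) / volumes.max()),
        systole_ms=spec.systole_fraction * spec.cycle_ms,
    )
    return study, truth


def half_ellipsoid_study(
    a_mm: float = 25.0,
    c_mm: float = 80.0,
    n_slices: int = 80,
    thickness_mm: float = 1.0,
    points_per_contour: int = 100,
    n_frames: int = 1,
) -> CineStudy:
    """A static half-ellipsoid contour stack (midpoint-sampled slices).

    Volume oracle fixture: the analytic blood-pool volume is
    ``(2/3) pi a^2 c``.  No deformation; every frame is identical.
    """
    z = (np.arange(n_slices) + 0.5) * thickness_mm
    radii = _ellipsoid_radius(z, a_mm, c_mm)
    short_axis = []
    for i in range(n_slices):
        cine = []
        for k in range(n_frames):
            poly = ContourPolygon(
                _circle(float(radii[i]), points_per_contour, None, 0.0),
                Layer.ENDOCARDIUM,
            )
            cine.append(
                SliceFrame(
                    slice_index=i, z_mm=float(z[i]), thickness_mm=thickness_mm,
                    frame_index=k, time_ms=float(k * 40.0),
                    contours={Layer.ENDOCARDIUM: poly},
                )
            )
        short_axis.append(cine)
    return CineStudy(
        subject_id="half-ellipsoid", timepoint=Timepoint.BASELINE,
        weight_kg=62.5, short_axis=short_axis,
    )


# ---------------------------------------------------------------------------
# synthetic proteome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedProtein:
    protein_id: str
    ratio: float
    r_squared: float


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of the synthetic paired proteome.

    Planted proteins carry an exact infarct/remote ratio (>= 2 so the
    twofold filter must recover them) and an infarct abundance exactly
    linear in the covariate up to a residual solved analytically to hit
    ``planted_r2``.  Null proteins are independent log-normal pairs with
    expected log-ratio 0; ``abundance_log_sd`` (default 0.25, i.e. ~25%
    coefficient of variation) keeps null geometric-mean ratios far below
    the twofold line at the default subject count.
    """

    n_proteins: int = 500
    n_subjects: int = 5
    n_planted: int = 10
    planted_ratio: float = 2.5
    planted_r2: float = 0.99
    covariate: tuple[float, ...] | None = None  # default: spread of ECSR-like values
    abundance_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted >= self.n_proteins:
            raise SpecError("n_planted must be < n_proteins")
        if self.planted_ratio < 2.0:
            raise SpecError("planted_ratio must be >= 2 (twofold filter truth)")
        if not 0.0 < self.planted_r2 <= 1.0:
            raise SpecError("planted_r2 must be in (0, 1]")
        if self.planted_r2 < 1.0 and self.n_subjects < 3:
            raise SpecError("planted_r2 < 1 needs >= 3 subjects for a residual")
        if self.covariate is not None and len(self.covariate) != self.n_subjects:
            raise SpecError("covariate length must equal n_subjects")

    def covariate_values(self) -> np.ndarray:
        if self.covariate is not None:
            return np.asarray(self.covariate, dtype=float)
        # equatorial circumferential strain-rate-like spread, s^-1
        return np.linspace(-1.5, -0.5, self.n_subjects)


def generate_synthetic_proteome(
    spec: ProteomeSpec,
) -> tuple[AbundanceTable, list[PlantedProtein]]:
    """Build the paired abundance table and its planted-protein truth list."""
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_proteins, spec.n_subjects
    subjects = [f"S{j + 1}" for j in range(s)]
    proteins = [f"P{i + 1:04d}" for i in range(n)]
    planted_idx = np.sort(rng.choice(n, size=spec.n_planted, replace=False))

    base = np.exp(rng.normal(0.0, 1.0, size=n))  # per-protein abundance scale
    infarct = base[:, None] * np.exp(rng.normal(0.0, spec.abundance_log_sd, (n, s)))
    remote = base[:, None] * np.exp(rng.normal(0.0, spec.abundance_log_sd, (n, s)))

    c = spec.covariate_values()
    u = (c - c.mean()) / c.std(ddof=1)
    truth: list[PlantedProtein] = []
    for idx in planted_idx:
        # infarct abundance exactly linear in the covariate, residual
        # orthogonal to {1, c} scaled to achieve R^2 = planted_r2 exactly
        amp = base[idx]
        signal = 2.0 - u  # more shortening (more negative rate) -> higher abundance
        if spec.planted_r2 < 1.0:
            e = rng.standard_normal(s)
            design = np.column_stack([np.ones(s), u])
            e = e - design @ np.linalg.lstsq(design, e, rcond=None)[0]
            norm = np.linalg.norm(e)
            if norm == 0:  # pragma: no cover - probability zero
                raise SpecError("degenerate residual draw")
            target = math.sqrt((s - 1) * (1.0 - spec.planted_r2) / spec.planted_r2)
            e = e / norm * target
        else:
            e = np.zeros(s)
        inf_values = amp * (signal + e)
        if np.any(inf_values <= 0):
            raise SpecError(
                "planted abundance went non-positive; raise planted_r2 or "
                "narrow the covariate spread"
            )
        infarct[idx] = inf_values
        remote[idx] = inf_values / spec.planted_ratio
        truth.append(
            PlantedProtein(proteins[idx], spec.planted_ratio, spec.planted_r2)
        )

    table = AbundanceTable(
        pd.DataFrame(infarct, index=proteins, columns=subjects),
        pd.DataFrame(remote, index=proteins, columns=subjects),
    )
    return table, truth
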