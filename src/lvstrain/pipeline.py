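"""End-to-end orchestration: studies in, strain/volume/stats/proteomics
tables out, with a deterministic manifest.

Every numeric output is produced by a stage module (`strain`,
`volumetrics`, `stats`, `proteomics`); this module only routes data,
writes the CSV dialects defined by those modules, and hashes the outputs.
Identical inputs and configuration yield an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as lvstats
from .contours import CineStudy, Layer, read_contour_study, validate_study
from .errors import DataError, ParameterError, PipelineError
from .proteomics import (
    AbundanceTable,
    abundance_ratio,
    fold_filter,
    regression_screen,
    volcano_table,
)
from .strain import (
    Direction,
    aggregate_strain,
    longitudinal_strain,
    partition_regions,
    peak_value,
    slice_strain_curves,
)
from .volumetrics import end_diastolic_frame, function_metrics, volume_series

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lvstrain.pipeline")


@dataclass
class PipelineConfig:
    """Declarative configuration for :func:`run_pipeline`.

    All paper-gap choices are surfaced: the peak convention, the ratio
    aggregation, the screen regressand and every threshold.
    """

    studies_dir: str | Path
    out_dir: str | Path
    abundance_tsv: str | Path | None = None
    covariate_csv: str | Path | None = None
    fold_threshold: float = 2.0
    r2_threshold: float = 0.95
    alpha: float = 0.05
    bonferroni_m: int = 21
    peak_convention: str = "most_negative"
    ratio_aggregation: str = "geometric_mean"
    regressand: str = "infarct"
    reference_frame: int | None = None  # None -> max-volume rule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.r2_threshold <= 0 or self.alpha <= 0:
            raise ParameterError("thresholds must be positive")
        if self.bonferroni_m < 1:
            raise ParameterError("bonferroni_m must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def _scope_label(scope: tuple[str, object]) -> str:
    kind, detail = scope
    if kind == "slice":
        return f"slice_{detail}"
    if kind == "region":
        return getattr(detail, "value", str(detail))
    return "global"


def _study_curves(study: CineStudy, reference_frame: int | None):
    """All strain and strain-rate curves of one study, tagged for output."""
    ref = end_diastolic_frame(study) if reference_frame is None else reference_frame
    curves = []
    for layer in Layer:
        try:
            per_slice = slice_strain_curves(study, layer, ref, is_rate=False)
            per_slice_rate = slice_strain_curves(study, layer, ref, is_rate=True)
        except DataError:
            continue  # layer absent on this study
        partition = partition_regions(sorted(per_slice))
        for group in (per_slice, per_slice_rate):
            curves.extend(group.values())
            for region in ("apex", "mid", "base"):
                curves.append(aggregate_strain(group, partition, region))
            curves.append(aggregate_strain(group, partition, "global"))
        if study.long_axis and all(
            layer in f.contours for f in study.long_axis
        ):
            curves.append(longitudinal_strain(study, layer, ref, is_rate=False))
            curves.append(longitudinal_strain(study, layer, ref, is_rate=True))
    return curves


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written to
    ``<out_dir>/manifest.json``).  Raises :class:`PipelineError` with a
    stage-naming message on failure."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    study_paths = sorted(Path(config.studies_dir).glob("*.json"))
    if not study_paths:
        raise PipelineError(f"INPUT_MISSING: no study JSON files in {config.studies_dir}")

    studies: list[CineStudy] = []
    for path in study_paths:
        study = read_contour_study(path)
        report = validate_study(study)
        if not report.ok:
            first = report.errors[0]
            raise PipelineError(
                f"VALIDATION: {path.name}: {first.code}: {first.message}"
            )
        studies.append(study)
    log.info("loaded %d studies", len(studies))

    outputs: list[Path] = []

    # ---- strain stage ----------------------------------------------------
    curve_rows, peak_rows = [], []
    peak_metrics: dict[tuple[str, str], dict[str, list[float]]] = {}
    for study in studies:
        for curve in _study_curves(study, config.reference_frame):
            scope = _scope_label(curve.scope)
            for k, (t, v) in enumerate(zip(curve.times_ms, curve.values)):
                curve_rows.append(
                    dict(subject_id=study.subject_id, timepoint=study.timepoint.value,
                         direction=curve.direction.value, layer=curve.layer.value,
                         scope=scope, is_rate=curve.is_rate, frame_index=k,
                         time_ms=t, value=v)
                )
            peak = peak_value(curve, config.peak_convention)
            peak_rows.append(
                dict(subject_id=study.subject_id, timepoint=study.timepoint.value,
                     direction=curve.direction.value, layer=curve.layer.value,
                     scope=scope, is_rate=curve.is_rate,
                     convention=peak.convention, frame_index=peak.frame_index,
                     value=peak.value)
            )
            if scope in ("apex", "mid", "base", "global"):
                name = _metric_name(curve.direction, curve.layer.value, scope, curve.is_rate)
                peak_metrics.setdefault((name, study.timepoint.value), {}).setdefault(
                    "values", []
                ).append(peak.value)
    outputs.append(_write_csv(pd.DataFrame(curve_rows), out_dir / "strain_curves.csv"))
    outputs.append(_write_csv(pd.DataFrame(peak_rows), out_dir / "strain_peaks.csv"))

    # ---- volumetrics stage ----------------------------------------------
    metric_rows = []
    baselines: dict[str, object] = {}
    for study in sorted(studies, key=lambda s: (s.subject_id,
                                                list(s.timepoint.__class__).index(s.timepoint))):
        vols = volume_series(study)
        baseline = baselines.get(study.subject_id)
        metrics = function_metrics(vols, study.weight_kg, baseline)
        if study.timepoint.value == "baseline":
            baselines[study.subject_id] = metrics
        metric_rows.append(
            dict(subject_id=study.subject_id, timepoint=study.timepoint.value,
                 lvedv_ml=metrics.lvedv_ml, lvesv_ml=metrics.lvesv_ml,
                 lvef_pct=metrics.lvef_pct, bsa_m2=metrics.bsa_m2,
                 lvesvi_ml_per_m2=metrics.lvesvi_ml_per_m2,
                 remodelling=metrics.remodelling)
        )
        peak_metrics.setdefault(("lvef_pct", study.timepoint.value), {}).setdefault(
            "values", []
        ).append(metrics.lvef_pct)
    outputs.append(_write_csv(pd.DataFrame(metric_rows), out_dir / "function_metrics.csv"))

    # ---- cohort statistics stage ----------------------------------------
    stats_rows = []
    threshold = lvstats.bonferroni_threshold(config.alpha, config.bonferroni_m)
    metric_names = sorted({name for name, _ in peak_metrics})
    for name in metric_names:
        groups = {
            tp: lvstats.GroupSample(tp, np.array(vals["values"]))
            for (n_, tp), vals in sorted(peak_metrics.items())
            if n_ == name
        }
        if "baseline" not in groups or len(groups) < 2:
            continue
        group_list = list(groups.values())
        kw = None
        if sum(len(g) for g in group_list) >= 3:
            kw = lvstats.kruskal_wallis(group_list)
        base = groups["baseline"]
        med_b = lvstats.median_ci(base) if len(base) > 1 else (base.values[0],) * 3 + (0.0,)
        for tp, sample in groups.items():
            if tp == "baseline":
                continue
            mw = lvstats.mann_whitney(base, sample)
            med_a = (
                lvstats.median_ci(sample)
                if len(sample) > 1
                else (sample.values[0],) * 3 + (0.0,)
            )
            stats_rows.append(
                dict(metric=name, timepoint_a="baseline", timepoint_b=tp,
                     median_a=med_b[0], ci_a_lo=med_b[1], ci_a_hi=med_b[2],
                     median_b=med_a[0], ci_b_lo=med_a[1], ci_b_hi=med_a[2],
                     method=mw.method, statistic=mw.statistic, p=mw.p_value,
                     kruskal_wallis_p=kw.p_value if kw else float("nan"),
                     significant_unadjusted=bool(mw.p_value < config.alpha),
                     significant_bonferroni=bool(mw.p_value < threshold))
            )
    outputs.append(_write_csv(pd.DataFrame(stats_rows), out_dir / "stats_report.csv"))

    # ---- proteomics stage ------------------------------------------------
    if config.abundance_tsv is not None:
        table = AbundanceTable.from_tsv(config.abundance_tsv)
        ratios = abundance_ratio(table, config.ratio_aggregation)
        hits = fold_filter(ratios, config.fold_threshold)
        log.info("fold filter: %d of %d proteins >= %.1f-fold",
                 len(hits), len(ratios), config.fold_threshold)
        if config.covariate_csv is None:
            raise PipelineError("COVARIATE_MISSING: proteomics screen needs covariate_csv")
        cov_df = pd.read_csv(config.covariate_csv)
        covariate = dict(zip(cov_df["subject_id"], cov_df["value"].astype(float)))
        _, records = regression_screen(
            table, covariate, config.r2_threshold, candidates=hits,
            regressand=config.regressand,
        )
        assoc = pd.DataFrame(
            [dataclasses.asdict(r) for r in records]
        )
        outputs.append(_write_csv(assoc, out_dir / "associations.csv"))
        volcano = pd.DataFrame([dataclasses.asdict(r) for r in volcano_table(table)])
        outputs.append(_write_csv(volcano, out_dir / "volcano.csv"))

    # ---- manifest --------------------------------------------------------
    manifest = {
        "n_studies": len(studies),
        "outputs": {
            p.name: {"path": str(p), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(outputs)
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _metric_name(direction: Direction, layer: str, scope: str, is_rate: bool) -> str:
    if direction is Direction.LONGITUDINAL:
        stem = "gls"
    else:
        stem = {"apex": "acs", "mid": "ecs", "base": "bcs", "global": "gcs"}[scope]
    name = f"{stem}_{layer}"
    return name + "_rate" if is_rate else name
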