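"""Infarct/remote proteomics: abundance ratios, fold filtering, and the
per-protein regression screen against a mechanical covariate.

Each heart contributes a paired sample: protein abundance in the infarcted
territory and in remote viable myocardium.  Per-subject infarct/remote
ratios are aggregated across subjects (geometric mean by default, median
optional); proteins at least twofold over-expressed pass the fold filter;
candidate proteins are then regressed one at a time on a scalar mechanical
covariate (e.g. the acute equatorial circumferential strain rate) and kept
when R^2 reaches the focus threshold (default 0.95).  Volcano coordinates
(aggregated ratio vs -log10 of a paired t-test p on log-abundances) are
also produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

__all__ = [
    "AbundanceTable",
    "AssociationRecord",
    "VolcanoRow",
    "abundance_ratio",
    "fold_filter",
    "regression_screen",
    "volcano_table",
]


@dataclass
class AbundanceTable:
    """Proteins x paired (infarct, remote) abundances, aligned by subject.

    ``infarct`` and ``remote`` are DataFrames indexed by protein id with one
    column per subject.  Proteins with a missing territory in any subject
    are flagged and excluded from ratio-based operations.
    """

    infarct: pd.DataFrame
    remote: pd.DataFrame
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.infarct.index.equals(self.remote.index):
            raise DataError("infarct/remote protein indices differ")
        if list(self.infarct.columns) != list(self.remote.columns):
            raise DataError("infarct/remote subject columns differ")
        missing = (
            self.infarct.isna().any(axis=1) | self.remote.isna().any(axis=1)
        )
        self.flagged = sorted(set(self.flagged) | set(self.infarct.index[missing]))
        complete_i = self.infarct[~missing]
        complete_r = self.remote[~missing]
        if (complete_i.values <= 0).any() or (complete_r.values <= 0).any():
            raise DataError("abundances must be strictly positive")

    @property
    def proteins(self) -> list[str]:
        return list(self.infarct.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.infarct.columns)

    def complete(self) -> "AbundanceTable":
        """Table restricted to proteins with both territories in all subjects."""
        keep = ~self.infarct.index.isin(self.flagged)
        return AbundanceTable(self.infarct[keep], self.remote[keep])

    def swapped(self) -> "AbundanceTable":
        """Territories exchanged (remote <-> infarct); ratio symmetry checks."""
        return AbundanceTable(self.remote.copy(), self.infarct.copy(), list(self.flagged))

    # -- TSV dialect: protein_id, then <subject>__infarct / <subject>__remote
    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        subjects: list[str] = []
        for col in df.columns:
            if col.endswith("__infarct"):
                subjects.append(col[: -len("__infarct")])
        if not subjects:
            raise DataError(f"{path}: no <subject>__infarct columns found")
        for s in subjects:
            if f"{s}__remote" not in df.columns:
                raise DataError(f"{path}: subject {s} lacks a __remote column")
        infarct = df[[f"{s}__infarct" for s in subjects]].set_axis(subjects, axis=1)
        remote = df[[f"{s}__remote" for s in subjects]].set_axis(subjects, axis=1)
        return cls(infarct, remote)

    def to_tsv(self, path: str | Path) -> Path:
        out = pd.DataFrame(index=self.infarct.index)
        out.index.name = "protein_id"
        for s in self.subjects:
            out[f"{s}__infarct"] = self.infarct[s]
            out[f"{s}__remote"] = self.remote[s]
        out.to_csv(path, sep="\t", lineterminator="\n")
        return Path(path)


@dataclass(frozen=True)
class AssociationRecord:
    """Per-protein OLS fit of abundance against a mechanical covariate."""

    protein_id: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    passes_screen: bool = False


@dataclass(frozen=True)
class VolcanoRow:
    protein_id: str
    ratio: float
    log2_ratio: float
    p_value: float
    neg_log10_p: float


def abundance_ratio(
    table: AbundanceTable, aggregation: str = "geometric_mean"
) -> pd.Series:
    """Infarct/remote ratio per protein, aggregated across subjects.

    The geometric mean (default) is the natural aggregate for a
    multiplicative quantity and is exactly reciprocal under territory swap;
    the per-subject median is available as ``aggregation='median'``.
    """
    tab = table.complete()
    per_subject = tab.infarct.values / tab.remote.values
    if aggregation == "geometric_mean":
        agg = np.exp(np.mean(np.log(per_subject), axis=1))
    elif aggregation == "median":
        agg = np.median(per_subject, axis=1)
    else:
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    return pd.Series(agg, index=tab.infarct.index, name="ratio")


def fold_filter(ratios: Mapping[str, float] | pd.Series, threshold: float = 2.0) -> list[str]:
    """Proteins with ratio >= threshold (inclusive), sorted by descending
    ratio (ties broken by protein id for determinism)."""
    series = pd.Series(ratios)
    hits = series[series >= threshold]
    return list(hits.sort_index().sort_values(ascending=False, kind="stable").index)


def _vectorised_ols(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS of each row of Y on x: slopes, intercepts, R^2, two-sided p.

    R^2 is defined as 0 for a zero-variance (constant) response, with p = 1;
    the t statistic uses n - 2 df.
    """
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ParameterError("zero-variance covariate")
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    syy = np.einsum("ij,ij->i", yc, yc)
    slope = sxy / sxx
    intercept = Y.mean(axis=1) - slope * x.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = (n - 2) * r2 / (1.0 - r2)  # inf when r2 == 1
    p = 2.0 * sps.t.sf(np.sqrt(t2), df=n - 2)
    p = np.where(syy > 0, p, 1.0)
    return slope, intercept, r2, p


def regression_screen(
    table: AbundanceTable,
    covariate: Mapping[str, float],
    r2_threshold: float = 0.95,
    candidates: Sequence[str] | None = None,
    regressand: str = "infarct",
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Univariate OLS of per-protein abundance on a scalar covariate.

    Regresses the infarct-territory abundance (default) or the per-subject
    infarct/remote ratio on the covariate, one protein at a time, and flags
    records reaching ``r2_threshold``.  Returns ``(passing, all_records)``.
    """
    tab = table.complete()
    subjects = tab.subjects
    missing = [s for s in subjects if s not in covariate]
    if missing:
        raise DataError(f"covariate missing for subjects: {missing}")
    if len(subjects) < 3:
        raise ParameterError("regression screen needs >= 3 subjects")
    if candidates is None:
        candidates = tab.proteins
    else:
        unknown = set(candidates) - set(tab.proteins)
        if unknown:
            raise DataError(f"candidate proteins not in table: {sorted(unknown)}")
    x = np.array([float(covariate[s]) for s in subjects])
    if regressand == "infarct":
        Y = tab.infarct.loc[list(candidates)].values
    elif regressand == "ratio":
        Y = (tab.infarct / tab.remote).loc[list(candidates)].values
    else:
        raise ParameterError(f"unknown regressand {regressand!r}")
    slope, intercept, r2, p = _vectorised_ols(x, Y)
    records = [
        AssociationRecord(
            protein_id=pid,
            slope=float(slope[i]),
            intercept=float(intercept[i]),
            r_squared=float(r2[i]),
            p_value=float(p[i]),
            n=len(subjects),
            passes_screen=bool(r2[i] >= r2_threshold),
        )
        for i, pid in enumerate(candidates)
    ]
    passing = [r for r in records if r.passes_screen]
    return passing, records


def volcano_table(
    table: AbundanceTable, aggregation: str = "geometric_mean"
) -> list[VolcanoRow]:
    """Volcano coordinates: aggregated ratio vs paired-t significance.

    The p-value is a two-sided paired t-test on natural-log abundances
    (infarct vs remote across subjects).  A protein with identical
    territories in every subject gets p = 1 by convention; rows are sorted
    by descending -log10 p (ties by protein id).
    """
    tab = table.complete()
    if len(tab.subjects) < 2:
        raise DataError("volcano table needs >= 2 paired subjects")
    ratios = abundance_ratio(tab, aggregation)
    log_diff = np.log(tab.infarct.values) - np.log(tab.remote.values)
    rows = []
    for i, pid in enumerate(tab.proteins):
        d = log_diff[i]
        if np.allclose(d, 0.0):
            p = 1.0
        elif np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
            p = 0.0  # constant nonzero log-difference: zero within-pair variance
        else:
            p = float(sps.ttest_rel(np.log(tab.infarct.values[i]),
                                    np.log(tab.remote.values[i])).pvalue)
        ratio = float(ratios[pid])
        rows.append(
            VolcanoRow(
                protein_id=pid,
                ratio=ratio,
                log2_ratio=float(np.log2(ratio)),
                p_value=p,
                neg_log10_p=float(-np.log10(p)) if p > 0 else float("inf"),
            )
        )
    rows.sort(key=lambda r: (-r.neg_log10_p, r.protein_id))
    return rows
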