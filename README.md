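# lvstrain

Contour-based regional myocardial strain analysis for serial cardiac
cine imaging, with ventricular volumetrics, small-cohort nonparametric
statistics, and a proteomics–strain association screen.

## Who this is for

Groups following left-ventricular (LV) function after myocardial
infarction — in large-animal models or clinical cohorts — who trace
endocardial and epicardial borders on short-axis and 4-chamber cine
stacks and want a transparent, non-proprietary strain metric instead of
vendor feature-tracking. The package consumes traced contours (a simple
JSON/CSV dialect; no DICOM parsing), not images.

## The method

**Strain.** For each short-axis slice the circumferential strain at
frame *n* is the fractional change of the border perimeter relative to
end-diastole (ED):

    ε(tₙ) = (L(tₙ) − L₀) / L₀

where *L₀* is the perimeter at ED (the frame of maximal blood-pool
volume). The strain rate is the forward difference between successive
frames, in s⁻¹:

    ε̇(tₙ) = (L(tₙ₊₁) − L(tₙ)) / (L₀ · Δt)

Slices (typically 7–9, apex→base) are grouped into three contiguous
regions — apex, equator/mid, base, 2–3 slices each — and regional
curves are pointwise means over member slices; the global
circumferential strain (GCS) averages all slices. The 4-chamber
long-axis border (an open polyline) feeds the identical formula to give
global longitudinal strain (GLS). Everything runs per layer
(endocardium / epicardium). Peaks default to the most-negative value
(systolic shortening).

**Volumetrics.** Blood-pool volume is the disc summation
Σ slices (endocardial area × thickness); LVEF = 100·(EDV−ESV)/EDV;
body surface area uses the porcine allometric relation
BSA = 0.0734·W^0.656 (m², W in kg); LVESVi = ESV/BSA. LV remodelling
(LVR) is a ≥ 10 % change in **both** EDV and ESV versus baseline.

**Statistics.** Medians with distribution-free order-statistic CIs, a
Kruskal–Wallis gate across timepoints, pairwise Mann–Whitney follow-up
(exact by full enumeration at small n), Bonferroni thresholding
(α/m), and Pearson/Spearman correlation of strain with scalar
covariates.

**Proteomics screen.** Per-heart infarct/remote abundance ratios
(geometric-mean aggregated), an inclusive twofold over-expression
filter, per-protein OLS of abundance on a mechanical covariate with an
R² ≥ 0.95 focus rule, and volcano coordinates (ratio vs −log₁₀ p of a
paired t-test on log abundances).

**Synthetic ground truth.** A truncated half-ellipsoid phantom deforms
each slice radius as r(z,t) = r_ED(z)·(1 + ε_region(z)·g(t)) with a
raised-cosine systolic profile g, so every strain, volume and LVEF has
an analytic truth; a synthetic proteome plants proteins with exact
ratios and exact R². These make every stage testable without imaging
data.

## Worked example

```bash
python examples/01_phantom_strain.py
```

```
healthy baseline (9 slices x 25 frames)
  apex  CS peak -0.3750  (prescribed -0.3750)
  mid   CS peak -0.3500  (prescribed -0.3500)
  base  CS peak -0.3300  (prescribed -0.3300)
  global CS peak -0.3517  (slice-mean truth -0.3517)
  global LS peak -0.2200  (prescribed -0.2200)

apical infarct (9 slices x 25 frames)
  apex  CS peak -0.1800  (prescribed -0.1800)
  mid   CS peak -0.3500  (prescribed -0.3500)
  base  CS peak -0.3300  (prescribed -0.3300)
  global CS peak -0.2867  (slice-mean truth -0.2867)
```

The pipeline recovers the prescribed shortening exactly on a noise-free
phantom. Note the infarct signature: apical CS weakens from −0.375 to
−0.18 (Δ ≈ 0.20) while global CS only moves from −0.35 to −0.29
(Δ ≈ 0.07) — a regional metric is the more sensitive marker of a focal
injury. The other examples cover volumes/remodelling
(`02_volumes_remodelling.py`: LVEF 56.6 % from mean volumes 131/56.8 ml,
remodelling = True for 131→194.6 / 56.8→100.4 ml), cohort statistics
(`03_cohort_stats.py`) and the proteomics screen
(`04_proteomics_screen.py`: 10/10 planted proteins recovered and passing
R² ≥ 0.95).

A thin CLI wraps the same stages:

```bash
lvstrain simulate --scenario infarct-apical --seed 3 --out data/
lvstrain run-all --config config.yaml
```

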