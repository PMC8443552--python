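# Methods

This note documents the models, conventions and numerical choices behind
`lvstrain`, and what the synthetic generators do and do not emulate.

## Perimeter strain

Circumferential strain of a traced border is ε = (L − L₀)/L₀ with L the
border perimeter at a frame and L₀ its value at end-diastole (ED). The
perimeter of a closed contour is the chord sum over its vertices
including the wrap segment; contours are stored without repeating the
first point so no segment is double-counted. Because an inscribed
N-gon's perimeter is 2NR·sin(π/N) for a circle of radius R, the chord
discretisation factor multiplies both L and L₀ and **cancels exactly**
in ε — strain is insensitive to point density on smooth contours; raw
perimeters, not resampled ones, enter the strain computation.

ED identification: the frame of maximal endocardial blood-pool volume,
falling back to frame 0 when volumes cannot be computed; overridable per
study. Strain is set to exactly 0 at the reference frame.

Strain rate is the forward difference ε̇ₙ = (Lₙ₊₁ − Lₙ)/(L₀·Δtₙ), Δt in
seconds. The curve has (frames − 1) samples timestamped at interval
midpoints, where a forward difference of a smooth signal is second-order
accurate; at 25 frames over a 600 ms cycle with a 240 ms systole the
worst-case error is sinc(ωΔt/2) ≈ 1.6 % of the peak rate. Because the
difference telescopes, cumulative summation of ε̇·Δt reconstructs the
strain curve to machine precision.

Peak convention: most-negative value (systolic shortening) for both
strain and strain rate, ties broken to the earliest frame;
most-positive and largest-magnitude conventions are available. Curves
are averaged across slices first and the peak taken from the averaged
curve, not the mean of per-slice peaks (the two agree when slice curves
are time-aligned, as in the phantom).

## Regional partition

Slices are indexed 0 from the apex. Apex/mid/base blocks are contiguous
with sizes as equal as possible; when the count is not divisible by 3
the extra slices go to the apex block first, then mid (7 → 3/2/2,
8 → 3/3/2, 9 → 3/3/3). The rule is arbitrary where block sizes are
genuinely ambiguous; it is deterministic, documented, and biased toward
resolution in the apical territory where focal injury is most often
assessed. Global CS is the mean over all slices, which equals the
slice-count-weighted mean of the three regional curves.

## Volumes and derived metrics

Disc summation: volume = Σ slices (shoelace area of the endocardial
polygon × slice thickness), mm³ → ml at 1000 mm³/ml, no partial-slice
correction and no blood-density correction. On a half-ellipsoid sampled
at slice midpoints the Riemann error is O(h²) (the integrand is
quadratic in z, so midpoint sampling is nearly exact; at 8 × 10 mm
slices the error is ≈ 0.13 %); the polygon-vs-circle area deficit is
sin(2π/N)/(2π/N) (≈ 0.07 % at N = 100). LVEF = 100·(EDV−ESV)/EDV is
invariant to both factors. BSA = 0.0734·W^0.656 m² (porcine allometric
fit; W in kg); LVESVi = ESV/BSA. Remodelling: |ΔEDV|/EDV₀ ≥ 10 % AND
|ΔESV|/ESV₀ ≥ 10 %, threshold inclusive.

## Nonparametric statistics

*Median CI*: the smallest symmetric order-statistic pair
[x₍ⱼ₎, x₍ₙ₊₁₋ⱼ₎] whose exact binomial coverage 1 − 2·P(Bin(n,½) ≤ j−1)
reaches the requested level; the achieved coverage is always reported.
For n ≤ 5 at 95 % no pair suffices; the sample range is returned with
its coverage and a warning.

*Mann–Whitney*: U counts x-over-y pairs with half-credit for ties. For
pooled n ≤ 12 the two-sided p is exact by full enumeration of all
C(nₓ+n_y, nₓ) labelings on pooled midranks, p = min(1, 2·min(tail
probabilities)) — feasible and deterministic at typical cohort sizes
(≤ 10 subjects). Larger samples use a normal approximation with
tie-corrected variance and **no continuity correction**, so that for two
groups the Kruskal–Wallis identity H = z² holds exactly; the
approximation's mid-p gap versus exact enumeration is a few hundredths
at 8 vs 8.

*Kruskal–Wallis*: tie-corrected H with χ²(k−1) p (scipy), with the
all-identical degenerate case defined as H = 0, p = 1.

*Correlation*: Pearson (t-distribution p) and Spearman (exact
permutation over all n! orderings for n ≤ 8, asymptotic above). The
Bonferroni threshold is α/m with m a required user input — the
hypothesis count is study-specific and never inferred.

The inference chain for serial cohorts is: Kruskal–Wallis gate at 0.05,
pairwise Mann–Whitney versus baseline, Bonferroni-corrected label on the
pairwise layer. One-way ANOVA with post-hoc testing is deliberately
excluded to keep a single authoritative nonparametric path.

## Proteomics screen

Per-subject infarct/remote ratios are aggregated by geometric mean
(default) — the natural aggregate for a multiplicative quantity, exactly
reciprocal under territory swap — or median. The fold filter is
inclusive at 2.0. The regression screen fits OLS of the
infarct-territory abundance (optionally the ratio) on the covariate for
every candidate protein; R² is defined as 0 for a constant response;
p comes from the t statistic with n−2 df. The implementation is
vectorised across proteins so that 10⁴-protein null calibrations run in
milliseconds; it is cross-checked against per-protein `scipy
linregress` in the tests. Under an independent Gaussian null with n
subjects, R² ~ Beta(½, (n−2)/2); at n = 4 the pass rate of the 0.95
screen is 1 − √0.95 ≈ 2.5 %, which the tests verify by simulation. No
multiple-testing correction is applied inside the screen; raw p is
reported next to R². Volcano p-values are two-sided paired t-tests on
natural-log abundances; identical territories give p = 1, an exactly
constant nonzero log-difference p = 0 by convention.

## Synthetic generators

*Cine phantom.* A truncated half-ellipsoid LV (equatorial radius 25 mm,
long semi-axis 80 mm), 9 slices of 8 mm sampled at slice-centre heights,
25 frames over a 600 ms cycle. Slice radius follows
r(z,t) = r_ED(z)·(1 + ε_region(z)·g(t)) with g(t) = sin²(πt/T_s) during
the systolic window (T_s = 0.4 cycle) and 0 through diastole — smooth,
differentiable (so an analytic strain-rate oracle exists), and minimal
in parameters. Region peak strains default to healthy endocardial
magnitudes (apex −0.375, mid −0.35, base −0.33); the infarct scenario
sets apex −0.18. The epicardium sits one wall thickness (10 mm) outward
with amplitudes scaled by 0.6 — epicardial shortening is smaller than
endocardial, and the factor is a documented free parameter, not a
measured quantity. The long-axis border is a half-ellipse polyline
scaled by 1 + ε_la·g(t) (default ε_la = −0.22). Noise is i.i.d.
Gaussian jitter on contour points. Generators are pure functions of
their spec (seed included); identical specs give byte-identical files.

What the phantom does **not** emulate: wall thickening, torsion, fibre
mechanics, through-plane motion, slice misregistration, non-circular
cross-sections, and observer-dependent tracing bias. Passing tests
demonstrate the computational pipeline is correct against analytic
truth, not that the strain values are accurate on real cine imaging.

*Noise and perimeter bias.* i.i.d. point jitter inflates chord sums:
with spacing μ and jitter σ per coordinate, E‖segment‖ ≈ √(μ² + 2σ²),
so at 100 points on apex-sized contours (μ ≈ 0.5–1 mm) a 0.5 mm jitter
inflates ED and ES perimeters unequally and attenuates strain severely
(raw recovery of an apical −0.18 peak comes out near −0.05). The
mitigation used in tests and documented as the recommended ingestion for
jittery contours: circular moving-average smoothing (window 5) followed
by arc-length resampling to ~25 points, after which the apical peak is
recovered within ~3 %. The deterministic chord-shortening of coarse
resampling cancels in the strain ratio.

*Proteome.* 500 proteins × 5 subjects. Null proteins: infarct and
remote independently log-normal around a shared per-protein level
(log-sd 0.25, ~25 % CV, typical label-free reproducibility), expected
ratio 1; the geometric-mean ratio then has log-sd ≈ 0.16, putting the
twofold line > 4 standard deviations out so planted-recovery is exact
for essentially every seed. Planted proteins (10): infarct abundance
linear in the covariate with the residual drawn, orthogonalised against
{1, covariate} and rescaled so the regression R² equals the target
exactly; remote = infarct / ratio so the per-subject ratio is exact.
(A remote drawn log-normally with infarct = remote·ratio cannot be
exactly linear in the covariate at the same time; exactness of both
planted properties was chosen as the more useful truth.) The default
covariate is an equatorial strain-rate-like spread, −1.5 … −0.5 s⁻¹.

## Degenerate inputs and tie-breaks

Peaks: ties to the earliest frame. Resampling starts at the first
stored vertex, so original vertices on multiples of the new spacing are
reproduced exactly; re-resampling at the same count is the identity once
segment lengths are uniform (e.g. when the new count divides the old).
Mask boundary extraction follows pixel edges (crack boundary), giving
exact pixel-count area oracles; masks must be a single 4-connected
component, holes warn and return the outer boundary. Validation reports
structural problems (frame counts, time base, z-order, layer gaps,
self-intersection) with codes rather than raising.

## Problem sizes

Defaults throughout are the study's natural scales: 9 slices × 25
frames, 7–10 subjects per group for the exact tests, 500 proteins × 5
hearts, and a 10⁴-protein simulation for the null calibration of the
R² screen. All tests and the acceptance script complete in well under a
minute on a single core.

## Known limitations

Perimeter strain on raw jittery contours is biased (see above) and the
package does not attempt automatic noise estimation. The remodelling
rule uses volumes (as defined for this pipeline), not diameters as in
some clinical definitions. Cycles of different lengths are not
time-normalised before cross-subject comparison; averaging happens
within study only. The contour dialect carries planar per-slice
coordinates and cannot represent oblique slice geometry.
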