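"""Ventricular volumes, ejection fraction and the remodelling rule.

Computes the phantom's disc-summation volume curve and LVEF, then applies
the published-cohort arithmetic: LVEF from mean end-diastolic/systolic
volumes, allometric body surface area, the indexed end-systolic volume,
and the >= 10% (both EDV and ESV) remodelling classification.
"""

import numpy as np

from lvstrain import (
    PhantomSpec,
    VolumeSeries,
    body_surface_area,
    function_metrics,
    generate_phantom_study,
    volume_series,
)

study, truth = generate_phantom_study(PhantomSpec())
vols = volume_series(study)
metrics = function_metrics(vols, study.weight_kg)
print(f"phantom: EDV {metrics.lvedv_ml:.1f} ml, ESV {metrics.lvesv_ml:.1f} ml, "
      f"LVEF {metrics.lvef_pct:.1f}% (truth {truth.lvef_pct:.1f}%)")

# cohort-mean arithmetic: baseline vs early-chronic volumes
baseline = function_metrics(
    VolumeSeries(np.array([131.0, 56.8]), np.array([0.0, 240.0]), 0, 1), 62.5)
chronic = function_metrics(
    VolumeSeries(np.array([194.6, 100.4]), np.array([0.0, 240.0]), 0, 1), 84.0,
    baseline=baseline)
print(f"baseline means: LVEF {baseline.lvef_pct:.1f}%, "
      f"BSA {baseline.bsa_m2:.3f} m^2 at 62.5 kg, "
      f"LVESVi {baseline.lvesvi_ml_per_m2:.1f} ml/m^2")
print(f"chronic vs baseline: EDV +{(194.6 - 131) / 131:.0%}, ESV +{(100.4 - 56.8) / 56.8:.0%} "
      f"-> remodelling = {chronic.remodelling}")
print(f"BSA is allometric in body mass: 84 kg -> {body_surface_area(84.0):.3f} m^2")
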