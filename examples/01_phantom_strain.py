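"""Regional circumferential strain on the deforming-ventricle phantom.

Generates a noise-free synthetic left ventricle with prescribed regional
peak shortening, runs the perimeter-strain pipeline, and prints recovered
regional/global peaks next to the prescribed truth.  Strains are negative
fractions (shortening); multiply by 100 for percent.
"""

from lvstrain import (
    Layer,
    PhantomSpec,
    Region,
    aggregate_strain,
    generate_phantom_study,
    longitudinal_strain,
    partition_regions,
    peak_value,
    slice_strain_curves,
)

for label, spec in [
    ("healthy baseline", PhantomSpec.healthy()),
    ("apical infarct", PhantomSpec.infarcted_apex()),
]:
    study, truth = generate_phantom_study(spec)
    curves = slice_strain_curves(study, Layer.ENDOCARDIUM, reference_frame=0)
    partition = partition_regions(sorted(curves))
    print(f"\n{label} ({study.n_slices} slices x {study.n_frames} frames)")
    for region in Region:
        peak = peak_value(aggregate_strain(curves, partition, region))
        print(f"  {region.value:5s} CS peak {peak.value:+.4f}"
              f"  (prescribed {truth.region_peak_strain[region.value]:+.4f})")
    gcs = peak_value(aggregate_strain(curves, partition, "global"))
    print(f"  global CS peak {gcs.value:+.4f}  (slice-mean truth {truth.global_peak_strain:+.4f})")
    gls = peak_value(longitudinal_strain(study, Layer.ENDOCARDIUM))
    print(f"  global LS peak {gls.value:+.4f}  (prescribed {truth.long_axis_peak_strain:+.4f})")

print("\nAn apical infarct moves apical CS by ~0.20 but global CS by only ~0.07:")
print("regional strain is the more sensitive marker of a focal injury.")
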