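"""Render a brown-fat phantom and read its lifetime signature off the phasor.

Builds a multilocular brown-adipose phantom, phasor-transforms the
time-resolved NAD(P)H/lipid channel, calibrates against a simulated
reference-fluorophore measurement, and prints the phase lifetime of the
field centroid together with the long-lifetime intensity fraction (LLIF).
"""

import numpy as np

import adipoflim as af

REF_LIFETIME = 5.4  # ns, known lifetime of the calibration standard

spec = af.tissue_spec("BAT", seed=42)
labels = af.generate_phantom_geometry(spec)
stack, fad, truth = af.render_decay_stack(labels, spec, noise=True)

ref = af.generate_reference_measurement(REF_LIFETIME, spec, noise=False)
cal = af.ReferenceCalibration.from_stack(ref, REF_LIFETIME)
field = af.calibrate(af.phasor_transform(stack, bin_factor=5), cal)
llif_map = af.llif(field, spec.tau_short, spec.tau_long)

g, s = af.centroid(field)
tau_phase = af.lifetime_from_phasor(g, s, field.omega)
print(f"phantom: {spec.tissue_type}, {labels.shape[0]}x{labels.shape[1]} px, "
      f"{(labels == 2).mean():.0%} lipid area")
print(f"phasor centroid (g, s) = ({g:.3f}, {s:.3f})")
print(f"centroid phase lifetime = {tau_phase:.2f} ns")
print(f"mean LLIF over lipid     = {np.nanmean(llif_map.values[labels == 2]):.3f}")
print(f"mean LLIF over cytoplasm = {np.nanmean(llif_map.values[labels == 1]):.3f}")
print()
print("The centroid lifetime falls between the 0.3 ns and 6.5 ns trajectory")
print("endpoints because brown fat mixes short-lived cytoplasmic NAD(P)H")
print("with longer-lived lipid-droplet emission; lipid LLIF is close to the")
print(f"value implied by the 5.7 ns droplet lifetime, cytoplasm near its "
      f"true fraction {spec.cyto_llif}.")
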