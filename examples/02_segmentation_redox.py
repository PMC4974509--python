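"""Segment cytoplasm vs lipid droplets and compute per-compartment readouts.

Renders a subcutaneous white-fat phantom, excludes dim nuclei by Otsu
thresholding, classifies lipid droplets by their weak FAD signal and long
lifetime, erodes the compartments to suppress boundary cross-talk, and
prints the recovered optical redox ratio and LLIF means next to the
generating truth.
"""

import adipoflim as af

REF_LIFETIME = 5.4

spec = af.tissue_spec("scWAT", seed=7)
labels = af.generate_phantom_geometry(spec)
stack, fad_raw, truth = af.render_decay_stack(labels, spec, noise=True)

ref = af.generate_reference_measurement(REF_LIFETIME, spec, noise=False)
cal = af.ReferenceCalibration.from_stack(ref, REF_LIFETIME)
field = af.calibrate(af.phasor_transform(stack), cal)
llif_map = af.llif(field, spec.tau_short, spec.tau_long)

nadh = af.normalize_by_power_squared(af.integrate_decay(stack), 1.0)
fad = af.normalize_by_power_squared(fad_raw, 1.0)

foreground = af.otsu_exclude(nadh)
mask = af.classify_compartments(nadh, fad, llif_map, foreground)
print(f"Dice vs ground truth before erosion: "
      f"lipid {af.dice(mask.lipid, labels == 2):.3f}, "
      f"cytoplasm {af.dice(mask.cytoplasm, labels == 1):.3f}")
mask = af.erode_compartments(mask, radius=5)
summary = af.summarize_image(nadh, fad, llif_map, mask)
print(f"pixels: {summary.n_cyto_px} cytoplasm, {summary.n_lipid_px} lipid, "
      f"{summary.n_excluded_px} excluded")
print(f"redox ratio (cytoplasm): {summary.mean_redox_cyto:.3f}  "
      f"[truth {truth.true_redox:.2f}]")
print(f"NAD(P)H LLIF (cytoplasm): {summary.mean_nadh_llif_cyto:.3f}  "
      f"[truth {truth.cyto_llif:.2f}]")
print(f"lipid LLIF: {summary.mean_lipid_llif:.3f}  "
      f"[6.5 ns droplets project to 1.0 on the 0.3-6.5 ns chord]")
print()
print("Redox is FAD/(NAD(P)H+FAD) from mean power-normalized intensities")
print("over segmented cytoplasm; white fat reads low (reduced, lipogenic).")
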