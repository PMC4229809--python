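"""Generate one synthetic NeuN-stained slide and inspect its ground truth.

Builds a 2 x 3 mm two-compartment section (cortex with a dense layer-VI band
over white matter with sparse heterotopic neurons), renders it as an RGB
brightfield image, and prints the exact cell bookkeeping the generator
emits. The printed areal density should sit near Nv (T + h̄)/1000 — the
relationship the Abercrombie correction inverts.
"""

import wmnquant as w

config = w.SlideConfig(seed=7)
slide, truth = w.generate_slide(config, case_id="demo")
slide.to_tiff("demo_slide.tiff")
truth.to_csv("demo_truth.csv")

wm = truth.compartment_cells("white_matter")
print(f"raster: {slide.rgb.shape[1]} x {slide.rgb.shape[0]} px at {slide.mpp} um/px")
print(f"section thickness T = {truth.thickness_T:.1f} um")
print(f"white-matter area   = {truth.wm_area_mm2:.2f} mm^2")
print(f"true WMN density    = {truth.true_Nv_wm:.0f} cells/mm^3")
print(f"WM profiles in slab = {len(wm)} ({truth.true_Na_wm:.1f} /mm^2)")
expected_na = truth.true_Nv_wm * (truth.thickness_T + wm["diameter_um"].mean()) / 1000.0
print(f"expected profiles   = {expected_na:.1f} /mm^2  (Nv (T + h)/1000)")
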