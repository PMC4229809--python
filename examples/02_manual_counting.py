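"""Whole-slide counting with a manual ROI and the 0.5 mm exclusion rule.

Outlines the white matter, erodes it 0.5 mm away from the cortical margin
(so no layer-VI neuron can contaminate the count), detects NeuN-positive
profiles by stain separation and an optical-density threshold, and reports
the Abercrombie-corrected density next to the generating truth.
"""

import wmnquant as w
from wmnquant.pipeline import _truth_cortex_mask
from wmnquant.stereology import wm_truth_roi

config = w.SlideConfig(seed=5)
slide, truth = w.generate_slide(config)

roi = wm_truth_roi(truth, slide.shape)
cortex_mask = _truth_cortex_mask(truth, slide.shape)
roi = w.exclude_boundary_margin(roi, cortex_mask, margin_mm=0.5)

dets = w.detect_cells(slide, roi, w.DetectionParams())
result = w.density_from_detections(dets, roi, slide.thickness_T, method="wsa_manual")

print(f"counting area (0.5 mm margin applied): {result.area_mm2:.2f} mm^2")
print(f"profiles detected: {result.n_profiles}  (Na = {result.Na:.1f} /mm^2)")
print(f"mean profile diameter h = {result.h_um:.2f} um; T = {result.T_um:.1f} um")
print(f"Abercrombie factor T/(T+h) = {result.abercrombie_factor:.3f}")
print(f"corrected density Nv = {result.Nv:.0f} cells/mm^3 (truth {truth.true_Nv_wm:.0f})")
small, medium, large = result.size_fractions
print(f"size classes: small {small:.0%}, medium {medium:.0%}, large {large:.0%}")
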