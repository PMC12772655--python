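"""Simulate one low-dose acquisition and read it with the ROI pipeline.

Generates a 1.6 mGy energy-integrating scan of the four-lesion phantom,
places the deterministic 8 mm ROI scheme (lesion + adjacent parenchyma per
lesion + water ring, on three central slices) and reports noise and
contrast-to-noise ratios.
"""

import numpy as np

import ctphantom as cp

phantom = cp.canonical_phantoms()[0]
truth, mask = cp.rasterize_phantom(phantom, cp.DEFAULT_MATERIALS, "EIDCT", seed=2)
model = cp.default_noise_models()["EIDCT"]
scan = cp.simulate_scan(truth, mask, model, dose=1.6, seed=42)

rois = cp.place_rois(mask, phantom)
measurements = [cp.measure_roi(scan, r) for r in rois]

noise = [m.sd for m in measurements if m.roi.material == "lung_parenchyma"]
print(f"parenchyma noise at 1.6 mGy: {np.mean(noise):.1f} +/- "
      f"{np.std(noise, ddof=1):.1f} HU over {len(noise)} ROIs "
      "(calibrated to 134.4 HU)")

by_key = {(m.roi.region_name, m.roi.lesion_id, m.roi.slice_index): m
          for m in measurements}
print("\nCNR per lesion (first central slice):")
for lesion in phantom.lesions:
    z = min(m.roi.slice_index for m in measurements
            if m.roi.region_name == lesion.lesion_id)
    cnr = cp.compute_cnr(by_key[(lesion.lesion_id, lesion.lesion_id, z)],
                         by_key[("lung_parenchyma", lesion.lesion_id, z)])
    print(f"  {lesion.lesion_id:20s} |CNR| = {abs(cnr):5.2f}")
print("Solid lesions stand far above the parenchyma background; ground-glass "
      "contrast is an order of magnitude smaller, which is why low-dose "
      "noise matters clinically.")
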