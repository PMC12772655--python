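"""Extract the 107-feature radiomics vector for one lesion.

18 first-order + 14 shape + 75 texture features (GLCM/GLRLM/GLSZM/GLDM/
NGTDM) on fixed-bin-width (25 HU) discretized intensities.
"""

import ctphantom as cp

phantom = cp.canonical_phantoms()[0]
truth, mask = cp.rasterize_phantom(phantom, cp.DEFAULT_MATERIALS, "PCCT", seed=3)
scan = cp.simulate_scan(truth, mask, cp.default_noise_models()["PCCT"],
                        dose=9.8, seed=7)

fv = cp.extract_all(scan, mask, label="large_solid")
print(f"extracted {len(fv)} features; per family: {fv.group_counts()}")
for name in ("firstorder_Mean", "firstorder_Entropy", "shape_MeshVolume",
             "shape_Sphericity", "shape_Maximum3DDiameter", "glcm_Contrast",
             "glrlm_RunEntropy", "glszm_ZonePercentage", "ngtdm_Coarseness"):
    print(f"  {name:28s} {fv.values[name]:12.4f}")
print("Mean HU sits near the lesion's -94.8 HU specification; the 43.1 mm "
      "maximum 3D diameter and near-ellipsoidal sphericity describe the "
      "rendered geometry; texture features quantify the noise-plus-texture "
      "pattern the scanner condition imprinted.")
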