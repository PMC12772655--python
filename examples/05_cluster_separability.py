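"""Lesion-type clustering of radiomics features in PCA space.

Runs a reduced study (one dose, one repetition, both scanners), embeds the
107-feature vectors in the principal components retaining 95% of variance,
and reports within-cluster distance (feature consistency) and separability
(lesion-type discrimination) per scanner.
"""

import ctphantom as cp

config = cp.StudyConfig(doses=(9.8,), repetitions=1)
report = cp.run_study(config, with_radiomics=True, with_stats=False)

cr = report.cluster_report
print(f"{cr.n_components} principal components retain 95% of variance")
for scanner, by_type in cr.within.items():
    for lesion_type, (mean, sd) in by_type.items():
        print(f"  within-cluster {scanner:6s} {lesion_type:13s} "
              f"{mean:5.2f} +/- {sd:4.2f}")
for scanner, sep in cr.separability.items():
    print(f"  separability   {scanner:6s} {sep:5.2f}")
print("Separability > 1 means lesion-type centroids are farther apart than "
      "points scatter within a type: the embedding distinguishes solid, "
      "part-solid and ground-glass morphologies on either scanner.")
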