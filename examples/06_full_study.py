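"""The complete dose-matched two-scanner study, end to end.

180 lesion-measurement instances (6 lesions x 5 doses x 2 scanners x 3
repetitions): generation, ROI metrics, radiomics, clustering, statistics.
Takes a few minutes on one CPU; pass write_volumes=True (or use the
``ctphantom all`` CLI) to also keep the NIfTI volumes.
"""

import ctphantom as cp

report = cp.run_study(cp.StudyConfig(), with_radiomics=True, with_stats=True)
print(report.summary_text())
print()
sig = report.stats[report.stats["significant"]]
print(f"{len(sig)} of {len(report.stats)} comparisons significant at the 5% "
      "level, including the per-dose noise advantage of the photon-counting "
      "system at the lower doses.")
report.save("study_out")
print("tables written to study_out/")
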