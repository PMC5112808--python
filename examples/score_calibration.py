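"""MICCAI-style score calibration of segmentation error measures.

Each error eps is mapped to  S = max(100 - 25 eps / eps_ref, 0)  where the
reference values (VOE 6.4 %, RVD 4.7 %, ASD 1.0 mm, RMSE 1.8 mm, MSD 19 mm)
are the measured performance of an independent human rater, who therefore
scores exactly 75.
"""

from flrw import MICCAI_STANDARDS, aggregate_cases, miccai_score

per_case = [
    {"voe": 8.80, "rvd": 6.51, "asd": 1.30, "rmse": 1.98, "msd": 17.60},
    {"voe": 9.18, "rvd": 5.21, "asd": 1.57, "rmse": 2.03, "msd": 10.95},
    {"voe": 7.83, "rvd": 5.89, "asd": 1.14, "rmse": 2.12, "msd": 16.12},
    {"voe": 7.63, "rvd": 5.52, "asd": 0.85, "rmse": 1.87, "msd": 31.30},
]

averaged = aggregate_cases(per_case)
print("averaged errors :", averaged)

report = miccai_score(averaged)
for m in ("voe", "rvd", "asd", "rmse", "msd"):
    print(f"  {m:4s}: eps = {report.errors[m]:6.2f}  eps_ref = {report.standards[m]:5.2f}"
          f"  -> score {report.scores[m]}")
print("total score     :", report.total)

print()
print("human reference :", miccai_score(dict(MICCAI_STANDARDS)).total)
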