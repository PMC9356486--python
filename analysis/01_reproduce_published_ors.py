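"""Reproduce the cohort's unadjusted odds ratios and prevalences from the
published hip counts.

The hip-level counts (cases among 142 cam / 546 non-cam hips for the OA
phenotypes; 143 cam / 551 non-cam hips for high bone mass) fully determine
the unadjusted (Model 1) estimates: an independence-GEE point estimate on a
binary exposure coincides with the crude 2x2 odds ratio regardless of how
hips are paired into individuals.  Writes results/unadjusted_ors.csv.
"""

import pandas as pd

from camhip.stats import TwoByTwo, chi_squared, crude_or

TABLES = {
    "cam -> rHOA (Croft >= 3)": TwoByTwo(57, 85, 79, 467),
    "cam -> JSN": TwoByTwo(60, 82, 90, 456),
    "cam -> sclerosis": TwoByTwo(15, 127, 19, 527),
    "cam -> osteophyte": TwoByTwo(119, 23, 345, 201),
    "HBM -> cam": TwoByTwo(81, 62, 379, 172),
}

rows = []
for name, t in TABLES.items():
    res = crude_or(t)
    chi2, chi2_p = chi_squared(t)
    rows.append(
        {
            "analysis": name,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "or": round(res.or_, 2),
            "ci_low": round(res.ci_low, 2),
            "ci_high": round(res.ci_high, 2),
            "p": f"{res.p:.3g}",
            "chi2": round(chi2, 2),
            "chi2_p": f"{chi2_p:.3g}",
        }
    )
table = pd.DataFrame(rows)
table.to_csv("results/unadjusted_ors.csv", index=False)
print(table.to_string(index=False))
print()
print(f"cam prevalence: 143/694 = {143 / 694 * 100:.1f}%")
t = TABLES["cam -> rHOA (Croft >= 3)"]
print(f"rHOA prevalence: {(t.a + t.c)}/{t.a + t.b + t.c + t.d} = "
      f"{(t.a + t.c) / (t.a + t.b + t.c + t.d) * 100:.1f}%")
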