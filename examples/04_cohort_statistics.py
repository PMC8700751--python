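"""Cohort statistics at the published sizes (40 malignant / 29 inflammatory).

Draws a calibrated cohort of the six flow parameters, runs the
normality-gated group comparisons and ROC analyses, and compares the
discriminative ability of tissue perfusion intensity (TPI) against
single-vessel flow velocity (FV) with DeLong's paired test.
"""

from dopplerquant import build_report, compare_auc, draw_cohort_params

df = draw_cohort_params(40, 29, seed=1)
table1, table2, _ = build_report(df)

print("group comparisons (mean±SD for t-tested, median (IQR) otherwise):")
print(table1.to_string(index=False))
print("\nROC discrimination (nadir = Youden-optimal cut-off):")
print(table2.round(3).to_string(index=False))

p = compare_auc(df["tpi"], df["fv"], df["label"].to_numpy())
print(f"\nDeLong paired comparison, TPI vs FV AUC: p = {p:.4f}")
print("a small p means tissue perfusion discriminates malignant from "
      "inflammatory lesions better than single-vessel velocity on the same cases")
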