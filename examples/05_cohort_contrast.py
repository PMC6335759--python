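"""Density versus sociology at cohort level.

Simulates an 11-vs-8 patient cohort (5 ROIs each) whose groups differ only
in how immune cells are spatially mixed into the tumor — immune counts,
hence densities, are matched.  The rank-sum test on the tumor-immune
neighbor frequency then detects the group difference that the density
metric cannot, and the per-ROI benefit score summarizes the gain per
patient.
"""

from cellsoc import compare_groups, generate_cohort, roi_benefit_score

table = generate_cohort(seed=0)
print(f"cohort: {table['patient_id'].nunique()} patients, {len(table)} ROIs")

p_den = compare_groups(table, value_col="density")
p_soc = compare_groups(table, value_col="sociology")
print(f"Mann-Whitney U, immune density : p = {p_den:.3g}")
print(f"Mann-Whitney U, tumor-immune f : p = {p_soc:.3g}")

scores = roi_benefit_score(table)
print(scores["verdict"].value_counts().to_string())
# Density p is non-significant (the groups' immune counts are matched by
# construction); the sociology metric separates them by orders of
# magnitude, and most patients are classified better ("improved") when the
# neighbor-frequency metric is added.
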