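"""TV-time exposure groups and covariate-adjusted adiposity change.

Subjects are classified by their TV trajectory (constantly low / moderate
/ high, increased, decreased); the 10-year waist change is compared across
groups with adjustment for sex, age, activity, energy intake, smoking and
baseline waist, using Tukey–Kramer corrected pairwise contrasts, plus
obesity (BMI > 30) risk ratios against the constantly-low group.
"""
from paircause import (CohortConfig, assign_tv_groups, change_table,
                       generate_cohort, obesity_risk_ratio)

ds = generate_cohort(CohortConfig(n_subjects=4000, seed=3,
                                  effect_tv_on_waist_change=1.8,
                                  change_sd_waist=(5.0, 7.5),
                                  effect_tv_on_bmi_change=0.9,
                                  change_sd_bmi=(2.0, 3.0)))
groups = assign_tv_groups(ds)
print(groups.value_counts().to_string())

tab = change_table(ds, groups, outcome="waist", horizon="10y")
print("\nadjusted 10y waist change (cm):")
print(tab.adjusted.to_string(float_format=lambda v: f"{v:.2f}"))
sig = tab.contrasts[tab.contrasts.significant]
print(f"\n{len(sig)} significant Tukey–Kramer contrasts, e.g.:")
print(sig.head(3).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

rr = obesity_risk_ratio(ds, groups)
print("\nobesity risk ratios vs constantly_low:")
print(rr.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# With a strong TV effect the high-TV groups change about twice as much
# as the constantly-low group and carry an elevated obesity risk.
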