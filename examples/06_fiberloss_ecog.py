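"""Classify T2/FLAIR lesions, compute total fiber loss, and model ECOG.

Total fiber loss = (1 - relative FD) x segment volume (mm^3) converts a
density deficit into an absolute amount of lost fiber; logistic regression
asks which lesion type's loss predicts an impaired performance status.
"""

from lesionfd import RunConfig, classify_t2flair, ecog_regression, fiberloss_frame, run_pipeline

print(classify_t2flair(ce_volume_mL=15.0, fet_volume_mL=12.0, months_since_rt=20.0))
print(classify_t2flair(ce_volume_mL=0.05, fet_volume_mL=0.0, months_since_rt=8.0))

res = run_pipeline(RunConfig(n_patients=30, n_controls=30).with_seed(6))
df = fiberloss_frame(res.patient_records)
print(f"\nimpaired (ECOG >= 1): {df['impaired'].mean():.0%} of {len(df)} patients")
for r in ecog_regression(df, mode="univariate"):
    print(f"univariate {r.predictor}: OR/unit {r.odds_ratio:.4f}, p={r.p_value:.3f}")
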