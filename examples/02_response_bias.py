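"""Estimate and correct the response bias; descriptive Kappa statistics.

Simulates nine subjects with a built-in overproduction bias (0.137 s at
0.8 s, 0.045 s at 1.2 s), recovers it from the zero-separation baseline,
corrects the trials, and prints the Kappa bias (excess production per
separation) and per-condition variance.
"""

import kappafit as kf

gen = kf.GeneratorSpec(
    model="classical",
    params=[kf.published.classical_params(s) for s in kf.published.SUBJECTS],
    bias_by_condition={0.8: 0.137, 1.2: 0.045},
)
trials = kf.generate_exp1(kf.DesignSpec(n_subjects=9, seed=2), gen)

bias = kf.response_bias_table(trials)
group = bias.groupby("sample_interval_s")["bias_r_s"].agg(["mean", "sem"])
print("group response bias (s):")
print(group.round(3).to_string())
# Bias is mean baseline production minus the sample interval; the 0.8-s
# value should recover the injected 0.137 s within sampling error.

corrected = kf.correct_bias(trials, bias)
print("\nKappa bias after correction, subject S1, 0.8-s condition (s):")
print(kf.compute_bias_k(corrected[corrected.subject_id == "S1"], 0.8).round(3).to_string())
# BIAS_k rises with separation: that is the Kappa effect itself.

v08 = [kf.compute_var(g, 0.8) for _, g in corrected.groupby("subject_id")]
v12 = [kf.compute_var(g, 1.2) for _, g in corrected.groupby("subject_id")]
t = kf.paired_t(v08, v12)
print(f"\nmean VAR 0.8 s: {sum(v08)/9:.3f} s², 1.2 s: {sum(v12)/9:.3f} s², "
      f"paired t({t['df']}) = {t['t']:.2f}")
# Scalar variability: longer intervals are reproduced with larger variance.
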