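"""Simulate two-flash time-reproduction sessions.

Builds the default separation experiment (2 sample intervals × 17 flash
separations × 40 trials per subject) and the same-location control
(2 intervals × 3 locations × 40 trials), driven by the published
per-subject constant-speed parameters, and prints the cell structure.
"""

import kappafit as kf

design = kf.DesignSpec(n_subjects=2, seed=1)
gen = kf.population_spec_from_tables("classical")

exp1 = kf.generate_exp1(design, gen)
exp2 = kf.generate_exp2(design, gen)

print(f"separation experiment: {len(exp1)} trials "
      f"({len(exp1) // design.n_subjects} per subject)")
print(f"same-location control: {len(exp2)} trials "
      f"({len(exp2) // design.n_subjects} per subject)")
print()
print("per-cell counts (subject S1, 0.8-s condition):")
s1 = exp1[(exp1.subject_id == "S1") & (exp1.sample_interval_s == 0.8)]
print(s1.groupby("distance_deg").size().to_string())
print()
print("first five trials:")
print(exp1.head().to_string(index=False))
# Each (interval, separation) cell holds exactly 40 trials; production
# times scatter around the model's time estimate with SD = w_p * t_e.
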