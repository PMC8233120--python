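"""Edge-wise age correction against the control population.

Each edge of each subject is re-expressed as the residual from the
control age fit (res) and as that residual divided by the fit RMSE
(corr) — the deviation in SD units from an age-matched control.
"""

import numpy as np

from netprog import SimulationConfig, normalize_cohort, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(seed=2))
corrected = normalize_cohort(cohort, modalities=("FC",))

model = corrected.models["FC"]
iu = np.triu_indices(cohort.atlas.n_regions, 1)
r = np.corrcoef(model.slope[iu], truth.fc_age_slopes[iu])[0, 1]
print(f"fitted vs planted age slopes across {len(iu[0])} edges: r = {r:.3f}")

patient = cohort.patients()[0]
corr = corrected.corr[(patient.subject_id, "FC")].matrix[iu]
print(f"{patient.subject_id} (age {patient.age:.0f}, duration "
      f"{patient.duration:.0f} y): FC_corr mean = {corr.mean():+.3f}, "
      f"SD = {corr.std():.3f}")
print("A corr value of +2 means that edge is two control-SDs above the "
      "level expected at the subject's age.")
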