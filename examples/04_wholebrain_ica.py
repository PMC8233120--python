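"""Whole-brain hybrid FC/SC ICA and the duration-of-disease component.

Patient FC_corr and SC_corr connectomes (ipsi/contra frame) are
concatenated edge-wise, decomposed with repeated FastICA after a
90%-variance PCA, merged across runs, and screened for components whose
patient weights track duration of disease. The selected component is
projected to a per-region weighted degree and compared with the
healthy-brain distance models.
"""

import numpy as np

from netprog import (ICAConfig, SimulationConfig, analyze_wholebrain,
                     build_topology, normalize_cohort, plant_ica_component,
                     simulate_cohort)

cohort, truth = simulate_cohort(SimulationConfig(seed=4,
                                                 effect_profile=(0.0,) * 5))
cohort, truth = plant_ica_component(cohort, loading_vs_duration_rho=0.7,
                                    amplitude=4.0, seed=4,
                                    ground_truth=truth,
                                    pattern_mode="distance_decay",
                                    pattern_sparsity=0.3)
corrected = normalize_cohort(cohort)
models = {k: build_topology(cohort, k) for k in ("LEN", "SC", "FC", "RSN")}
result = analyze_wholebrain(cohort, corrected, ICAConfig(n_runs=10, seed=4),
                            models)

m = result.merged
print(f"{result.runs.n_pca_components} PCA components, "
      f"{len(m.components)} merged ICA components")
if m.selected is None:
    print("no component related to duration of disease")
else:
    i = m.selected
    print(f"selected component: Spearman rho = {m.duration_rho[i]:.2f} "
          f"(p = {m.duration_p[i]:.1e}), identification frequency "
          f"{m.frequencies[i]:.0%}")
    for block in ("FC", "SC"):
        c = result.model_correlations[block]["LEN"]
        print(f"{block} degree vs streamline-length model: r = {c.r:+.2f}, "
              f"p = {c.p:.1e}")
    print("A negative r means the regions whose connectivity changes most "
          "with duration are those closest to the anterior hippocampus.")
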