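"""Relapse-free survival stratified by MM status.

Generates a cohort whose relapse hazard is 1.72-fold higher for MM
tumours, then estimates the Kaplan-Meier curves, the log-rank test and a
multivariate Cox model. The Cox hazard ratio for MM presence should land
near the generating value with its 95% CI.
"""

import numpy as np
import pandas as pd

from multimut import (
    SyntheticCohortConfig,
    cox_fit,
    km_estimate,
    logrank_test,
    simulate_cohort,
)

cohort = simulate_cohort(SyntheticCohortConfig(n_samples=400, seed=9))
clinical = cohort.clinical
mm = np.array(
    [cohort.ground_truth.mm_status[s] == "MM_tumor" for s in clinical["sample_id"]]
)

for label, mask in (("MM", mm), ("SM", ~mm)):
    fit = km_estimate(clinical["rfs_months"][mask], clinical["rfs_event"][mask])
    med = f"{fit.median_time:.1f} months" if fit.median_time else "not reached"
    print(f"{label}: n={fit.n_subjects}, events={fit.n_events}, median RFS {med}")

statistic, p = logrank_test(
    [
        (clinical["rfs_months"][mm], clinical["rfs_event"][mm]),
        (clinical["rfs_months"][~mm], clinical["rfs_event"][~mm]),
    ]
)
print(f"log-rank: chi2={statistic:.2f}, p={p:.4f}")

design = pd.DataFrame(
    {
        "mm_present": mm.astype(float),
        "microvascular_invasion": clinical["microvascular_invasion"].astype(float),
        "age_ge_70": (clinical["age_years"] >= 70).astype(float),
    }
)
fit = cox_fit(design, clinical["rfs_months"], clinical["rfs_event"])
coef = fit["mm_present"]
print(
    f"Cox MM hazard ratio {coef.hazard_ratio:.2f} "
    f"(95% CI {coef.ci_low:.2f}-{coef.ci_high:.2f}, p={coef.p_value:.3f}); "
    f"generating value 1.72"
)
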