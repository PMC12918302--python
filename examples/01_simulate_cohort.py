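"""Generate a synthetic cohort and inspect its calibrated marginals.

The generator draws proxy features X1, a true phenotype Strue driven by X1,
a degraded continuous proxy score S*, structured covariates X2, and a binary
outcome Y plus censored event time T driven by (Strue, X2).
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from releap import CohortConfig, duhs_like_fixture, generate_cohort

cohort = generate_cohort(CohortConfig(n_patients=20_000, outcome_prevalence=0.10, seed=1))
print(f"patients:            {cohort.n}")
print(f"outcome prevalence:  {cohort.y.mean():.3f}   (target 0.100)")
print(f"phenotype prevalence:{cohort.s_true.mean():.3f}   (target 0.300)")
print(f"proxy AUC vs Strue:  {roc_auc_score(cohort.s_true, cohort.s_proxy):.3f}   (<1: degraded by design)")
print(f"censored fraction:   {1 - cohort.event_flag.mean():.3f}   (target 0.700)")

# a fixture calibrated to published large-health-system marginals
fx = duhs_like_fixture(seed=1, n=50_000)
print("\nfixture marginals (targets 0.78% / 9.0% / 52.7%):")
print(f"  outcome:        {100 * fx.y.mean():.2f}%")
print(f"  code coverage:  {100 * np.mean(fx.x1.sum(axis=1) > 0):.2f}%")
print(f"  never-smoker:   {100 * np.mean(fx.s_true == 0):.2f}%")
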