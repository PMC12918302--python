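"""Score an unlabeled pool with the three querying strategies and combine
them under mixture weights.

Uncertainty favors patients the downstream model finds ambiguous, diversity
favors patients far from the labeled set, and query-by-committee favors
patients a perturbed model ensemble disagrees about.  Each score is min-max
normalized so a simplex weight vector can mix them into one ranking.
"""

import numpy as np

from releap import (
    CohortConfig,
    QbcConfig,
    StrategyScores,
    composite_rank,
    diversity_scores,
    fit_classifier,
    generate_cohort,
    qbc_scores,
    uncertainty_scores,
    zscore_standardize,
)

cohort = generate_cohort(CohortConfig(n_patients=2_000, seed=3))
labeled = np.arange(200)  # pretend the first 200 are reference-labeled
unlabeled = np.arange(200, 2_000)

clf = fit_classifier(cohort.s_true[labeled], cohort.x2[labeled], cohort.y[labeled])
probs = clf.predict_proba(cohort.s_proxy[unlabeled], cohort.x2[unlabeled])

features = zscore_standardize(np.column_stack([cohort.x1, cohort.x2]), labeled)
scores = StrategyScores.from_raw(
    uncertainty_scores(probs),
    diversity_scores(features[unlabeled], features[labeled]),
    qbc_scores(features[labeled], cohort.s_true[labeled], features[unlabeled], QbcConfig(seed=3)),
)

for name, raw in [
    ("uncertainty", scores.raw_uncertainty),
    ("diversity", scores.raw_diversity),
    ("qbc", scores.raw_qbc),
]:
    print(f"{name:12s} raw range [{raw.min():.4f}, {raw.max():.4f}]")

top = composite_rank(scores, weights=(0.5, 0.25, 0.25), k=5, seed=0)
print("\ntop-5 composite picks (positions in the unlabeled pool):", top.tolist())
print("their composite emphasis is ambiguity-heavy: entropy of their outcome probs =",
      np.round(scores.raw_uncertainty[top], 3).tolist())
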