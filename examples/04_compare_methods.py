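"""Benchmark all comparator arms with paired replications and 95% CIs.

Within a replication every arm shares the same stratified split and
balanced seed set, so differences reflect querying behaviour alone.
A compact configuration keeps this example fast; the desk-scale preset
(releap.DESK_PRESET) is the default study size.
"""

import pandas as pd

from releap import CohortConfig, ExperimentConfig, aggregate, run_replications

cfg = ExperimentConfig(
    cohort=CohortConfig(n_patients=4_000, outcome_prevalence=0.10),
    methods=("proxy_only", "oracle", "random", "uncertainty", "releap"),
    n_replications=3,
    budget_total=800,
    batch_size_k=100,
    seed_set_size=100,
    master_seed=9,
)
results = run_replications(cfg)
summary = aggregate(results)

final_auc = (
    summary[summary.metric == "auc"]
    .sort_values("iteration")
    .groupby("method")
    .last()[["mean", "ci_low", "ci_high"]]
    .round(4)
)
print("final validation AUC (mean and 95% CI over 3 replications):")
print(final_auc.to_string())
print("\nquerying arms should land between proxy_only (noisy floor) and oracle (ceiling)")
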