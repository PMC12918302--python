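"""Comparator arms, replications, aggregation, subgroups, CLI."""

import numpy as np
import pandas as pd
import pytest

from releap.cohort import CohortConfig, generate_cohort
from releap.experiment import (
    ExperimentConfig,
    ReplicationResult,
    aggregate,
    budget_percentage,
    metrics_table,
    run_method,
    run_replications,
    subgroup_evaluate,
)
from releap.models import MetricsReport, evaluate_classification


@pytest.fixture(scope="module")
def tiny_cfg():
    return ExperimentConfig(
        cohort=CohortConfig(n_patients=1_200, seed=0),
        methods=("proxy_only", "oracle", "random", "uncertainty"),
        n_replications=2,
        budget_total=150,
        batch_size_k=50,
        seed_set_size=50,
        master_seed=5,
    )


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(CohortConfig(n_patients=1_200, seed=17))


class TestRunMethod:
    def test_proxy_only_consumes_zero_labels(self, tiny_cfg, tiny_cohort):
        res = run_method("proxy_only", tiny_cohort, tiny_cfg)
        assert res.query_positions is None
        assert len(res.reports) == 1

    def test_oracle_invariant_to_budget(self, tiny_cfg, tiny_cohort):
        from dataclasses import replace

        a = run_method("oracle", tiny_cohort, tiny_cfg)
        b = run_method("oracle", tiny_cohort, replace(tiny_cfg, budget_total=600))
        assert a.final.auc == b.final.auc

    def test_querying_arm_spends_full_budget(self, tiny_cfg, tiny_cohort):
        res = run_method("uncertainty", tiny_cohort, tiny_cfg)
        n_labeled = len(res.query_positions)
        assert n_labeled == tiny_cfg.seed_set_size + tiny_cfg.budget_total

    def test_unknown_method_rejected(self, tiny_cfg, tiny_cohort):
        with pytest.raises(ValueError):
            run_method("mystery", tiny_cohort, tiny_cfg)

    def test_aphrodite_arm_errors_with_explanation(self):
        with pytest.raises(ValueError, match="aphrodite"):
            ExperimentConfig(methods=("aphrodite",))

    def test_fixed_arm_equals_frozen_policy_episode(self, tiny_cfg, tiny_cohort):
        """The uncertainty arm and the adaptive runner pinned at (1,0,0)
        must produce the identical query sequence and metrics (the
        equivalence oracle for one-hot mixtures)."""
        from releap.agent import CohortSplit, EpisodeConfig, run_episode
        from releap.experiment import _rep_seed
        from releap.labels import SplitSpec, init_seed_set, stratified_split
        from releap.ppo import FrozenPolicy
        from dataclasses import replace

        res = run_method("uncertainty", tiny_cohort, tiny_cfg)
        rep_seed = _rep_seed(tiny_cfg.master_seed, 0)
        tr, va = stratified_split(tiny_cohort, SplitSpec(seed=rep_seed))
        split = CohortSplit.from_cohort(tiny_cohort, tr, va)
        st = init_seed_set(
            split.s_true, split.s_proxy, tiny_cfg.seed_set_size,
            tiny_cfg.budget_total, tiny_cfg.batch_size_k, seed=rep_seed,
        )
        _, reports, _ = run_episode(
            split, st, FrozenPolicy((1, 0, 0), compute_all_scores=True),
            EpisodeConfig(seed=rep_seed),
        )
        np.testing.assert_array_equal(res.query_positions, np.flatnonzero(st.labeled_mask))
        assert res.final.auc == reports[-1].auc


class TestReplications:
    def test_replication_count_and_reproducibility(self, tiny_cfg):
        a = run_replications(tiny_cfg)
        b = run_replications(tiny_cfg)
        assert len(a) == len(tiny_cfg.methods) * tiny_cfg.n_replications
        pd.testing.assert_frame_equal(metrics_table(a), metrics_table(b))

    def test_different_replications_query_differently(self, tiny_cfg, tiny_cohort):
        a = run_method("random", tiny_cohort, tiny_cfg, replication=0)
        b = run_method("random", tiny_cohort, tiny_cfg, replication=1)
        assert not np.array_equal(a.query_positions, b.query_positions)


def _fake_result(values, method="m"):
    return [
        ReplicationResult(method, i, [MetricsReport(auc=v, f1=0.0, tpr_at_fpr10=0.0,
                                                    ppv_at_fpr10=0.0, prob_mse=0.0)])
        for i, v in enumerate(values)
    ]


class TestAggregate:
    def test_normal_approximation_ci_closed_form(self):
        out = aggregate(_fake_result([0.70, 0.72, 0.74]))
        row = out[out.metric == "auc"].iloc[0]
        assert row["mean"] == pytest.approx(0.72)
        assert row["ci_low"] == pytest.approx(0.72 - 1.96 * 0.02 / np.sqrt(3))
        assert row["ci_high"] == pytest.approx(0.72 + 1.96 * 0.02 / np.sqrt(3))

    def test_identical_replicates_zero_width(self):
        out = aggregate(_fake_result([0.7, 0.7, 0.7]))
        row = out[out.metric == "auc"].iloc[0]
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-12)
        assert row["mean"] == pytest.approx(0.7)

    def test_order_invariance(self):
        a = aggregate(_fake_result([0.70, 0.72, 0.74]))
        shuffled = _fake_result([0.74, 0.70, 0.72])
        b = aggregate(shuffled)
        pd.testing.assert_frame_equal(
            a.drop(columns="n_replications"), b.drop(columns="n_replications")
        )

    def test_single_replication_ci_absent(self):
        out = aggregate(_fake_result([0.7]))
        row = out[out.metric == "auc"].iloc[0]
        assert np.isnan(row["ci_low"]) and np.isnan(row["ci_high"])


class TestSubgroups:
    def _result(self, probs, y):
        n = len(y)
        return ReplicationResult(
            "m", 0, [evaluate_classification(probs, y)],
            final_val_probs=probs, val_y=y, val_indices=np.arange(n),
        )

    def test_identical_groups_identical_metrics(self):
        y = np.tile([0, 1, 0, 0], 50)
        probs = y * 0.6 + 0.2 + np.tile([0.0, 0.01, 0.02, 0.03], 50)
        groups = np.repeat([0, 1], 100)  # two copies of the same joint
        out = subgroup_evaluate([self._result(probs, y)], groups)
        assert len(out) == 2
        assert out.iloc[0].auc == out.iloc[1].auc
        assert out.iloc[0].prob_mse == out.iloc[1].prob_mse

    def test_whole_cohort_group_recovers_overall_metrics(self, rng):
        y = (rng.random(300) < 0.3).astype(int)
        probs = np.clip(y * 0.5 + rng.random(300) * 0.5, 0, 1)
        res = self._result(probs, y)
        out = subgroup_evaluate([res], np.zeros(300, dtype=int))
        assert out.iloc[0].auc == res.final.auc

    def test_noisier_group_scores_lower_auc(self, rng):
        n = 4_000
        groups = (rng.random(n) < 0.5).astype(int)
        y = (rng.random(n) < 0.3).astype(int)
        noise = np.where(groups == 1, 0.9, 0.2)  # injected noise gap
        probs = np.clip(y + noise * rng.standard_normal(n), 0, 1)
        out = subgroup_evaluate([self._result(probs, y)], groups)
        auc0 = out[out.group == 0].auc.iloc[0]
        auc1 = out[out.group == 1].auc.iloc[0]
        assert auc0 > auc1

    def test_single_class_group_skipped_with_warning(self, rng):
        y = np.array([0, 1] * 20 + [0] * 10)
        probs = rng.random(50)
        groups = np.array([0] * 40 + [1] * 10)  # group 1 has no positives
        with pytest.warns(UserWarning, match="single outcome class"):
            out = subgroup_evaluate([self._result(probs, y)], groups)
        assert set(out.group) == {0}


class TestBudgetPercentage:
    def test_direct_ratio(self):
        assert budget_percentage(50, 200) == 25.0

    def test_bad_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            budget_percentage(10, 0)


class TestCli:
    def test_simulate_writes_cohort_file(self, tmp_path):
        from releap.cli import main

        out = tmp_path / "cohort.csv"
        rc = main(["simulate", "--preset", "rare", "--seed", "1", "--n", "500", "--out", str(out)])
        assert rc == 0
        df = pd.read_csv(out)
        assert len(df) == 500
        assert {"patient_id", "s_proxy", "s_true", "y", "t_event", "event_flag"} <= set(df.columns)

    def test_compare_and_report_round_trip(self, tmp_path):
        from releap.cli import main
        import yaml

        cfg = {
            "cohort": {"n_patients": 600, "seed": 2},
            "methods": ["proxy_only", "oracle", "random"],
            "n_replications": 2,
            "budget_total": 60,
            "batch_size_k": 30,
            "seed_set_size": 20,
            "master_seed": 3,
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "out"
        assert main(["compare", "--config", str(cfg_path), "--out", str(out)]) == 0
        metric_files = list(out.glob("metrics_*.csv"))
        assert len(metric_files) == 6  # 3 methods x 2 replications
        assert (out / "summary.csv").exists()
        assert (out / "resolved_config.json").exists()

        rep = tmp_path / "report"
        assert main(["report", "--results", str(out), "--out", str(rep)]) == 0
        summary = pd.read_csv(rep / "summary.csv")
        assert set(summary.method) == {"proxy_only", "oracle", "random"}

    def test_bad_config_nonzero_exit(self, tmp_path):
        from releap.cli import main

        bad = tmp_path / "bad.yaml"
        bad.write_text("methods: [mystery]")
        assert main(["compare", "--config", str(bad), "--out", str(tmp_path / "o")]) == 1
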