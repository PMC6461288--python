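"""Calling protocols: partitioning, z-score calls, confusion evaluation."""

import dataclasses
import statistics

import numpy as np
import pytest

from sizenipt import (
    AneuploidyCall,
    CohortSimConfig,
    FetalFraction,
    ProtocolConfig,
    SizeRange,
    compute_statistic,
    evaluate_calls,
    call_sample,
    fit_training_stats,
    run_protocol,
    select_training,
    simulate_cohort,
    simulate_sample,
)
from sizenipt.chromosomes import TARGET_CHROMS
from sizenipt.errors import ConfigurationError, EvaluationError


class TestSelectTraining:
    def test_reference_cohort_partition(self):
        table = simulate_cohort(CohortSimConfig(depth=10_000, seed=1))
        protocol = ProtocolConfig.size_filtered(seed=9)
        train, test = select_training(table, protocol)
        assert len(train) == 30
        assert len(test) == 114
        assert set(train) | set(test) == set(table.sample_ids)
        assert not set(train) & set(test)
        assert all(table.get(sid).label == "euploid" for sid in train)

    def test_deterministic_under_fixed_seed(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(seed=3, n_training=6)
        assert select_training(small_cohort, protocol) == select_training(
            small_cohort, protocol
        )

    def test_explicit_non_euploid_id_rejected(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(
            training_selection="explicit_ids",
            training_ids=("euploid_000", "T21_000"),
            n_training=2,
        )
        with pytest.raises(ConfigurationError, match="T21_000"):
            select_training(small_cohort, protocol)

    def test_too_few_euploids_rejected(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(n_training=99)
        with pytest.raises(ConfigurationError, match="99"):
            select_training(small_cohort, protocol)


class TestCallSample:
    def _fixture(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(seed=0, n_training=6)
        train, _ = select_training(small_cohort, protocol)
        stats = fit_training_stats(
            small_cohort, train, "ratio", SizeRange(80, 155)
        )
        return protocol, stats

    def test_z_exactly_at_cutoff_is_negative(self, small_cohort):
        protocol, stats = self._fixture(small_cohort)
        value = stats.mean["chr21"] + protocol.cutoff * stats.sd["chr21"]
        call = call_sample(
            small_cohort.samples[0],
            stats,
            protocol,
            statistic_override={"chr21": value},
        )
        assert call.z["chr21"] == pytest.approx(protocol.cutoff)
        assert call.positive["chr21"] is False

    def test_training_mean_statistic_is_negative(self, small_cohort):
        protocol, stats = self._fixture(small_cohort)
        call = call_sample(
            small_cohort.samples[0],
            stats,
            protocol,
            statistic_override={t: stats.mean[t] for t in TARGET_CHROMS},
        )
        for t in TARGET_CHROMS:
            assert call.z[t] == pytest.approx(0.0)
            assert not call.positive[t]

    def test_simulated_t21_called_positive(self):
        """A T21 sample at f=0.10 sits far above the 2.5 ratio cutoff."""
        config = CohortSimConfig(
            n_per_class={"euploid": 30},
            depth=100_000,
            fetal_fraction=FetalFraction.fixed(0.10),
            seed=21,
        )
        table = simulate_cohort(config)
        stats = fit_training_stats(
            table, table.sample_ids, "ratio", SizeRange(80, 155)
        )
        rng = np.random.default_rng(99)
        t21 = simulate_sample(config, "T21", rng, "t21")
        call = call_sample(t21, stats, ProtocolConfig.size_filtered())
        assert call.positive["chr21"]
        assert call.z["chr21"] > 2.5


class TestEvaluateCalls:
    @staticmethod
    def _mk_calls(flags):
        return [
            AneuploidyCall(f"s{i}", {"chr18": 0.0}, {"chr18": pos}, 2.5)
            for i, pos in enumerate(flags)
        ]

    def test_reported_confusion_arithmetic(self):
        """23 TP / 4 FN / 83 TN / 4 FP gives 85.2% / 95.4%."""
        flags = [True] * 23 + [False] * 4 + [False] * 83 + [True] * 4
        labels = {f"s{i}": ("T18" if i < 27 else "euploid") for i in range(114)}
        summary = evaluate_calls(self._mk_calls(flags), labels, "chr18")
        assert (summary.TP, summary.FN, summary.TN, summary.FP) == (23, 4, 83, 4)
        assert summary.sensitivity == pytest.approx(0.852, abs=5e-4)
        assert summary.specificity == pytest.approx(0.954, abs=5e-4)

    def test_perfect_classifier(self):
        flags = [True] * 5 + [False] * 7
        labels = {f"s{i}": ("T18" if i < 5 else "euploid") for i in range(12)}
        summary = evaluate_calls(self._mk_calls(flags), labels, "chr18")
        assert summary.sensitivity == 1.0 and summary.specificity == 1.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(17)
        flags = list(rng.random(60) < 0.4)
        label_pool = ["T13", "T18", "T21", "euploid"]
        labels = {f"s{i}": label_pool[rng.integers(4)] for i in range(60)}
        summary = evaluate_calls(self._mk_calls(flags), labels, "chr18")
        tp = sum(1 for i in range(60) if labels[f"s{i}"] == "T18" and flags[i])
        fn = sum(1 for i in range(60) if labels[f"s{i}"] == "T18" and not flags[i])
        fp = sum(1 for i in range(60) if labels[f"s{i}"] != "T18" and flags[i])
        tn = 60 - tp - fn - fp
        assert (summary.TP, summary.FN, summary.FP, summary.TN) == (tp, fn, fp, tn)
        assert summary.n == 60

    def test_unknown_label_rejected(self):
        calls = self._mk_calls([True, False])
        with pytest.raises(EvaluationError, match="s1"):
            evaluate_calls(calls, {"s0": "T18", "s1": "unknown"}, "chr18")


class TestRunProtocol:
    def test_calls_match_independent_z_recomputation(self, small_cohort):
        """End-to-end z-scores equal a from-scratch recomputation."""
        protocol = ProtocolConfig.size_filtered(seed=2, n_training=6)
        result = run_protocol(small_cohort, protocol)
        window = result.resolved_range
        training_values = {
            t: [
                compute_statistic(small_cohort.get(sid), "ratio", window, t)
                for sid in result.training_ids
            ]
            for t in TARGET_CHROMS
        }
        for call in result.calls:
            rec = small_cohort.get(call.sample_id)
            for t in TARGET_CHROMS:
                vals = training_values[t]
                mean = statistics.fmean(vals)
                sd = statistics.stdev(vals)
                value = compute_statistic(rec, "ratio", window, t)
                assert call.z[t] == pytest.approx((value - mean) / sd, rel=1e-9)
                assert call.positive[t] == (call.z[t] > 2.5)

    def test_cutoff_monotonicity(self, small_cohort):
        protocol_low = ProtocolConfig.size_filtered(seed=2, n_training=6, cutoff=1.5)
        n_pos = {}
        for cutoff in (1.5, 2.5, 4.0):
            protocol = dataclasses.replace(protocol_low, cutoff=cutoff)
            result = run_protocol(small_cohort, protocol)
            n_pos[cutoff] = sum(
                sum(c.positive.values()) for c in result.calls
            )
        assert n_pos[1.5] >= n_pos[2.5] >= n_pos[4.0]

    def test_infinite_cutoff_gives_no_positives(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(seed=2, n_training=6, cutoff=1e12)
        result = run_protocol(small_cohort, protocol)
        for s in result.summaries.values():
            assert s.sensitivity == 0.0
            assert s.specificity == 1.0

    def test_seed_reproducibility(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(seed=8, n_training=6)
        r1 = run_protocol(small_cohort, protocol)
        r2 = run_protocol(small_cohort, protocol)
        assert r1.training_ids == r2.training_ids
        assert [c.z for c in r1.calls] == [c.z for c in r2.calls]
        assert r1.summaries == r2.summaries

    def test_confusion_counts_sum_to_test_set(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(seed=4, n_training=6)
        result = run_protocol(small_cohort, protocol)
        for s in result.summaries.values():
            assert s.n == len(result.test_ids)

    def test_size_filtered_dominates_full_range_sensitivity(self):
        """Aggregated over seeds, the windowed ratio protocol detects at
        least as many trisomies as the full-range proportion protocol."""
        tp_ratio = tp_prop = 0
        for seed in range(6):
            table = simulate_cohort(
                CohortSimConfig(
                    n_per_class={"T13": 3, "T18": 3, "T21": 3, "euploid": 40},
                    depth=50_000,
                    seed=100 + seed,
                )
            )
            shared = dict(seed=seed, n_training=30)
            res_b = run_protocol(table, ProtocolConfig.size_filtered(**shared))
            res_a = run_protocol(table, ProtocolConfig.full_range(**shared))
            tp_ratio += sum(s.TP for s in res_b.summaries.values())
            tp_prop += sum(s.TP for s in res_a.summaries.values())
        assert tp_ratio >= tp_prop

    def test_outlier_policy_replaces_extreme_nontarget_statistic(self, small_cohort):
        protocol = ProtocolConfig.size_filtered(
            seed=2, n_training=6, outlier_policy="replace_with_training_mean",
            outlier_z=0.5,  # low threshold to force replacements
        )
        result = run_protocol(small_cohort, protocol)
        assert result.outlier_log  # something was replaced...
        replaced = {(sid, t) for sid, t, _ in result.outlier_log}
        for call in result.calls:
            own = small_cohort.get(call.sample_id).label
            for sid, t, _ in result.outlier_log:
                if sid == call.sample_id:
                    # replaced statistics z-score to ~0 against training mean
                    assert call.z[t] == pytest.approx(0.0)
                    # a sample's own trisomy chromosome is never replaced
                    assert t != {"T13": "chr13", "T18": "chr18", "T21": "chr21"}.get(own)
        assert replaced
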