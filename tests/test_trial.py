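"""ADA classification, rank-sum statistics, the [ADA]:[Drug] metric,
and the paired full / PK-only trial engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from adaqsp.config import SamplingSchedule
from adaqsp.pbpk import SubjectTrajectory
from adaqsp.population import generate_population
from adaqsp.trial import (
    ada_drug_ratio,
    classify_ada,
    compare_pk,
    run_trial,
    wilcoxon_rank_sum,
    wilcoxon_rank_sum_permutation,
)
from adaqsp.units import ng_per_ml_to_nM


def make_trajectory(times, ada_nM, plasma_nM, mode="full"):
    times = np.asarray(times, dtype=float)
    ada = np.asarray(ada_nM, dtype=float)
    plasma = np.asarray(plasma_nM, dtype=float)
    zeros = np.zeros_like(times)
    return SubjectTrajectory(
        times=times,
        drug_nM={"plasma": plasma, "depot": zeros},
        ada_free_nM=ada,
        ada_total_nM=ada,
        complex_nM=zeros,
        cells={},
        mode=mode,
    )


SCHEDULE = SamplingSchedule(
    ada_times_h=[100.0, 200.0], pk_times_h=[100.0, 200.0], final_time_h=200.0
)


class TestClassification:
    def test_peak_above_threshold_positive(self):
        # 150 ng/mL at 150 kDa = 1 nM
        traj = make_trajectory([100.0, 200.0], [1.0, 0.1], [10.0, 10.0])
        assert classify_ada(traj, [100.0, 200.0], 100.0)

    def test_zero_ada_negative(self):
        traj = make_trajectory([100.0, 200.0], [0.0, 0.0], [10.0, 10.0])
        assert not classify_ada(traj, [100.0, 200.0], 100.0)

    def test_strict_exceed_at_sampled_times_only(self):
        """Exactly at threshold when sampled, above it only between samples."""
        t = [50.0, 100.0, 150.0, 200.0]
        at_thresh = ng_per_ml_to_nM(100.0, 150_000.0)
        peak = ng_per_ml_to_nM(150.0, 150_000.0)
        traj = make_trajectory(t, [peak, at_thresh, peak, at_thresh], [1.0] * 4)
        assert not classify_ada(traj, [100.0, 200.0], 100.0)

    def test_invalid_threshold_rejected(self):
        traj = make_trajectory([100.0, 200.0], [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            classify_ada(traj, [100.0], 0.0)


class TestWilcoxon:
    def test_disjoint_small_groups_exact(self):
        # all three x below all three y: 2/20 assignments as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_matches_permutation_oracle_all_small_sizes(self, rng):
        for n in range(2, 11):
            for n1 in range(1, n):
                vals = rng.normal(size=n) + rng.integers(0, 2) * 0.5
                x, y = vals[:n1], vals[n1:]
                ours = wilcoxon_rank_sum(x, y)
                oracle = wilcoxon_rank_sum_permutation(x, y)
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_exact_agrees_with_independent_library(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=5) + 0.3
            ours = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_sample_approximation_reasonable(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(loc=1.0, size=40)
        p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(ref, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestRatio:
    def test_zero_ada_zero_ratio(self):
        full = make_trajectory([100.0, 200.0], [0.0, 0.0], [10.0, 8.0])
        pk = make_trajectory([100.0, 200.0], [0.0, 0.0], [10.0, 9.0], mode="pk_only")
        ratio, inf_flag = ada_drug_ratio(full, pk, SCHEDULE)
        assert ratio == 0.0 and not inf_flag

    def test_equimolar_gives_one(self):
        # 150 ug/mL ADA at 150 kDa = 1000 nM; same for the drug
        ada = ng_per_ml_to_nM(150_000.0, 150_000.0)
        full = make_trajectory([100.0, 200.0], [ada, ada / 2], [5.0, 5.0])
        pk = make_trajectory([100.0, 200.0], [0.0, 0.0], [900.0, 1000.0], "pk_only")
        ratio, _ = ada_drug_ratio(full, pk, SCHEDULE)
        assert ratio == pytest.approx(1.0)

    def test_unit_conversion_example(self):
        # 30 ug/mL ADA at 150 kDa = 200 nM; 10 ug/mL drug at 100 kDa = 100 nM
        ada = ng_per_ml_to_nM(30_000.0, 150_000.0)
        drug = ng_per_ml_to_nM(10_000.0, 100_000.0)
        assert ada == pytest.approx(200.0)
        full = make_trajectory([100.0, 200.0], [ada / 3, ada], [1.0, 1.0])
        pk = make_trajectory([100.0, 200.0], [0.0, 0.0], [500.0, drug], "pk_only")
        ratio, _ = ada_drug_ratio(full, pk, SCHEDULE)
        assert ratio == pytest.approx(2.0)

    def test_zero_drug_flagged_infinite(self):
        full = make_trajectory([100.0, 200.0], [1.0, 1.0], [0.0, 0.0])
        pk = make_trajectory([100.0, 200.0], [0.0, 0.0], [1.0, 0.0], "pk_only")
        ratio, inf_flag = ada_drug_ratio(full, pk, SCHEDULE)
        assert np.isinf(ratio) and inf_flag


def subjects_frame(pos_vals, neg_vals):
    rows = [
        {"ada_positive": True, "free_drug_final_full": v, "solver_failed": False}
        for v in pos_vals
    ] + [
        {"ada_positive": False, "free_drug_final_full": v, "solver_failed": False}
        for v in neg_vals
    ]
    return pd.DataFrame(rows)


class TestVerdict:
    def test_no_positives_not_assessable(self):
        verdict, p = compare_pk(subjects_frame([], [1.0, 2.0, 3.0]))
        assert verdict == "not_assessable" and p is None

    def test_identical_groups_no_impact(self):
        verdict, p = compare_pk(subjects_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert verdict == "no_impact"

    def test_extreme_shift_is_impact(self, rng):
        neg = rng.lognormal(mean=0.0, sigma=0.3, size=230) * 100
        pos = neg[:20] * 0.01
        verdict, p = compare_pk(subjects_frame(pos, neg))
        assert verdict == "impact"
        assert p < 1e-6

    def test_significant_increase_is_not_impact(self, rng):
        neg = rng.normal(loc=10, scale=0.5, size=50)
        pos = rng.normal(loc=100, scale=0.5, size=20)
        verdict, _p = compare_pk(subjects_frame(pos, neg))
        assert verdict == "no_impact"


class TestTrialEngine:
    def test_immune_disabled_trial_all_negative(self, high_risk_scenario):
        sc = high_risk_scenario
        pop = generate_population(sc.hla_table, drug=sc.drug, n=8, seed=4)
        res = run_trial(
            pop, sc.drug, sc.regimen, sc.schedule,
            trial_config=sc.trial, rates=sc.rates, immune_enabled=False,
        )
        assert res.incidence_pct == 0.0
        assert np.all(res.subjects["ratio"] == 0.0)
        assert res.verdict == "not_assessable"

    def test_paired_design_and_positivity(self, high_risk_scenario):
        sc = high_risk_scenario
        pop = generate_population(sc.hla_table, drug=sc.drug, n=6, seed=4)
        res = run_trial(
            pop, sc.drug, sc.regimen, sc.schedule,
            trial_config=sc.trial, rates=sc.rates, keep_trajectories=True,
        )
        assert res.incidence_pct > 0.0
        df = res.subjects
        pos = df[df["ada_positive"]]
        assert np.all(pos["max_ada_ng_ml"] > sc.trial.ada_threshold_ng_per_ml)
        # PK-only arm shares the subject's parameter set: its final free drug
        # must exceed the immune-coupled arm's (ADA can only deplete drug)
        assert np.all(
            df["free_drug_final_pkonly"] >= df["free_drug_final_full"] - 1e-9
        )
        for sid, (full, pk) in res.metadata["trajectories"].items():
            assert full.subject_id == pk.subject_id == sid
            assert pk.mode == "pk_only" and full.mode == "full"

    def test_trial_deterministic(self, low_risk_scenario):
        sc = low_risk_scenario
        pop = generate_population(sc.hla_table, drug=sc.drug, n=5, seed=13)
        a = run_trial(pop, sc.drug, sc.regimen, sc.schedule, rates=sc.rates)
        b = run_trial(pop, sc.drug, sc.regimen, sc.schedule, rates=sc.rates)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
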