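"""Splits, pair generation, calibration, decisions and biometric rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muzzleid.errors import (
    CalibrationError,
    EvaluationError,
    MuzzleIdError,
    PairGenerationError,
)
from muzzleid.verification import (
    ConfusionCounts,
    DecisionThreshold,
    calibrate_threshold,
    compute_fta,
    compute_metrics,
    evaluate_scores,
    generate_pairs,
    genuine_pool,
    imposter_pool_size,
    load_scores,
    save_scores,
    split_database,
)


def tiny_manifest(images_per_individual):
    rows = []
    for i, n in enumerate(images_per_individual):
        for k in range(n):
            rows.append(
                {
                    "individual_id": f"id{i}",
                    "image_path": f"id{i}_{k}.png",
                    "species": "red_deer",
                    "sex": "female",
                    "angle": "0",
                    "quality": "high",
                    "blacklisted": False,
                }
            )
    return pd.DataFrame(rows)


class TestSplitDatabase:
    def test_equal_split_no_crossover(self):
        m = tiny_manifest([2] * 10)
        train, test = split_database(m, split_seed=0)
        assert train["individual_id"].nunique() == 5
        assert test["individual_id"].nunique() == 5
        assert not set(train["individual_id"]) & set(test["individual_id"])

    def test_deterministic(self):
        m = tiny_manifest([2] * 9)
        t1 = split_database(m, split_seed=3)
        t2 = split_database(m, split_seed=3)
        pd.testing.assert_frame_equal(t1[0], t2[0])

    def test_study_scale_split_arithmetic(self):
        m = tiny_manifest([1] * 972)
        train, test = split_database(m, split_seed=1)
        assert train["individual_id"].nunique() == 486
        assert test["individual_id"].nunique() == 486

    def test_too_few_individuals(self):
        with pytest.raises(MuzzleIdError):
            split_database(tiny_manifest([3]))


class TestGeneratePairs:
    def test_pools_by_enumeration(self):
        m = tiny_manifest([2, 2, 2])
        assert len(genuine_pool(m)) == 3
        assert imposter_pool_size(m) == 12

    @pytest.mark.parametrize("r, expected_imposters", [(0.1, 90), (0.5, 10)])
    def test_ratio_arithmetic(self, r, expected_imposters):
        m = tiny_manifest([2] * 10 + [1] * 30)  # 10 genuine pairs available
        ps = generate_pairs(m, r=r, pair_seed=0)
        assert ps.n_genuine == 10
        assert ps.n_imposter == expected_imposters

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        r=st.floats(0.05, 0.95),
        seed=st.integers(0, 10_000),
    )
    def test_realized_fraction_invariant(self, r, seed):
        m = tiny_manifest([2] * 6 + [1] * 40)
        ps = generate_pairs(m, r=r, pair_seed=seed)
        total = len(ps.pairs)
        assert abs(ps.n_genuine / total - r) <= 1.0 / total + 1e-12

    def test_labels_match_identities(self):
        m = tiny_manifest([2, 2, 1, 1])
        ps = generate_pairs(m, r=0.3, pair_seed=1)
        for p in ps.pairs:
            assert (p.label == "genuine") == (p.individual_a == p.individual_b)
            assert p.path_a != p.path_b

    def test_no_genuine_possible(self):
        with pytest.raises(PairGenerationError, match="two or more images"):
            generate_pairs(tiny_manifest([1, 1]), r=0.5)

    def test_deterministic_given_seed(self):
        m = tiny_manifest([2] * 5 + [1] * 20)
        p1 = generate_pairs(m, r=0.3, pair_seed=9)
        p2 = generate_pairs(m, r=0.3, pair_seed=9)
        assert p1.pairs == p2.pairs


class TestCalibrateThreshold:
    def test_integer_score_example(self):
        scores = [10, 20, 30, 25, 40, 50]
        labels = ["imposter"] * 3 + ["genuine"] * 3
        th = calibrate_threshold(scores, labels)
        assert th.t_star == 31 and th.delta == 1
        counts = evaluate_scores(scores, labels, th)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 0, 3)

    def test_separable_case(self):
        th = calibrate_threshold([1, 2, 5, 6], ["imposter", "imposter", "genuine", "genuine"])
        assert th.t_star == 3
        counts = evaluate_scores([1, 2, 5, 6], ["imposter"] * 2 + ["genuine"] * 2, th)
        assert counts.tp == 2 and counts.fp == 0

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(123)
        scores = np.round(rng.uniform(0, 1, 1000), 3)
        labels = np.where(rng.random(1000) < 0.4, "genuine", "imposter")
        th = calibrate_threshold(scores, labels)
        imposters = scores[labels == "imposter"]
        assert (imposters >= th.t_star).sum() == 0
        # oracle: smallest candidate threshold with zero imposter acceptance
        candidates = np.concatenate([np.unique(scores), [imposters.max() + th.delta]])
        feasible = [t for t in candidates if (imposters >= t).sum() == 0]
        assert th.t_star == min(feasible)

    def test_no_imposters_errors(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([1.0, 2.0], ["genuine", "genuine"])


class TestEvaluateAndMetrics:
    def test_all_reject_matcher(self):
        scores = [0.0] * 7
        labels = ["genuine"] * 3 + ["imposter"] * 4
        c = evaluate_scores(scores, labels, DecisionThreshold(0.5, 0.1))
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 3, 4, 0)

    def test_zero_threshold_accepts_everything(self):
        scores = [0.2, 0.9, 0.4]
        labels = ["genuine", "imposter", "imposter"]
        c = evaluate_scores(scores, labels, DecisionThreshold(0.0, 0.1))
        assert c.tp == 1 and c.fp == 2 and c.tn == 0

    def test_hand_tallied_fixture(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 20)
        labels = ["genuine" if i % 2 else "imposter" for i in range(20)]
        th = DecisionThreshold(0.5, 0.01)
        c = evaluate_scores(scores, labels, th)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for s, l in zip(scores, labels):
            key = ("tp" if s >= 0.5 else "fn") if l == "genuine" else ("fp" if s >= 0.5 else "tn")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"], tally["tn"], tally["fn"])
        assert c.total == 20

    def test_metrics_arithmetic(self):
        rep = compute_metrics(ConfusionCounts(tp=3, fn=1, tn=9, fp=1))
        assert rep.tmr == 75.0 and rep.fnmr == 25.0
        assert rep.tnmr == 90.0 and rep.fmr == 10.0
        assert np.isclose(rep.accuracy, 100 * 12 / 14)

    def test_rate_identities_machine_precision(self):
        rep = compute_metrics(ConfusionCounts(tp=174, fn=15, tn=185, fp=4))
        assert rep.tmr + rep.fnmr == 100.0
        assert rep.tnmr + rep.fmr == 100.0

    def test_undefined_rates_are_none(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert rep.tmr is None and rep.fnmr is None
        assert rep.fmr is not None

    @pytest.mark.parametrize(
        "unusable, attempts, expected",
        [(0, 100, 0.0), (50, 100, 50.0), (95, 2193, 100 * 95 / 2193)],
    )
    def test_fail_to_acquire(self, unusable, attempts, expected):
        assert np.isclose(compute_fta(unusable, attempts), expected)

    def test_fta_guards(self):
        with pytest.raises(EvaluationError):
            compute_fta(1, 0)
        with pytest.raises(EvaluationError):
            compute_fta(5, 4)

    def test_scores_cache_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            {"pair_id": [0, 1], "label": ["genuine", "imposter"], "score": [0.8, 0.1]}
        )
        save_scores(frame, tmp_path / "s.csv")
        back = load_scores(tmp_path / "s.csv")
        pd.testing.assert_frame_equal(back, frame)
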