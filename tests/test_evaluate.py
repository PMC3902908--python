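"""ROC machinery, threshold classification, group comparison, probing call.

AUC is cross-checked against the normalized pairwise-concordance statistic
(and sklearn's implementation) on tie-free data; sensitivity/specificity use
the strict-inequality definitions throughout.
"""

from __future__ import annotations

import math
import random
from itertools import product

import pytest
from hypothesis import given, strategies as st

from g4context import (
    EvalCandidate,
    G4DataError,
    ProbingProfile,
    auc,
    classify,
    compare_groups,
    confusion_counts,
    midpoint_thresholds,
    probing_call,
    roc_curve,
    sens_spec,
)

# ---------------------------------------------------------------- oracles


def concordance(cands) -> float:
    fold = [c.score for c in cands if c.label]
    nonfold = [c.score for c in cands if not c.label]
    pairs = [(f > n) + 0.5 * (f == n) for f, n in product(fold, nonfold)]
    return sum(pairs) / (len(fold) * len(nonfold))


def random_candidates(rng, n, ties=False):
    out = []
    for i in range(n):
        score = rng.randint(0, 5) if ties else rng.random() * 10
        out.append(EvalCandidate(f"c{i}", score, rng.random() < 0.5))
    # guarantee both classes
    out[0] = EvalCandidate("c0", out[0].score, True)
    out[1] = EvalCandidate("c1", out[1].score, False)
    return out


# ---------------------------------------------------------------- thresholds


class TestMidpointThresholds:
    def test_midpoints_plus_flanks(self):
        got = midpoint_thresholds([1, 2, 4])
        assert got == [0.0, 1.5, 3.0, 5.0]

    def test_duplicates_collapse(self):
        assert midpoint_thresholds([2, 2, 5]) == [1.0, 3.5, 6.0]

    def test_identical_scores_flank_pair(self):
        assert midpoint_thresholds([3, 3]) == [2.0, 4.0]

    def test_single_score_rejected(self):
        with pytest.raises(G4DataError):
            midpoint_thresholds([1.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_one_midpoint_per_adjacent_distinct_pair(self, scores):
        got = midpoint_thresholds(scores)
        distinct = sorted(set(scores))
        assert len(got) == len(distinct) + 1
        assert got == sorted(got)
        assert got[0] < distinct[0] and got[-1] > distinct[-1]


# ---------------------------------------------------------------- sens/spec


class TestSensSpec:
    def test_perfect_separation(self):
        cands = [
            *(EvalCandidate(f"f{i}", s, True) for i, s in enumerate([3, 4, 5])),
            *(EvalCandidate(f"n{i}", s, False) for i, s in enumerate([1, 2])),
        ]
        assert sens_spec(cands, 2.5) == (1.0, 1.0)

    def test_exact_threshold_counts_in_neither(self):
        cands = [EvalCandidate("f", 2, True), EvalCandidate("n", 2, False)]
        assert sens_spec(cands, 2) == (0.0, 0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(G4DataError):
            sens_spec([EvalCandidate("f", 1, True)], 0.5)

    def test_lower_is_folding_negation(self):
        cands = [EvalCandidate("f", 3, True), EvalCandidate("n", 9, False)]
        sens, spec = sens_spec(cands, 5, lower_is_folding=True)
        assert (sens, spec) == (1.0, 1.0)

    def test_monotone_in_threshold(self):
        rng = random.Random(0)
        cands = random_candidates(rng, 25)
        points = [sens_spec(cands, t) for t in midpoint_thresholds([c.score for c in cands])]
        sens = [p[0] for p in points]
        spec = [p[1] for p in points]
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)


# ---------------------------------------------------------------- ROC / AUC


class TestRocAuc:
    def test_perfect_separation_point_and_auc(self):
        cands = [
            *(EvalCandidate(f"f{i}", 5 + i, True) for i in range(4)),
            *(EvalCandidate(f"n{i}", i, False) for i in range(4)),
        ]
        roc = roc_curve(cands)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in roc)
        assert auc(roc) == pytest.approx(1.0)

    def test_identical_scores_degenerate(self):
        cands = [EvalCandidate(f"c{i}", 2.0, i % 2 == 0) for i in range(8)]
        roc = roc_curve(cands)
        inner = [p for p in roc if 1.0 < p.threshold < 3.0]
        assert inner == []
        assert auc(roc) == pytest.approx(0.5)

    def test_points_agree_with_recount(self):
        rng = random.Random(3)
        cands = random_candidates(rng, 30)
        for p in roc_curve(cands):
            fold = [c for c in cands if c.label]
            nonfold = [c for c in cands if not c.label]
            assert p.sensitivity == sum(c.score > p.threshold for c in fold) / len(fold)
            assert p.specificity == sum(c.score < p.threshold for c in nonfold) / len(nonfold)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_concordance_tie_free(self, seed):
        rng = random.Random(seed)
        cands = random_candidates(rng, 24)
        assert auc(roc_curve(cands)) == pytest.approx(concordance(cands))

    @pytest.mark.parametrize("seed", range(3))
    def test_auc_matches_sklearn_tie_free(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = random.Random(100 + seed)
        cands = random_candidates(rng, 30)
        expected = roc_auc_score([c.label for c in cands], [c.score for c in cands])
        assert auc(roc_curve(cands)) == pytest.approx(expected)

    def test_direction_consistency(self):
        rng = random.Random(11)
        cands = random_candidates(rng, 20)
        negated = [EvalCandidate(c.id, -c.score, c.label) for c in cands]
        a = auc(roc_curve(cands))
        b = auc(roc_curve(negated, lower_is_folding=True))
        assert a == pytest.approx(b)

    def test_random_labels_near_half(self):
        rng = random.Random(5)
        cands = random_candidates(rng, 400)
        assert auc(roc_curve(cands)) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------- classify


class TestClassify:
    def test_intermediate_score_flips_between_presets(self):
        assert classify(2.4, 2.05) == "folding"
        assert classify(2.4, 3.05) == "non-folding"

    def test_exact_threshold_is_non_folding(self):
        assert classify(2.05, 2.05) == "non-folding"

    def test_infinity_sentinel_folds(self):
        assert classify(math.inf, 3.05) == "folding"

    def test_undefined_sentinel_rejected(self):
        with pytest.raises(G4DataError, match="undefined"):
            classify(math.nan)

    @given(st.floats(0, 10, allow_nan=False))
    def test_presets_agree_outside_band(self, ratio):
        if not 2.05 < ratio <= 3.05:
            assert classify(ratio, 2.05) == classify(ratio, 3.05)

    def test_confusion_counts_sum(self):
        rng = random.Random(2)
        cands = random_candidates(rng, 20)
        conf = confusion_counts(cands, 5.0)
        assert sum(conf.values()) == 20
        sens, spec = sens_spec(cands, 5.0)
        assert conf["TP"] / (conf["TP"] + conf["FN"]) == pytest.approx(sens)
        assert conf["TN"] / (conf["TN"] + conf["FP"]) == pytest.approx(spec)


# ---------------------------------------------------------------- Mann-Whitney


class TestCompareGroups:
    def test_fully_separated_u_zero(self):
        u, p, method = compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0 and method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        u, p, method = compare_groups([1.0, 2.5, 3.5], [1.0, 2.5, 3.5])
        assert p > 0.9

    def test_exhaustive_pair_count(self):
        fold = [0.3, 2.2, 5.0, 7.7]
        nonfold = [1.1, 2.9, 4.2]
        expected = sum(f > n for f in fold for n in nonfold)
        u, _, _ = compare_groups(fold, nonfold)
        assert u == expected

    def test_auc_equals_u_over_pairs(self):
        rng = random.Random(9)
        cands = random_candidates(rng, 16)
        fold = [c.score for c in cands if c.label]
        nonfold = [c.score for c in cands if not c.label]
        u, _, _ = compare_groups(fold, nonfold)
        assert auc(roc_curve(cands)) == pytest.approx(u / (len(fold) * len(nonfold)))

    def test_large_n_uses_asymptotic(self):
        rng = random.Random(1)
        a = [rng.random() for _ in range(15)]
        b = [rng.random() for _ in range(15)]
        _, _, method = compare_groups(a, b)
        assert method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(G4DataError):
            compare_groups([], [1.0])


# ---------------------------------------------------------------- probing


def profile(values: dict[int, float], rep: str) -> ProbingProfile:
    return ProbingProfile(ratios=values, replicate=rep)


class TestProbingCall:
    base = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}

    def test_reproducible_accessible_loops_fold(self):
        p1 = profile({**self.base, 2: 2.5, 3: 3.1}, "r1")
        p2 = profile({**self.base, 2: 2.2, 3: 2.0}, "r2")
        assert probing_call([p1, p2], loop_mask={2, 3}) == "folding"

    def test_flat_profiles_do_not_fold(self):
        p1 = profile(self.base, "r1")
        p2 = profile(self.base, "r2")
        assert probing_call([p1, p2], loop_mask={2, 3}) == "non-folding"

    def test_single_qualifying_replicate_insufficient(self):
        p1 = profile({**self.base, 2: 2.5, 3: 3.1}, "r1")
        p2 = profile(self.base, "r2")
        assert probing_call([p1, p2], loop_mask={2, 3}) == "non-folding"

    def test_one_position_insufficient(self):
        p1 = profile({**self.base, 2: 9.0}, "r1")
        p2 = profile({**self.base, 2: 9.0}, "r2")
        assert probing_call([p1, p2], loop_mask={2, 3}) == "non-folding"

    def test_signal_outside_loop_mask_ignored(self):
        p1 = profile({**self.base, 1: 5.0, 4: 5.0}, "r1")
        p2 = profile({**self.base, 1: 5.0, 4: 5.0}, "r2")
        assert probing_call([p1, p2], loop_mask={2, 3}) == "non-folding"

    def test_mismatched_positions_rejected(self):
        p1 = profile(self.base, "r1")
        p2 = profile({1: 1.0, 2: 1.0}, "r2")
        with pytest.raises(G4DataError):
            probing_call([p1, p2], loop_mask={1})

    def test_too_few_replicates_rejected(self):
        with pytest.raises(G4DataError):
            probing_call([profile(self.base, "r1")], loop_mask={2})
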