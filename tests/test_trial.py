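"""Trial statistics: allocation, scoring, group comparison, power."""

import numpy as np
import pytest
import statsmodels.stats.power as smp

from pvsim.battery import AnswerKey
from pvsim.labeler import ASYNCHRONY_LABELS, SYNCHRONOUS
from pvsim.trial import (
    Participant,
    RaterResponse,
    allocate_stratified,
    compare_groups,
    monte_carlo_power,
    power_at,
    required_sample_size,
    score_responses,
    simulate_rater_responses,
)


def make_participants(n_per_stratum):
    out = []
    i = 0
    for prof in ("physician", "respiratory_therapist"):
        for exp in ("<=5y", ">5y"):
            for _ in range(n_per_stratum):
                out.append(Participant(f"p{i:03d}", prof, exp))
                i += 1
    return out


def small_key():
    """7 asynchrony scenarios + 3 synchronous."""
    key = AnswerKey()
    for i, lab in enumerate(ASYNCHRONY_LABELS, start=1):
        key.entries[i] = (lab,)
    for i in range(8, 11):
        key.entries[i] = (SYNCHRONOUS,)
    return key


def brute_force_scores(responses, key):
    """Independent confusion-matrix tally."""
    out = {}
    for r in responses:
        out.setdefault(r.participant_id, {})[r.scenario_id] = r.answered_label
    scores = {}
    for pid, ans in out.items():
        tally = {"tp": 0, "asynch": 0, "tn": 0, "syn": 0, "any": 0}
        for sid, truth in key.entries.items():
            if sid not in ans:
                continue
            if truth[0] == SYNCHRONOUS:
                tally["syn"] += 1
                tally["tn"] += ans[sid] == SYNCHRONOUS
            else:
                tally["asynch"] += 1
                tally["tp"] += ans[sid] == truth[0]
                tally["any"] += ans[sid] != SYNCHRONOUS
        scores[pid] = (
            tally["tp"] / tally["asynch"],
            tally["any"] / tally["asynch"],
            tally["tn"] / tally["syn"],
        )
    return scores


class TestAllocation:
    def test_98_balanced_participants_split_49_49(self):
        participants = make_participants(98 // 4)  # 24 or 25 per stratum
        # top up to exactly 98 keeping strata balanced in pairs
        extra = [Participant("x0", "physician", "<=5y"), Participant("x1", "physician", "<=5y")]
        allocated = allocate_stratified(participants + extra, seed=5)
        counts = {"control": 0, "pmus": 0}
        for p in allocated:
            counts[p.group] += 1
        assert counts["control"] == 49 and counts["pmus"] == 49

    def test_single_participant(self):
        allocated = allocate_stratified([Participant("a", "physician", ">5y")], seed=0)
        assert len(allocated) == 1 and allocated[0].group in ("control", "pmus")

    def test_same_seed_identical_allocation(self):
        ps = make_participants(7)
        a = allocate_stratified(ps, seed=9)
        b = allocate_stratified(ps, seed=9)
        assert [(p.id, p.group) for p in a] == [(p.id, p.group) for p in b]

    @pytest.mark.parametrize("n_per_stratum", [1, 2, 5, 10, 13])
    def test_per_stratum_balance_within_one(self, n_per_stratum):
        allocated = allocate_stratified(make_participants(n_per_stratum), seed=3)
        for prof in ("physician", "respiratory_therapist"):
            for exp in ("<=5y", ">5y"):
                diff = sum(
                    (1 if p.group == "pmus" else -1)
                    for p in allocated
                    if p.profession == prof and p.experience_stratum == exp
                )
                assert abs(diff) <= 1


class TestScoring:
    def test_perfect_rater_scores_one(self):
        key = small_key()
        responses = [
            RaterResponse("r0", sid, key.entries[sid][0]) for sid in key.entries
        ]
        perf = score_responses(responses, key)[0]
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0
        assert perf.sensitivity_any == 1.0

    def test_forced_arithmetic_30_of_40(self):
        key = AnswerKey()
        for i in range(1, 41):
            key.entries[i] = ("ineffective_effort",)
        for i in range(41, 51):
            key.entries[i] = (SYNCHRONOUS,)
        responses = [
            RaterResponse("r0", i, "ineffective_effort" if i <= 30 else "auto_triggering")
            for i in range(1, 41)
        ] + [RaterResponse("r0", i, SYNCHRONOUS) for i in range(41, 51)]
        perf = score_responses(responses, key)[0]
        assert perf.sensitivity == pytest.approx(0.75)

    def test_wrong_type_counts_against_both_types(self):
        key = small_key()
        responses = []
        for sid, truth in key.entries.items():
            if truth[0] == "ineffective_effort":
                responses.append(RaterResponse("r0", sid, "auto_triggering"))
            else:
                responses.append(RaterResponse("r0", sid, truth[0]))
        perf = score_responses(responses, key)[0]
        assert perf.per_type_sensitivity["ineffective_effort"] == 0.0
        assert perf.sensitivity < 1.0
        assert perf.sensitivity_any == 1.0  # an asynchrony was still reported

    def test_missing_responses_flagged(self):
        key = small_key()
        responses = [RaterResponse("r0", 1, "ineffective_effort")]
        with pytest.warns(UserWarning, match="missing"):
            perf = score_responses(responses, key)[0]
        assert not perf.complete

    def test_matches_brute_force_oracle_on_simulated_raters(self):
        key = small_key()
        responses = []
        for i in range(12):
            responses.extend(
                simulate_rater_responses(key, sensitivity=0.6, specificity=0.8,
                                         seed=50 + i, participant_id=f"r{i:02d}")
            )
        perf = {p.participant_id: p for p in score_responses(responses, key)}
        oracle = brute_force_scores(responses, key)
        assert set(perf) == set(oracle)
        for pid, (sens, any_, spec) in oracle.items():
            assert perf[pid].sensitivity == pytest.approx(sens)
            assert perf[pid].sensitivity_any == pytest.approx(any_)
            assert perf[pid].specificity == pytest.approx(spec)


class TestCompareGroups:
    def test_identical_constant_groups_p_one(self):
        cmp = compare_groups([0.5] * 10, [0.5] * 10)
        assert cmp.p_value == 1.0 and not cmp.significant

    def test_detects_difference_with_designed_power(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.53, 0.15, 49)
            b = rng.normal(0.66, 0.15, 49)
            if compare_groups(a, b).significant:
                rejections += 1
        assert rejections / n_rep >= 0.9

    def test_skewed_groups_use_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = rng.exponential(1.0, 60) ** 2
        b = rng.exponential(1.3, 60) ** 2
        cmp = compare_groups(a, b)
        assert cmp.test_used == "mann_whitney"

    def test_normal_groups_use_t(self):
        rng = np.random.default_rng(8)
        cmp = compare_groups(rng.normal(0.5, 0.1, 40), rng.normal(0.55, 0.1, 40))
        assert cmp.test_used == "student_t"
        assert "mean" in cmp.group_summaries["control"]


class TestPower:
    def test_design_inputs_give_49_per_group(self):
        n, total = required_sample_size(10.0, 15.0, power=0.9, alpha_two_sided=0.05)
        assert (n, total) == (49, 98)

    def test_power_at_49_meets_target(self):
        assert power_at(49, 10.0, 15.0, 0.05) >= 0.90
        assert power_at(48, 10.0, 15.0, 0.05) < 0.90  # 49 is minimal

    def test_large_effect_needs_at_most_8(self):
        n, _ = required_sample_size(30.0, 15.0, power=0.9, alpha_two_sided=0.05)
        assert n <= 8

    def test_cross_check_against_statsmodels(self):
        n, _ = required_sample_size(10.0, 15.0, 0.9, 0.05)
        sm_n = smp.TTestIndPower().solve_power(effect_size=10.0 / 15.0, alpha=0.05, power=0.9)
        assert n == int(np.ceil(sm_n))

    def test_monotonicity_over_grid(self):
        base = required_sample_size(10.0, 15.0, 0.9)[0]
        assert required_sample_size(15.0, 15.0, 0.9)[0] <= base  # larger effect
        assert required_sample_size(10.0, 20.0, 0.9)[0] >= base  # more noise
        assert required_sample_size(10.0, 15.0, 0.95)[0] >= base  # more power

    def test_monte_carlo_within_1p5_points_of_analytic(self):
        analytic = power_at(49, 10.0, 15.0, 0.05)
        mc = monte_carlo_power(49, 10.0, 15.0, 0.05, n_replicates=10_000, seed=17)
        assert abs(mc - analytic) < 0.015

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(-1.0, 15.0)
        with pytest.raises(ValueError):
            required_sample_size(10.0, 15.0, power=1.5)


class TestRaterSimulator:
    def test_perfect_profile_roundtrip(self):
        key = small_key()
        responses = simulate_rater_responses(key, 1.0, 1.0, seed=0)
        perf = score_responses(responses, key)[0]
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)

    def test_mean_scored_sensitivity_matches_profile(self):
        key = small_key()
        sens = []
        for i in range(1000):
            responses = simulate_rater_responses(key, 0.6, 1.0, seed=i, participant_id=f"r{i}")
            sens.append(score_responses(responses, key)[0].sensitivity)
        assert np.mean(sens) == pytest.approx(0.6, abs=0.02)

    def test_same_seed_identical_fixture(self):
        key = small_key()
        a = simulate_rater_responses(key, 0.5, 0.8, seed=42)
        b = simulate_rater_responses(key, 0.5, 0.8, seed=42)
        assert [(r.scenario_id, r.answered_label) for r in a] == [
            (r.scenario_id, r.answered_label) for r in b
        ]
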