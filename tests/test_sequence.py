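"""Preprocessing and episode-extraction checks against hand counts and the
brute-force window-scan oracle."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (oracle_error_emotion, oracle_future_accuracy,
                      oracle_pes, oracle_post_outcome)
from conftest import make_log, random_log
from pesddm import sequence


def triples(episode_set):
    return sorted(map(tuple, episode_set.frame[
        ["participant_id", "anchor_ordinal", "target_ordinal"]].to_numpy()))


class TestExclusion:
    def test_identical_accuracies_exclude_nobody(self):
        log = make_log({f"P{i}": "CCCCCCCCEC" for i in range(10)})
        kept, rep = sequence.exclude_participants(log)
        assert len(rep.excluded) == 0 and len(kept) == len(log)

    def test_single_slow_trial_removes_whole_participant(self):
        log = make_log({"A": "CCCC", "B": "CCCC"})
        log.loc[(log.participant_id == "B") & (log.ordinal == 3),
                "rt_ms"] = 12_000.0
        kept, rep = sequence.exclude_participants(log)
        assert rep.excluded["participant_id"].tolist() == ["B"]
        assert rep.excluded["reason"].iloc[0] == "slow_trial"
        assert set(kept["participant_id"]) == {"A"}

    def test_accuracy_outlier_three_sd_below_mean_removed(self):
        # 19 participants at 90% accuracy, one at 50%: mean = 0.88,
        # sd = 0.08944, mean - 3 sd = 0.6117 > 0.5 -> exactly one removed
        patterns = {f"P{i:02d}": "C" * 9 + "E" for i in range(19)}
        patterns["OUT"] = "CECECECEEE"
        log = make_log(patterns)
        accs = log.groupby("participant_id")["correct"].mean()
        thr = accs.mean() - 3 * accs.std(ddof=1)
        assert accs["OUT"] <= thr < accs["P00"]  # hand-check the threshold
        kept, rep = sequence.exclude_participants(log)
        assert rep.excluded["participant_id"].tolist() == ["OUT"]
        assert rep.accuracy_threshold == pytest.approx(thr)

    def test_empty_log_rejected(self):
        empty = make_log({"A": "CC"}).iloc[0:0]
        with pytest.raises(ValueError):
            sequence.exclude_participants(empty)

    def test_reapplying_with_recorded_threshold_is_noop(self):
        rng = np.random.default_rng(5)
        log = random_log(rng, n_participants=30, with_gaps=False)
        kept, rep = sequence.exclude_participants(log)
        again, rep2 = sequence.exclude_participants(kept, report=rep)
        pd.testing.assert_frame_equal(kept, again)


class TestTrimming:
    def test_identical_rts_trim_nothing(self):
        log = make_log({"A": "CCCC"})
        log["rt_ms"] = 900.0
        kept, rep = sequence.trim_rts(log)
        assert rep.n_removed == 0 and len(kept) == 4

    def test_lognormal_rts_trim_two_sided_two_sigma_mass(self):
        rng = np.random.default_rng(11)
        n = 50_000
        log = pd.DataFrame({
            "participant_id": "X", "ordinal": np.arange(1, n + 1),
            "rt_ms": np.exp(rng.normal(7.5, 0.4, n)),
        })
        _, rep = sequence.trim_rts(log)
        assert rep.fraction_removed == pytest.approx(0.0455, abs=0.01)

    def test_single_extreme_outlier_removed(self):
        rng = np.random.default_rng(2)
        n = 10_000
        log = pd.DataFrame({
            "participant_id": "X", "ordinal": np.arange(1, n + 1),
            "rt_ms": np.exp(rng.normal(7.5, 0.05, n)),
        })
        log.loc[n - 1, "rt_ms"] = 50_000.0
        kept, rep = sequence.trim_rts(log)
        assert n - 1 not in kept.index

    def test_reapplying_with_recorded_bounds_is_noop(self):
        rng = np.random.default_rng(3)
        log = random_log(rng, n_participants=30, with_gaps=False)
        kept, rep = sequence.trim_rts(log)
        again, _ = sequence.trim_rts(kept, report=rep)
        pd.testing.assert_frame_equal(kept, again)


class TestExtraction:
    def test_canonical_error_run_yields_all_distances(self):
        log = make_log({"A": "CCECCCCCC"})
        # the error at ordinal 3 anchors distances 1..5 (targets 4..8)
        for d in range(1, 6):
            ep = sequence.extract_post_outcome(log, "error", d)
            assert triples(ep) == [("A", 3, 3 + d)]
        # post-correct anchors need C C C; e.g. at d=1 anchors 6,7,8
        ep = sequence.extract_post_outcome(log, "correct", 1)
        assert triples(ep) == [("A", 6, 7), ("A", 7, 8), ("A", 8, 9)]

    def test_all_correct_participant_has_no_error_episodes(self):
        log = make_log({"A": "C" * 12})
        for d in range(1, 6):
            assert len(sequence.extract_post_outcome(log, "error", d)) == 0

    def test_consecutive_errors_invalidate_second_anchor(self):
        log = make_log({"A": "CCEEC"})
        ep = sequence.extract_post_outcome(log, "error", 1)
        # first E anchors (target = the second E, correctness of the target
        # is unconstrained); second E lacks the two-correct context
        assert triples(ep) == [("A", 3, 4)]

    def test_trimmed_trial_breaks_sequences(self):
        log = make_log({"A": "CCECC"})
        gap = log[log.ordinal != 4]  # as if trimmed
        assert len(sequence.extract_post_outcome(gap, "error", 1)) == 0
        # distance 2 needs the intervening ordinal-4 trial present
        assert len(sequence.extract_post_outcome(gap, "error", 2)) == 0

    def test_distance_out_of_range_rejected(self):
        log = make_log({"A": "CCEC"})
        with pytest.raises(ValueError):
            sequence.extract_post_outcome(log, "error", 6)
        with pytest.raises(ValueError):
            sequence.extract_post_outcome(log, "anchor", 1)

    @pytest.mark.parametrize("anchor", ["error", "correct"])
    @pytest.mark.parametrize("distance", [1, 2, 3, 4, 5])
    def test_matches_bruteforce_oracle_on_random_logs(self, rng, anchor,
                                                      distance):
        for rep in range(4):
            log = random_log(rng, n_participants=12, max_trials=80)
            ep = sequence.extract_post_outcome(log, anchor, distance)
            assert triples(ep) == oracle_post_outcome(log, anchor, distance)

    def test_episode_nesting_across_distances(self, rng):
        # a valid distance-d episode implies the distance-(d-1) episode for
        # the same anchor
        log = random_log(rng, n_participants=15, max_trials=100)
        for anchor in ("error", "correct"):
            sets = {d: set((p, a) for p, a, _ in triples(
                sequence.extract_post_outcome(log, anchor, d)))
                for d in range(1, 6)}
            for d in range(2, 6):
                assert sets[d] <= sets[d - 1]

    def test_no_episode_spans_participants(self, rng):
        log = random_log(rng, n_participants=10, max_trials=40)
        for d in (1, 3, 5):
            ep = sequence.extract_post_outcome(log, "error", d)
            tgt = ep.target_trials(log)
            assert (tgt["participant_id"].to_numpy()
                    == ep.frame["participant_id"].to_numpy()).all()


class TestSplits:
    def test_future_all_correct_goes_to_first_set(self):
        log = make_log({"A": "CCECCCCCC"})
        good, bad = sequence.split_by_future_accuracy(log)
        assert triples(good) == [("A", 3, 4)] and len(bad) == 0

    def test_future_error_goes_to_second_set(self):
        log = make_log({"A": "CCECCECCC"})
        good, bad = sequence.split_by_future_accuracy(log)
        assert triples(bad) == [("A", 3, 4)] and len(good) == 0

    def test_insufficient_lookahead_joins_neither(self):
        log = make_log({"A": "CCECC"})
        good, bad = sequence.split_by_future_accuracy(log)
        assert len(good) == 0 and len(bad) == 0

    def test_emotion_split_uses_anchor_trial_type(self):
        log = make_log({"A": [
            (True, "neutral", 900), (True, "happy", 950),
            (False, "angry", 1200), (True, "neutral", 1400),
            (True, "neutral", 1000), (True, "neutral", 1000),
            (False, "neutral", 1100), (True, "happy", 1300),
        ]})
        angry, happy = sequence.split_by_error_emotion(log)
        assert triples(angry) == [("A", 3, 4)]
        # the neutral-display error at ordinal 7 joins neither set
        assert len(happy) == 0

    def test_splits_match_bruteforce_oracle(self, rng):
        for rep in range(5):
            log = random_log(rng, n_participants=12, max_trials=80)
            good, bad = sequence.split_by_future_accuracy(log)
            o_good, o_bad = oracle_future_accuracy(log)
            assert triples(good) == o_good and triples(bad) == o_bad
            angry, happy = sequence.split_by_error_emotion(log)
            o_angry, o_happy = oracle_error_emotion(log)
            assert triples(angry) == o_angry and triples(happy) == o_happy


class TestPES:
    def test_delta_rt_arithmetic(self):
        log = make_log({"A": [
            (True, "neutral", 800), (True, "neutral", 600),
            (False, "angry", 1200), (True, "neutral", 900),
        ]})
        res = sequence.pes_delta_rt(log)
        assert res.deltas["delta_rt_ms"].tolist() == [300.0]
        assert res.n_skipped == 0

    def test_type_mismatch_skips_episode(self):
        log = make_log({"A": [
            (True, "neutral", 800), (True, "neutral", 600),
            (False, "angry", 1200), (True, "angry", 900),
        ]})
        res = sequence.pes_delta_rt(log)
        assert len(res.deltas) == 0 and res.n_skipped == 1

    def test_matches_bruteforce_oracle(self, rng):
        for rep in range(5):
            log = random_log(rng, n_participants=12, max_trials=80)
            res = sequence.pes_delta_rt(log)
            got = sorted((r.participant_id, r.anchor_ordinal,
                          pytest.approx(r.delta_rt_ms))
                         for r in res.deltas.itertuples())
            want, skipped = oracle_pes(log)
            assert res.n_skipped == skipped
            assert got == [(p, a, pytest.approx(d)) for p, a, d in want]


class TestSummaries:
    def test_all_correct_log_has_unit_accuracy_cells(self):
        log = make_log({"A": "C" * 10, "B": "C" * 10})
        eps = [sequence.extract_post_outcome(log, "correct", d)
               for d in (1, 2)]
        table = sequence.summarize_behavior(log, eps)
        assert (table["accuracy"] == 1.0).all()

    def test_handcrafted_cell_means(self):
        log = make_log({
            "A": [(True, "neutral", 1000), (True, "neutral", 1000),
                  (False, "angry", 2000), (True, "neutral", 1500)],
            "B": [(True, "neutral", 1000), (True, "neutral", 1200),
                  (False, "happy", 1800), (False, "neutral", 2500)],
        })
        table = sequence.summarize_behavior(
            log, [sequence.extract_post_outcome(log, "error", 1)])
        allrow = table[(table.difficulty == "(all)")].iloc[0]
        assert allrow["n"] == 2
        assert allrow["mean_rt_ms"] == pytest.approx((1500 + 2500) / 2)
        assert allrow["accuracy"] == pytest.approx(0.5)
        # ΔRT: A matched (1500-1000), B matched (2500-1200)
        assert allrow["mean_delta_rt_ms"] == pytest.approx((500 + 1300) / 2)

    def test_empty_episode_sets_produce_no_rows(self):
        log = make_log({"A": "C" * 8})
        table = sequence.summarize_behavior(
            log, [sequence.extract_post_outcome(log, "error", 1)])
        assert len(table) == 0
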