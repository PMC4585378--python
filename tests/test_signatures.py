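"""The two time point signatures methods: weight fitting, match scoring,
the -1/0/+1 score-matrix distance, and confidence tiers."""

import numpy as np
import pandas as pd
import pytest

import healstage as hs
from healstage.differential import CALL_DOWN, CALL_NONE, CALL_UP
from healstage.errors import DimensionError
from healstage.signatures import (
    NO_CHANGE_INCREMENT,
    build_score_matrix,
    score_vector,
)
from healstage.types import ClassificationResult

from conftest import TIME_POINTS, make_fc


def fc_from_calls(call_rows: dict, tps=None) -> "hs.FoldChangeMatrix":
    """Build a fold-change matrix whose calls equal the given profile
    (log2fc +-2 for up/down, 0 for none)."""
    tps = tps or TIME_POINTS
    mag = {CALL_UP: 2.0, CALL_DOWN: -2.0, CALL_NONE: 0.0}
    log2fc = pd.DataFrame(
        [[mag[c] for c in row] for row in call_rows.values()],
        index=list(call_rows), columns=tps,
    )
    return make_fc(log2fc)


class TestFitSpecific:
    def test_worked_example_up_two_down_one(self):
        """A gene up at 3 h and 10 h and down at 504 h weighs 1/2 per
        upregulated hour and 1 for the downregulated hour."""
        calls = [CALL_NONE] * 9
        calls[0] = calls[1] = CALL_UP
        calls[7] = CALL_DOWN
        model = hs.fit_specific(fc_from_calls({"g1": calls}))
        assert model.up_weight["g1"] == pytest.approx(0.5)
        assert model.down_weight["g1"] == pytest.approx(1.0)

    def test_up_at_all_nine_hours(self):
        model = hs.fit_specific(fc_from_calls({"g1": [CALL_UP] * 9}))
        assert model.up_weight["g1"] == pytest.approx(1 / 9)
        assert np.isnan(model.down_weight["g1"])

    def test_weights_match_per_row_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            rows = {
                f"g{i}": list(rng.choice([CALL_UP, CALL_DOWN, CALL_NONE], 9))
                for i in range(n)
            }
            model = hs.fit_specific(fc_from_calls(rows))
            for g, row in rows.items():
                n_up, n_down = row.count(CALL_UP), row.count(CALL_DOWN)
                if n_up:
                    assert model.up_weight[g] == pytest.approx(1 / n_up)
                else:
                    assert np.isnan(model.up_weight[g])
                if n_down:
                    assert model.down_weight[g] == pytest.approx(1 / n_down)
                else:
                    assert np.isnan(model.down_weight[g])


class TestScoreSpecific:
    def test_no_change_in_both_profiles_contributes_half(self):
        model = hs.fit_specific(fc_from_calls({"g1": [CALL_NONE] * 9}))
        test = pd.Series({"g1": CALL_NONE})
        assert hs.score_specific(model, test, 3) == pytest.approx(NO_CHANGE_INCREMENT)

    def test_single_tp_self_profile_hand_computed(self):
        """Ten single-hour genes, exactly one active at the candidate hour:
        the self profile scores 9 x 0.5 + 1 x 1 = 5.5."""
        rows = {}
        for i in range(10):
            calls = [CALL_NONE] * 9
            calls[i % 9] = CALL_UP
            rows[f"g{i}"] = calls
        # hour 24 (index 2) has exactly one active gene: g2
        fc = fc_from_calls(rows)
        model = hs.fit_specific(fc)
        test = fc.calls[24]
        assert hs.score_specific(model, test, 24) == pytest.approx(5.5)

    def test_disjoint_feature_sets_rejected(self):
        model = hs.fit_specific(fc_from_calls({"g1": [CALL_NONE] * 9}))
        with pytest.raises(DimensionError):
            hs.score_specific(model, pd.Series({"other": CALL_NONE}), 3)

    def test_control_candidate_expects_all_none(self):
        fc = fc_from_calls({"g1": [CALL_UP] + [CALL_NONE] * 8, "g2": [CALL_NONE] * 9})
        model = hs.fit_specific(fc)
        test = pd.Series({"g1": CALL_NONE, "g2": CALL_NONE})
        assert hs.score_specific(model, test, "control") == pytest.approx(1.0)


class TestFitWeighted:
    def test_direct_normalization(self):
        log2fc = pd.DataFrame([[4.0, 2.0, 1.0, 0.0]], index=["g1"], columns=[3, 10, 24, 48])
        model = hs.fit_weighted(make_fc(log2fc))
        np.testing.assert_allclose(model.weights.loc["g1"], [1.0, 0.5, 0.25, 0.0])
        assert model.max_tp["g1"] == 3

    def test_all_zero_row_is_inert(self):
        log2fc = pd.DataFrame([[0.0, 0.0]], index=["g1"], columns=[3, 10])
        model = hs.fit_weighted(make_fc(log2fc))
        assert (model.weights.loc["g1"] == 0).all()

    def test_weights_match_per_row_normalization_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 20))
            log2fc = pd.DataFrame(
                rng.normal(0, 2, (n, 9)), columns=TIME_POINTS,
                index=[f"g{i}" for i in range(n)],
            )
            model = hs.fit_weighted(make_fc(log2fc))
            for g in log2fc.index:
                row = log2fc.loc[g].abs()
                expect = row / row.max() if row.max() > 0 else row * 0
                np.testing.assert_allclose(model.weights.loc[g], expect)
            # weight 1 exactly at the max-|fold| hour(s)
            np.testing.assert_allclose(model.weights.max(axis=1), 1.0)


class TestScoreWeighted:
    def test_single_matching_feature_scores_its_weight(self):
        log2fc = pd.DataFrame([[1.6, 2.0]], index=["g1"], columns=[3, 10])
        model = hs.fit_weighted(make_fc(log2fc))
        test = pd.Series({"g1": CALL_UP})
        assert hs.score_weighted(model, test, 3) == pytest.approx(0.8)

    def test_none_none_match_adds_half(self):
        log2fc = pd.DataFrame([[0.0, 2.0]], index=["g1"], columns=[3, 10])
        model = hs.fit_weighted(make_fc(log2fc))
        test = pd.Series({"g1": CALL_NONE})
        assert hs.score_weighted(model, test, 3) == pytest.approx(NO_CHANGE_INCREMENT)

    def test_training_aggregate_maximizes_own_hour(self, small_study):
        """Scoring a training hour's own call profile ranks that hour top."""
        study, _ = small_study
        agg = hs.aggregate_replicates(study)
        fc = hs.compute_fold_changes(agg, agg)
        sel = hs.select_features(fc, hs.FilterSpec())
        model = hs.fit_weighted(fc.subset(sel))
        for tp in fc.time_points:
            res = hs.classify_signature(model, fc.calls[tp].loc[sel])
            assert res.winner == tp

    def test_scores_match_loop_oracle(self, rng, small_study):
        """Vectorized scores equal an explicit per-gene loop on a synthetic
        study's profiles."""
        study, _ = small_study
        agg = hs.aggregate_replicates(study)
        fc = hs.compute_fold_changes(agg, agg)
        sel = hs.select_features(fc, hs.FilterSpec())[:200]
        fc_sel = fc.subset(sel)
        model_w = hs.fit_weighted(fc_sel)
        model_s = hs.fit_specific(fc_sel)
        for trial in range(25):
            test = pd.Series(
                rng.choice([CALL_UP, CALL_DOWN, CALL_NONE], len(sel)), index=sel
            )
            for tp in [*TIME_POINTS, "control"]:
                expect_w, expect_s = 0.0, 0.0
                for g in sel:
                    exp = CALL_NONE if tp == "control" else model_w.calls.loc[g, tp]
                    if test[g] != exp:
                        continue
                    if exp == CALL_NONE:
                        expect_w += 0.5
                        expect_s += 0.5
                    else:
                        expect_w += model_w.weights.loc[g, tp]
                        expect_s += (
                            model_s.up_weight[g] if exp == CALL_UP else model_s.down_weight[g]
                        )
                assert hs.score_weighted(model_w, test, tp) == pytest.approx(expect_w)
                assert hs.score_specific(model_s, test, tp) == pytest.approx(expect_s)

    def test_feature_order_permutation_invariant(self, rng):
        rows = {
            f"g{i}": list(rng.choice([CALL_UP, CALL_DOWN, CALL_NONE], 9))
            for i in range(40)
        }
        fc = fc_from_calls(rows)
        model = hs.fit_weighted(fc)
        test = pd.Series(
            rng.choice([CALL_UP, CALL_DOWN, CALL_NONE], 40), index=list(rows)
        )
        shuffled = test.sample(frac=1.0, random_state=1)
        for tp in (3, 168, "control"):
            assert hs.score_weighted(model, test, tp) == pytest.approx(
                hs.score_weighted(model, shuffled, tp)
            )


class TestScoreMatrix:
    def test_identical_profile_has_zero_distance_and_wins(self):
        rows = {"g1": [CALL_UP] + [CALL_NONE] * 8, "g2": [CALL_NONE] * 8 + [CALL_DOWN]}
        fc = fc_from_calls(rows)
        mat = build_score_matrix(fc)
        test = fc.calls[3]
        res = hs.score_matrix_classify(mat, test)
        assert res.winner == 3
        assert res.scores[3] == 0.0

    def test_opposite_sign_cell_contributes_two(self):
        rows = {"g1": [CALL_UP] + [CALL_NONE] * 8}
        mat = build_score_matrix(fc_from_calls(rows))
        test = pd.Series({"g1": CALL_DOWN})
        res = hs.score_matrix_classify(mat, test)
        assert res.scores[3] == 2.0  # |+1 - (-1)|

    def test_distances_match_exhaustive_cell_loop(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 25))
            train = pd.DataFrame(
                rng.choice([-1, 0, 1], (n, 9)), columns=TIME_POINTS,
                index=[f"g{i}" for i in range(n)],
            )
            test_vec = pd.Series(rng.choice([-1, 0, 1], n), index=train.index)
            calls = test_vec.map({1: CALL_UP, -1: CALL_DOWN, 0: CALL_NONE})
            res = hs.score_matrix_classify(train, calls)
            for tp in TIME_POINTS:
                expect = sum(
                    abs(int(train.loc[g, tp]) - int(test_vec[g])) for g in train.index
                )
                assert res.scores[tp] == expect
            assert res.scores["control"] == int(test_vec.abs().sum())

    def test_score_vector_encoding(self):
        calls = pd.Series({"a": CALL_UP, "b": CALL_DOWN, "c": CALL_NONE})
        assert list(score_vector(calls)) == [1, -1, 0]


class TestConfidence:
    @pytest.mark.parametrize(
        "margin,tier",
        [(120.0, "high"), (100.5, "high"), (100.0, "medium"), (75.0, "medium"),
         (50.0, "medium"), (49.9, "low"), (0.0, "low")],
    )
    def test_margin_tiers(self, margin, tier):
        res = ClassificationResult(
            scores={3: 200.0, 10: 200.0 - margin}, winner=3, margin=margin
        )
        assert hs.assign_confidence(res).confidence == tier

    def test_tie_is_low_and_flagged(self):
        res = ClassificationResult(
            scores={3: 5.0, 10: 5.0}, winner=3, margin=0.0, tie=True
        )
        out = hs.assign_confidence(res)
        assert out.confidence == "low" and out.tie

    def test_tie_breaks_toward_earlier_class(self):
        scores = {10: 5.0, 3: 5.0, "control": 1.0}
        winner, margin, tie = hs.best_class(scores)
        assert winner == 3 and margin == 0.0 and tie

    def test_single_class_rejected(self):
        res = ClassificationResult(scores={3: 1.0}, winner=3, margin=0.0)
        with pytest.raises(DimensionError):
            hs.assign_confidence(res)
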