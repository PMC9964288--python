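import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waterscape.core_io import ReviewRecord
from waterscape.fixtures import load_table
from waterscape.sentiment_analysis import (
    LexiconScorer,
    SenseLexicon,
    fit_rate_emotion_regression,
    relative_stats,
    score_sentiment,
    sense_word_frequency,
    summarize_park,
)


@pytest.fixture(scope="module")
def scorer():
    return LexiconScorer.default()


class TestScorer:
    def test_no_hits_neutral(self, scorer):
        assert scorer("just a plain sentence about trams") == 5.0

    def test_all_positive_maxes_out(self, scorer):
        assert scorer("beautiful wonderful peaceful") == 10.0

    def test_three_pos_one_neg(self, scorer):
        assert scorer("beautiful peaceful happy ugly") == 7.5

    def test_empty_text_neutral(self, scorer):
        assert scorer("") == 5.0

    def test_swap_symmetry(self, scorer):
        swapped = LexiconScorer(positive=scorer.negative, negative=scorer.positive)
        for text in ("beautiful day", "ugly mess", "beautiful but dirty and noisy"):
            assert swapped(text) == pytest.approx(10.0 - scorer(text))

    def test_score_sentiment_validates_range(self):
        with pytest.raises(ValueError, match="outside"):
            score_sentiment(["x"], scorer=lambda t: 42.0)


class TestRelativeStats:
    def test_qcp_published_row(self):
        s = relative_stats(410, 1376, 7.2, 3.5, park_id="QCP")
        assert s.relative_evaluation_rate == 29.8
        assert s.relative_emotional_value == 2.1

    def test_ywp_published_row(self):
        s = relative_stats(10, 28, 7.8, 4.5, park_id="YWP")
        assert s.relative_evaluation_rate == 35.7
        assert s.relative_emotional_value == 1.7

    def test_equal_values_ratio_one(self):
        assert relative_stats(5, 10, 6.0, 6.0).relative_emotional_value == 1.0

    def test_zero_park_count_error(self):
        with pytest.raises(ValueError):
            relative_stats(0, 0, 5.0, 5.0)

    def test_zero_park_value_error(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_stats(1, 2, 5.0, 0.0)

    def test_fixture_has_nine_of_twelve_above_one(self):
        table5 = load_table("table5")
        ratios = table5["landscape_emotional_value"] / table5["park_emotional_value"]
        assert int((ratios > 1).sum()) == 9
        above_two = set(table5.loc[ratios > 2, "park_id"])
        assert {"QCP", "BTP"} <= above_two

    def test_ratio_above_one_iff_landscape_higher(self, rng):
        for _ in range(25):
            lv, pv = rng.uniform(0.5, 9.5, size=2)
            if abs(lv / pv - 1.0) < 0.05:  # avoid the rounding boundary
                continue
            s = relative_stats(1, 2, lv, pv)
            assert (s.relative_emotional_value > 1) == (lv > pv)


class TestSummarizePark:
    def test_scores_by_target(self, scorer):
        records = [
            ReviewRecord("P", "landscape", "", score=8.0),
            ReviewRecord("P", "landscape", "", score=6.0),
            ReviewRecord("P", "park", "", score=2.0),
            ReviewRecord("P", "park", "", score=4.0),
        ]
        s = summarize_park(records)
        assert s.n_landscape == 2
        assert s.n_park == 4
        assert s.landscape_emotional_value == 7.0
        assert s.park_emotional_value == 5.0
        assert s.relative_emotional_value == 1.4
        assert s.relative_evaluation_rate == 50.0

    def test_unscored_records_use_scorer(self, scorer):
        records = [
            ReviewRecord("P", "landscape", "beautiful peaceful"),
            ReviewRecord("P", "park", "ugly dirty"),
        ]
        s = summarize_park(records, scorer)
        assert s.landscape_emotional_value == 10.0
        assert s.park_emotional_value == 5.0

    def test_multiple_parks_rejected(self):
        records = [
            ReviewRecord("P", "landscape", "", score=5.0),
            ReviewRecord("Q", "park", "", score=5.0),
        ]
        with pytest.raises(ValueError, match="multiple parks"):
            summarize_park(records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_park([])


class TestRegression:
    def make_summaries(self, xs, ys):
        return [
            relative_stats(int(x), 100, y * 2.0, 2.0, park_id=str(i))
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_collinear_r2_one(self):
        s = self.make_summaries([10, 20, 30, 40], [1.0, 2.0, 3.0, 4.0])
        res = fit_rate_emotion_regression(s)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_constant_y_slope_zero(self):
        s = self.make_summaries([10, 20, 30], [2.0, 2.0, 2.0])
        res = fit_rate_emotion_regression(s)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_rate_emotion_regression(self.make_summaries([10, 20], [1.0, 2.0]))

    @given(st.integers(0, 2000))
    @settings(max_examples=25, deadline=None)
    def test_r2_equals_squared_correlation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        xs = rng.integers(1, 99, size=n)
        ys = rng.uniform(0.5, 4.0, size=n)
        summaries = self.make_summaries(xs, ys)
        x = np.array([s.relative_evaluation_rate for s in summaries])
        y = np.array([s.relative_emotional_value for s in summaries])
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            return
        res = fit_rate_emotion_regression(summaries)
        r = np.corrcoef(x, y)[0, 1]
        assert res.r_squared == pytest.approx(r**2)


class TestSenseFrequency:
    def test_empty_corpus_all_zero(self):
        counts = sense_word_frequency([])
        assert set(counts) == {"vision", "smell", "hearing", "touch", "taste", "feeling"}
        assert all(v == 0 for v in counts.values())

    def test_repeated_vision_term(self):
        counts = sense_word_frequency(["scenic scenic scenic scenic"])
        assert counts["vision"] == 4
        assert sum(counts.values()) == 4

    def test_manual_count_oracle(self):
        corpus = [
            "beautiful golden view with fragrant breeze",
            "quiet and peaceful, delicious snacks",
            "bright colorful flowers; noisy crowd though",
        ]
        counts = sense_word_frequency(corpus)
        # hand count: vision: beautiful, golden, view, bright, colorful = 5
        assert counts["vision"] == 5
        assert counts["smell"] == 1  # fragrant
        assert counts["hearing"] == 2  # quiet, noisy
        assert counts["touch"] == 1  # breeze
        assert counts["taste"] == 1  # delicious
        assert counts["feeling"] == 1  # peaceful

    def test_ranked_ties_break_lexicographically(self):
        counts = sense_word_frequency(["smooth delicious"])
        keys = list(counts)
        assert keys[0] == "taste" or keys[0] == "touch"
        tied = [k for k, v in counts.items() if v == 1]
        assert tied == sorted(tied)

    def test_overlapping_senses_rejected(self):
        with pytest.raises(ValueError, match="both"):
            SenseLexicon({"vision": frozenset({"x"}), "smell": frozenset({"x"})})
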