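"""Review sentiment: emotional values, relative statistics, the rate-emotion
regression, and five-sense word frequencies.

The original study scored Chinese microblog text with a proprietary engine;
here the scorer is a pluggable callable.  The default is a transparent
lexicon scorer on the same 0-10 scale: 5 + 5*(pos-neg)/(pos+neg) over lexicon
hits, neutral 5 with no hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from waterscape.core_io import ReviewRecord, round_half_even
from waterscape.fixtures import load_terms, load_sense_lexicon

__all__ = [
    "SenseLexicon",
    "LexiconScorer",
    "ParkSentimentSummary",
    "RegressionResult",
    "score_sentiment",
    "summarize_park",
    "relative_stats",
    "fit_rate_emotion_regression",
    "sense_word_frequency",
]

SENSES = ("vision", "smell", "hearing", "touch", "taste", "feeling")

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str, segmenter: Callable[[str], list[str]] | None = None) -> list[str]:
    """Whitespace/word tokenization; pass a segmenter for CJK text."""
    if segmenter is not None:
        return segmenter(text)
    return [t.lower() for t in _TOKEN_RE.findall(text)]


@dataclass(frozen=True)
class SenseLexicon:
    terms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sense, terms in self.terms.items():
            for term in terms:
                if term in seen:
                    raise ValueError(f"term {term!r} in both {seen[term]!r} and {sense!r}")
                seen[term] = sense

    @classmethod
    def default(cls) -> "SenseLexicon":
        return cls(terms={s: frozenset(t) for s, t in load_sense_lexicon().items()})


@dataclass(frozen=True)
class LexiconScorer:
    """Token-hit scorer: 5 + 5*(pos - neg)/(pos + neg), clipped to [0, 10]."""

    positive: frozenset[str]
    negative: frozenset[str]
    segmenter: Callable[[str], list[str]] | None = None

    @classmethod
    def default(cls) -> "LexiconScorer":
        return cls(
            positive=frozenset(load_terms("lexicon_positive.txt")),
            negative=frozenset(load_terms("lexicon_negative.txt")),
        )

    def __call__(self, text: str) -> float:
        tokens = tokenize(text, self.segmenter)
        pos = sum(1 for t in tokens if t in self.positive)
        neg = sum(1 for t in tokens if t in self.negative)
        if pos + neg == 0:
            return 5.0
        return float(np.clip(5.0 + 5.0 * (pos - neg) / (pos + neg), 0.0, 10.0))


def score_sentiment(texts: Sequence[str], scorer: Callable[[str], float] | None = None) -> list[float]:
    scorer = scorer if scorer is not None else LexiconScorer.default()
    scores = [float(scorer(t)) for t in texts]
    for s in scores:
        if not 0.0 <= s <= 10.0:
            raise ValueError(f"scorer returned {s}, outside [0, 10]")
    return scores


@dataclass(frozen=True)
class ParkSentimentSummary:
    park_id: str
    n_landscape: int
    n_park: int
    relative_evaluation_rate: float
    landscape_emotional_value: float
    park_emotional_value: float
    relative_emotional_value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def relative_stats(
    n_landscape: int,
    n_park: int,
    landscape_value: float,
    park_value: float,
    park_id: str = "",
) -> ParkSentimentSummary:
    """Relative statistics from counts and (unrounded) emotional values.

    Ratios are formed before rounding, then rounded to 1 decimal — the order
    that matches the published figures (7.8/4.5 = 1.73 -> 1.7).
    """
    if n_park <= 0:
        raise ValueError("park evaluation count must be positive")
    if park_value <= 0:
        raise ValueError("relative emotional value undefined: park emotional value is 0")
    return ParkSentimentSummary(
        park_id=park_id,
        n_landscape=int(n_landscape),
        n_park=int(n_park),
        relative_evaluation_rate=round_half_even(100.0 * n_landscape / n_park, 1),
        landscape_emotional_value=round_half_even(landscape_value, 1),
        park_emotional_value=round_half_even(park_value, 1),
        relative_emotional_value=round_half_even(landscape_value / park_value, 1),
    )


def summarize_park(
    records: Sequence[ReviewRecord],
    scorer: Callable[[str], float] | None = None,
) -> ParkSentimentSummary:
    """Per-park summary from scored review records.

    Records missing a score are scored with ``scorer`` (default lexicon
    scorer).  All records must belong to one park.
    """
    if not records:
        raise ValueError("no review records")
    park_ids = {r.park_id for r in records}
    if len(park_ids) != 1:
        raise ValueError(f"records span multiple parks: {sorted(park_ids)}")
    needs = [r for r in records if r.score is None]
    if needs:
        scores = score_sentiment([r.text for r in needs], scorer)
        for r, s in zip(needs, scores):
            r.score = s
    by_landscape = [r.score for r in records if r.target == "landscape"]
    all_scores = [r.score for r in records]
    if not by_landscape:
        raise ValueError("no landscape-targeted records; landscape emotional value undefined")
    return relative_stats(
        n_landscape=len(by_landscape),
        n_park=len(records),
        landscape_value=float(np.mean(by_landscape)),
        park_value=float(np.mean(all_scores)),
        park_id=park_ids.pop(),
    )


def fit_rate_emotion_regression(
    summaries: Sequence[ParkSentimentSummary],
) -> RegressionResult:
    """OLS of relative emotional value on relative evaluation rate."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 parks for the regression")
    x = np.array([s.relative_evaluation_rate for s in summaries], dtype=float)
    y = np.array([s.relative_emotional_value for s in summaries], dtype=float)
    if np.ptp(y) == 0:  # constant response: flat fit, nothing explained
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(summaries))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(summaries),
    )


def sense_word_frequency(
    texts: Iterable[str],
    lexicon: SenseLexicon | None = None,
    segmenter: Callable[[str], list[str]] | None = None,
) -> dict[str, int]:
    """Count lexicon-term occurrences per sense across a corpus.

    The returned dict is ordered by descending count with lexicographic
    tie-break on the sense name.
    """
    lexicon = lexicon if lexicon is not None else SenseLexicon.default()
    if not any(lexicon.terms.values()):
        raise ValueError("sense lexicon is empty")
    counts = {sense: 0 for sense in lexicon.terms}
    term_to_sense = {t: s for s, terms in lexicon.terms.items() for t in terms}
    for text in texts:
        for token in tokenize(text, segmenter):
            sense = term_to_sense.get(token)
            if sense is not None:
                counts[sense] += 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
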