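"""Word-stimulus pools and per-group stimulus selection.

Each participant rates a pool of candidate words for how anxiety-provoking
they are (1-9 Likert scale). The task then uses the 20 highest-rated
anxiety words -- disorder-specific words for the patient group (AN),
general anxiety words for controls -- and the 20 lowest-rated neutral
words, syllable-matched to the chosen anxiety set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

VALID_CATEGORIES = ("disorder", "general", "neutral")

# Exhaustive tie-resolution is attempted up to this many candidate subsets.
_MAX_TIE_COMBOS = 100_000


@dataclass(frozen=True)
class WordRating:
    """One rated candidate word."""

    word: str
    category: str
    rating: float
    syllables: int

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown word category {self.category!r}")
        if not 1.0 <= self.rating <= 9.0:
            raise ValueError(f"rating {self.rating} outside the 1-9 scale")
        if self.syllables < 1:
            raise ValueError("syllable count must be >= 1")


@dataclass(frozen=True)
class StimulusSet:
    """The 20 anxiety and 20 neutral words chosen for one participant."""

    anxiety_words: tuple[str, ...]
    neutral_words: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, words in (("anxiety", self.anxiety_words),
                            ("neutral", self.neutral_words)):
            if len(words) != 20 or len(set(words)) != 20:
                raise ValueError(f"{name} word list must hold 20 unique words")
        if set(self.anxiety_words) & set(self.neutral_words):
            raise ValueError("anxiety and neutral word lists overlap")


def default_word_pool(seed: int = 0, n_per_category: int = 50) -> list[WordRating]:
    """Synthetic rated word pool standing in for participant ratings.

    Ratings are drawn once from a seeded generator: anxiety categories
    skew high on the 1-9 scale, neutral words skew low; syllable counts
    are 1-5. Tokens are opaque (``disorder_07`` etc.) -- the analysis only
    ever uses ratings, categories and syllable counts.
    """
    rng = np.random.default_rng(seed)
    pool: list[WordRating] = []
    for category, (lo, hi) in (("disorder", (4.0, 9.0)),
                               ("general", (4.0, 9.0)),
                               ("neutral", (1.0, 5.0))):
        ratings = np.round(rng.uniform(lo, hi, size=n_per_category), 2)
        syllables = rng.integers(1, 6, size=n_per_category)
        for i in range(n_per_category):
            pool.append(WordRating(f"{category}_{i:02d}", category,
                                   float(ratings[i]), int(syllables[i])))
    return pool


def _mean_syllables(words: list[WordRating]) -> float:
    return float(np.mean([w.syllables for w in words]))


def select_stimuli(pool: list[WordRating], group: str) -> StimulusSet:
    """Pick the per-participant stimulus set from a rated pool.

    AN participants receive the 20 highest-rated disorder-specific words,
    controls the 20 highest-rated general anxiety words. Neutral words are
    the 20 lowest-rated; when several candidates are tied at the rating
    cutoff, the tie is resolved by choosing the subset whose mean syllable
    count is closest to the anxiety set's. Deterministic for a fixed pool.
    """
    if group not in ("AN", "CON"):
        raise ValueError(f"group must be 'AN' or 'CON', got {group!r}")
    anx_category = "disorder" if group == "AN" else "general"

    anx_candidates = [w for w in pool if w.category == anx_category]
    neutral_candidates = [w for w in pool if w.category == "neutral"]
    if len(anx_candidates) < 20:
        raise ValueError(
            f"need at least 20 words in category {anx_category!r}, "
            f"found {len(anx_candidates)}")
    if len(neutral_candidates) < 20:
        raise ValueError(
            f"need at least 20 words in category 'neutral', "
            f"found {len(neutral_candidates)}")

    # Highest-rated anxiety words; word token breaks rating ties.
    anx_sorted = sorted(anx_candidates, key=lambda w: (-w.rating, w.word))
    anxiety = anx_sorted[:20]
    target = _mean_syllables(anxiety)

    # Lowest-rated neutral words, with syllable matching among ties at the
    # rating cutoff.
    neu_sorted = sorted(neutral_candidates, key=lambda w: (w.rating, w.word))
    cutoff = neu_sorted[19].rating
    mandatory = [w for w in neu_sorted if w.rating < cutoff]
    tied = [w for w in neu_sorted if w.rating == cutoff]
    k = 20 - len(mandatory)
    if k == len(tied):
        neutral = mandatory + tied
    else:
        import math

        n_combos = math.comb(len(tied), k)
        if n_combos <= _MAX_TIE_COMBOS:
            best = min(
                itertools.combinations(tied, k),
                key=lambda combo: (
                    abs(_mean_syllables(mandatory + list(combo)) - target),
                    tuple(w.word for w in combo),
                ),
            )
            neutral = mandatory + list(best)
        else:
            # Degenerate huge tie sets: greedy on syllable distance to the
            # anxiety-set mean, then word token.
            tied_sorted = sorted(
                tied, key=lambda w: (abs(w.syllables - target), w.word))
            neutral = mandatory + tied_sorted[:k]

    return StimulusSet(tuple(w.word for w in anxiety),
                       tuple(w.word for w in neutral))
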