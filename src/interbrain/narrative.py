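"""Transcript-derived statistics for interpreting the coupling lag.

A time lag between a speaker's and a listener's neural activity is only
interpretable against the temporal grain of the narration itself: how long
a word takes, how many words make up a small semantic unit (a proposition
or set of propositions advancing the plot), and hence how many words or
units fit into the observed lag.  These are simple arithmetic quantities,
but the rounding conventions matter for reproducing printed values, so
they are centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SegmentedTranscript", "mean_word_duration", "unit_stats",
    "unit_duration", "lag_interpretation", "segmentation_agreement",
]


@dataclass
class SegmentedTranscript:
    """An ordered word sequence partitioned into small semantic units.

    ``unit_boundaries`` are the strictly increasing word indices at which a
    new unit starts (excluding index 0 and the word count), so ``k``
    boundaries partition the words into ``k + 1`` units covering all words.
    """

    words: list[str]
    unit_boundaries: list[int]
    story_duration: float

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("transcript must contain at least one word")
        if self.story_duration <= 0:
            raise ValueError("story duration must be positive")
        b = list(self.unit_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("unit boundaries must be strictly increasing")
        if b and (b[0] <= 0 or b[-1] >= len(self.words)):
            raise ValueError("boundaries must be interior word indices")

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def units(self) -> list[list[str]]:
        edges = [0, *self.unit_boundaries, len(self.words)]
        return [self.words[a:b] for a, b in zip(edges, edges[1:])]

    @property
    def words_per_unit(self) -> np.ndarray:
        return np.asarray([len(u) for u in self.units])


def mean_word_duration(transcript: SegmentedTranscript) -> float:
    """Average word length in seconds: story duration / word count."""
    return transcript.story_duration / transcript.n_words


def unit_stats(transcript: SegmentedTranscript,
               quantiles: tuple[float, float] = (0.05, 0.95)) -> dict:
    """Words-per-unit statistics and the corresponding unit durations.

    Unit duration is words-per-unit times the mean word duration.  The
    default quantiles are the 5-95% band.
    """
    wpu = transcript.words_per_unit
    if len(wpu) == 0:
        raise ValueError("transcript has no units")
    word_dur = mean_word_duration(transcript)
    lo, hi = np.quantile(wpu, quantiles)
    return {
        "n_units": len(wpu),
        "words_per_unit_mean": float(wpu.mean()),
        "words_per_unit_quantiles": (float(lo), float(hi)),
        "unit_duration_mean_s": float(wpu.mean() * word_dur),
        "unit_duration_quantiles_s": (float(lo * word_dur), float(hi * word_dur)),
    }


def unit_duration(n_words: float, word_dur: float,
                  ndigits: int | None = None) -> float:
    """Duration of a unit of ``n_words`` words, optionally rounded.

    Definitional identity: quantile word counts times the mean word
    duration give the quantile unit durations exactly.
    """
    if word_dur <= 0:
        raise ValueError("word duration must be positive")
    d = n_words * word_dur
    return d if ndigits is None else round(d, ndigits)


def lag_interpretation(lag_s: float, word_dur: float,
                       words_per_unit: float) -> tuple[int, float]:
    """Express a neural coupling lag in words and in small semantic units.

    Words are rounded to the nearest integer; units (the unrounded
    words-equivalent divided by the mean unit length) to one decimal.
    Scaling lag and word duration by a common factor leaves both outputs
    unchanged.
    """
    if word_dur <= 0 or words_per_unit <= 0:
        raise ValueError("word duration and words-per-unit must be positive")
    if lag_s < 0:
        raise ValueError("lag must be non-negative for unit conversion")
    words_equiv = lag_s / word_dur
    return int(round(words_equiv)), round(words_equiv / words_per_unit, 1)


def segmentation_agreement(rater_a: Sequence[int], rater_b: Sequence[int],
                           n_words: int) -> float:
    """Fraction of between-word positions with identical boundary decisions.

    Each rater's segmentation is the set of word indices at which they
    placed a unit boundary; there are ``n_words - 1`` between-word
    positions, each a binary boundary / no-boundary decision.
    """
    if n_words < 2:
        raise ValueError("need at least two words to have boundary positions")
    positions = range(1, n_words)
    sa, sb = set(rater_a), set(rater_b)
    for s, name in ((sa, "rater_a"), (sb, "rater_b")):
        if any(p not in positions for p in s):
            raise ValueError(f"{name} has boundaries outside the token sequence")
    agree = sum((p in sa) == (p in sb) for p in positions)
    return agree / (n_words - 1)
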