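"""Generation and scoring of the concretely specified cognitive tasks.

Two task generators are implemented in full:

* odd-one-out (language): five words are delivered, four of which are
  related; the participant names the unrelated word within a five-second
  response window;
* spelling backwards (attention): a word of 3, 4 or 5+ letters (the
  difficulty tiers) is spelled in reverse.

Responses are normalized (lowercase, trimmed, punctuation stripped) before
comparison — a desk-scale stand-in for the platform's spoken-response
capture. A correct answer delivered after the window closes is scored
incorrect. Open-ended prompts are unscoreable and excluded from
percent-correct.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .kinematics_io import CognitiveResult

__all__ = [
    "DEFAULT_RESPONSE_WINDOW_S",
    "OddOneOutItem",
    "SpellBackwardsItem",
    "load_word_bank",
    "make_odd_one_out",
    "make_spell_backwards",
    "score_item",
    "percent_correct",
]

#: standard response window before the next stimulus, seconds
DEFAULT_RESPONSE_WINDOW_S = 5.0

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_response(text: Optional[str]) -> str:
    if text is None:
        return ""
    return " ".join(text.lower().translate(_PUNCT_TABLE).split())


@dataclass(frozen=True)
class OddOneOutItem:
    """Five words, four related; the odd one must be named within the window."""

    words: tuple[str, ...]
    related_category: str
    odd_index: int
    response_window: float = DEFAULT_RESPONSE_WINDOW_S

    def __post_init__(self) -> None:
        if len(self.words) != 5:
            raise ValueError(f"odd-one-out delivers exactly 5 words, got {len(self.words)}")
        if len(set(self.words)) != 5:
            raise ValueError("odd-one-out words must be distinct")
        if not (0 <= self.odd_index <= 4):
            raise ValueError("odd_index must lie in 0..4")

    @property
    def odd_word(self) -> str:
        return self.words[self.odd_index]


@dataclass(frozen=True)
class SpellBackwardsItem:
    """A word to spell in reverse; difficulty tier is the word-length band."""

    word: str
    response_window: float = DEFAULT_RESPONSE_WINDOW_S

    def __post_init__(self) -> None:
        if len(self.word) < 3:
            raise ValueError("spelling-backwards words have at least 3 letters")

    @property
    def difficulty_tier(self) -> int:
        """3, 4, or 5 (meaning five-plus letters)."""
        return min(len(self.word), 5)

    @property
    def expected(self) -> str:
        return self.word[::-1]


def load_word_bank() -> dict[str, list[str]]:
    """Categorized word bank shipped with the package."""
    with resources.files("dartkit.data").joinpath("word_bank.json").open("r") as fh:
        return json.load(fh)


def make_odd_one_out(
    bank: Optional[dict[str, Sequence[str]]] = None,
    category: Optional[str] = None,
    rng_seed: int = 0,
    response_window: float = DEFAULT_RESPONSE_WINDOW_S,
) -> OddOneOutItem:
    """Draw an odd-one-out item: 4 words from ``category``, 1 from outside.

    Deterministic for a fixed seed; the odd word's position is uniform over
    the five slots. ``category`` defaults to a seeded uniform draw from the
    bank.
    """
    bank = bank if bank is not None else load_word_bank()
    rng = np.random.default_rng(rng_seed)
    categories = sorted(bank)
    if category is None:
        category = categories[int(rng.integers(len(categories)))]
    if category not in bank:
        raise ValueError(f"unknown category {category!r}")
    in_cat = sorted(set(bank[category]))
    outside = sorted({w for c in categories if c != category for w in bank[c]} - set(in_cat))
    if len(in_cat) < 4:
        raise ValueError(f"category {category!r} needs >= 4 words, has {len(in_cat)}")
    if not outside:
        raise ValueError("word bank needs at least one word outside the category")
    related = list(rng.choice(in_cat, size=4, replace=False))
    odd = str(rng.choice(outside))
    odd_index = int(rng.integers(5))
    words = related[:odd_index] + [odd] + related[odd_index:]
    return OddOneOutItem(words=tuple(words), related_category=category,
                         odd_index=odd_index, response_window=response_window)


def make_spell_backwards(
    difficulty_tier: int = 3,
    bank: Optional[dict[str, Sequence[str]]] = None,
    rng_seed: int = 0,
) -> SpellBackwardsItem:
    """Draw a word of the requested length tier (3, 4, or 5 = five-plus)."""
    if difficulty_tier not in (3, 4, 5):
        raise ValueError("difficulty_tier must be 3, 4 or 5 (five-plus)")
    bank = bank if bank is not None else load_word_bank()
    words = sorted({w for ws in bank.values() for w in ws})
    pool = [w for w in words if (len(w) >= 5 if difficulty_tier == 5 else len(w) == difficulty_tier)]
    if not pool:
        raise ValueError(f"no words available for tier {difficulty_tier}")
    rng = np.random.default_rng(rng_seed)
    return SpellBackwardsItem(word=str(rng.choice(pool)))


def score_item(
    item,
    response: Optional[str],
    response_time: Optional[float] = None,
) -> dict:
    """Score one response: correct iff it matches the target in time.

    ``item`` is an :class:`OddOneOutItem`, :class:`SpellBackwardsItem`, or
    any object with an ``expected``/``odd_word`` target; an item without a
    target (open-ended) yields ``scoreable=False``.
    """
    if isinstance(item, OddOneOutItem):
        target = item.odd_word
        window = item.response_window
    elif isinstance(item, SpellBackwardsItem):
        target = item.expected
        window = item.response_window
    else:
        target = getattr(item, "expected", None)
        window = getattr(item, "response_window", DEFAULT_RESPONSE_WINDOW_S)
    if target is None:
        return {"correct": None, "scoreable": False}
    in_time = response_time is None or response_time <= window
    correct = in_time and normalize_response(response) == normalize_response(target)
    return {"correct": bool(correct), "scoreable": True}


def percent_correct(results: Sequence[CognitiveResult]) -> float:
    """Percent of scoreable items answered correctly; NaN when none are.

    Open-ended (unscoreable) items are excluded from both numerator and
    denominator.
    """
    scoreable = [r for r in results if r.scoreable]
    if not scoreable:
        return math.nan
    n_correct = sum(1 for r in scoreable if r.correct)
    return 100.0 * n_correct / len(scoreable)
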