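"""Shared tokenizer.

A single tokenizer is used for cohort word counts, embedding input and term
extraction, so that the 100-word documentation threshold, the embedding
vocabulary and the top-1000 term ranking all count the same units.
"""

from __future__ import annotations

import re

# Strip punctuation, keep letters and numerals; underscores survive so that
# synthetic vocabulary tokens like "w00042" or "agitated_s2" stay whole.
_NON_TOKEN = re.compile(r"[^\w\s]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace.

    Numerals are kept. Returns an empty list for empty/whitespace input.
    """
    if not text:
        return []
    return _NON_TOKEN.sub(" ", text.lower()).split()


def word_count(text: str) -> int:
    return len(tokenize(text))
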