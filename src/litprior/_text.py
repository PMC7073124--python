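"""Whole-word phrase matching shared by the validator and the offline searcher."""

from __future__ import annotations

import re
from functools import lru_cache


@lru_cache(maxsize=4096)
def _phrase_pattern(phrase: str) -> re.Pattern[str]:
    # Word-boundary guards prevent substring artifacts (synonym "CAT" must not
    # match inside "catalytic"). Interior whitespace is collapsed so that
    # multiword phrases match across normalized spacing.
    words = [re.escape(w) for w in phrase.split()]
    body = r"\s+".join(words)
    return re.compile(r"(?<![A-Za-z0-9])" + body + r"(?![A-Za-z0-9])", re.IGNORECASE)


def phrase_in_text(phrase: str, text: str) -> bool:
    """Case-insensitive whole-word/phrase containment test."""
    if not phrase or not text:
        return False
    return bool(_phrase_pattern(phrase.strip()).search(text))
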