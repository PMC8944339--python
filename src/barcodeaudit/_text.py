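"""Name normalization and edit distance for gazetteer matching.

Free-text locality strings are matched against canonical administrative-unit
names after aggressive normalization (case folding, diacritic stripping,
punctuation removal).  Misspellings are detected with a restricted
Damerau-Levenshtein distance (optimal string alignment), which treats a
transposition of two adjacent characters as a single edit -- the most common
typo class in hand-entered place names.
"""

from __future__ import annotations

import re
import unicodedata

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_name(s: str) -> str:
    """Case-fold, strip diacritics and punctuation, collapse whitespace."""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = _PUNCT.sub(" ", s.casefold())
    return _WS.sub(" ", s).strip()


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (OSA) distance between two strings."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def edit_threshold(name: str) -> int:
    """Maximum edit distance at which a token may match ``name``.

    Short names tolerate a single edit; longer ones two.
    """
    return 1 if len(name) <= 8 else 2


def within_threshold(token: str, name: str) -> bool:
    return damerau_levenshtein(token, name) <= edit_threshold(name)
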