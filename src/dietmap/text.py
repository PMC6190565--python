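"""Text normalization and string similarity for food-name matching.

Normalization lowercases, maps punctuation (slashes, hyphens, parentheses,
commas, ...) to spaces and splits on whitespace; an optional stopword set is
removed. Similarity is a length-normalized Levenshtein measure on the
normalized strings, the standard fuzzy-matching primitive for short labels.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import edlib

_PUNCT = re.compile(r"[^\w\s]|_", re.UNICODE)
_DIGIT_OK = True  # digits are kept: catalogue names may carry pack sizes


def normalize_text(s: str, stopwords: Iterable[str] = ()) -> list[str]:
    """Lowercase, strip punctuation, split into tokens, drop stopwords.

    >>> normalize_text("Full fat cheese/yogurt/fromage frais")
    ['full', 'fat', 'cheese', 'yogurt', 'fromage', 'frais']
    """
    stop = set(stopwords)
    cleaned = _PUNCT.sub(" ", s.lower())
    return [t for t in cleaned.split() if t not in stop]


def normalize_join(s: str, stopwords: Iterable[str] = ()) -> str:
    """Normalized tokens joined with single spaces."""
    return " ".join(normalize_text(s, stopwords))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute) via edlib."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def similarity(a: str, b: str, stopwords: Iterable[str] = ()) -> float:
    """Normalized-string similarity in [0, 1].

    ``1 - d(norm(a), norm(b)) / max(len(norm(a)), len(norm(b)))`` where d is
    the Levenshtein distance. Two empty strings are defined to be identical
    (similarity 1.0). Symmetric; equals 1 iff the normalized forms coincide.
    """
    na, nb = normalize_join(a, stopwords), normalize_join(b, stopwords)
    if not na and not nb:
        return 1.0
    longest = max(len(na), len(nb))
    return 1.0 - levenshtein(na, nb) / longest


def tokens_of(phrases: Sequence[str]) -> set[str]:
    """Union of tokens across a list of normalized phrases."""
    out: set[str] = set()
    for p in phrases:
        out.update(p.split())
    return out
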