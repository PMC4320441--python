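"""Word overlap between conserved-domain descriptions and GO term names.

A gene passes the filter when the free-text descriptions of its *changed*
domains share at least one non-stopword token with one of the gene's GO term
names.  Tokens are lowercase alphanumeric runs; stopwords (conjunctions,
prepositions, articles by default) and single-character tokens are dropped.
No stemming is applied — "ions" and "ion" are different tokens.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import FrozenSet, Iterable, Optional, Set, Tuple

_TOKEN_RE = re.compile(r"[^0-9a-z]+")

_DEFAULT_STOPWORDS: Optional[FrozenSet[str]] = None


def load_stopwords(path=None) -> FrozenSet[str]:
    """Load a stopword list (one token per line, ``#`` comments allowed).

    Without a path, the packaged default list (conjunctions, prepositions,
    articles) is returned and cached.
    """
    global _DEFAULT_STOPWORDS
    if path is None:
        if _DEFAULT_STOPWORDS is None:
            text = (
                resources.files("spliceimpact.data")
                .joinpath("stopwords.txt")
                .read_text()
            )
            _DEFAULT_STOPWORDS = _parse_stopwords(text)
        return _DEFAULT_STOPWORDS
    with open(path) as fh:
        return _parse_stopwords(fh.read())


def _parse_stopwords(text: str) -> FrozenSet[str]:
    words = set()
    for line in text.splitlines():
        word = line.strip().lower()
        if word and not word.startswith("#"):
            words.add(word)
    return frozenset(words)


def tokenize(text: str, stopwords: Optional[FrozenSet[str]] = None) -> Set[str]:
    """Lowercase, split on non-alphanumerics, drop stopwords and 1-char tokens."""
    stopwords = load_stopwords() if stopwords is None else stopwords
    tokens = _TOKEN_RE.split(text.lower())
    return {t for t in tokens if len(t) > 1 and t not in stopwords}


def overlap_filter(
    domain_descriptions: Iterable[str],
    go_terms: Iterable[str],
    stopwords: Optional[FrozenSet[str]] = None,
) -> Tuple[Set[str], bool]:
    """Shared tokens between changed-domain descriptions and GO term names.

    Returns ``(shared_tokens, passes)``; passes is True iff the intersection
    is non-empty.  Callers supply only descriptions of domains whose status is
    not intact.
    """
    stopwords = load_stopwords() if stopwords is None else stopwords
    desc_tokens: Set[str] = set()
    for d in domain_descriptions:
        desc_tokens |= tokenize(d, stopwords)
    go_tokens: Set[str] = set()
    for t in go_terms:
        go_tokens |= tokenize(t, stopwords)
    shared = desc_tokens & go_tokens
    return shared, bool(shared)
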