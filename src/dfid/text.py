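"""Shared tokenization helpers.

Dosage-form names and monograph sentences are tokenized identically:
lowercase, hyphens and slashes treated as separators (so
"extended-release" yields the same tokens as "Extended Release"), other
punctuation stripped, split on whitespace.
"""

from __future__ import annotations

import re

_SEPARATORS = re.compile(r"[-–—/]+")
_STRIP = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens of *text*; empty list for blank input."""
    lowered = _SEPARATORS.sub(" ", text.lower())
    return _STRIP.sub("", lowered).split()


def first_token(text: str) -> str | None:
    """First word token of *text*, or None if there is none."""
    tokens = tokenize(text)
    return tokens[0] if tokens else None
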