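"""Word stemming for dosage-form matching.

Dosage-form names and evidence sentences are both reduced to bags of word
stems before matching, so that surface variation ("solution" vs.
"solutions", "coated" vs. "coating") does not block a lookup.  The default
algorithm is the classic Porter (1980) suffix-stripping stemmer, which maps
e.g. ``solution -> solut`` and ``tablets -> tablet``.  Any callable
``str -> str`` can be substituted; matching only requires that concept
names and sentences pass through the same function.
"""

from __future__ import annotations

from typing import Callable

Stemmer = Callable[[str], str]

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC (vowel-sequence, consonant-sequence) pairs in *stem*."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """Strip *suffix* and append *repl* when the stem's measure exceeds the
    threshold; return None when the rule does not fire."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + repl
    return word  # suffix matched but condition failed: rule consumed


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem = word[:-3]
        return stem + "ee" if _measure(stem) > 0 else word
    if word.endswith("ed"):
        stem = word[:-2]
        if not _has_vowel(stem):
            return word
        word = stem
    elif word.endswith("ing"):
        stem = word[:-3]
        if not _has_vowel(stem):
            return word
        word = stem
    else:
        return word
    # cleanup after removing -ed / -ing
    if word.endswith(("at", "bl", "iz")):
        return word + "e"
    if _ends_double_consonant(word) and word[-1] not in "lsz":
        return word[:-1]
    if _measure(word) == 1 and _ends_cvc(word):
        return word + "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _has_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2_RULES = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3_RULES = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4_SUFFIXES = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _step2(word: str) -> str:
    for suffix, repl in _STEP2_RULES:
        out = _replace(word, suffix, repl, 0)
        if out is not None:
            return out
    return word


def _step3(word: str) -> str:
    for suffix, repl in _STEP3_RULES:
        out = _replace(word, suffix, repl, 0)
        if out is not None:
            return out
    return word


def _step4(word: str) -> str:
    for suffix in _STEP4_SUFFIXES:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                continue
            if _measure(stem) > 1:
                return stem
            return word
    return word


def _step5(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            word = stem
    if word.endswith("ll") and _measure(word) > 1:
        word = word[:-1]
    return word


def porter_stem(word: str) -> str:
    """Stem a single lowercase word with the Porter (1980) algorithm.

    Words of length <= 2 are returned unchanged, per the original
    algorithm's convention.
    """
    word = word.lower()
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _step2(word)
    word = _step3(word)
    word = _step4(word)
    word = _step5(word)
    return word


def identity_stem(word: str) -> str:
    """No-op stemmer (lowercases only); used by the baseline lookup."""
    return word.lower()


_STEMMERS: dict[str, Stemmer] = {
    "porter": porter_stem,
    "identity": identity_stem,
}


def get_stemmer(name: str = "porter") -> Stemmer:
    try:
        return _STEMMERS[name]
    except KeyError:
        raise ValueError(
            f"unknown stemmer {name!r}; choose from {sorted(_STEMMERS)}"
        ) from None
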