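"""Suffix-stripping stemmer used to conflate inflectional variants of report terms.

Implements the Porter (1980) algorithm with one domain-motivated extension:
a Greek-plural pre-rule rewriting a terminal ``-sis`` to ``-ses`` before
step 1a, so that singular/plural pairs ubiquitous in radiology vocabulary
("metastasis"/"metastases", "stenosis"/"stenoses", "diagnosis"/"diagnoses")
reduce to one stem. Plain Porter leaves such pairs distinct, which would
split the document-frequency mass of a single clinical concept across two
table rows.

The stemmer is deterministic and pure: equal inputs always give equal
outputs. Inputs are expected to be lowercase alphabetic tokens.
"""

from __future__ import annotations

from functools import lru_cache

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a vowel when preceded by a consonant ("happy"), else consonant
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Porter's m: the number of vowel→consonant transitions in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_cons(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) pairs; within a step the longest matching suffix wins
# and no further rule of that step is tried, per the original algorithm.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)
_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)
_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _longest_rule(word: str, rules) -> tuple[str, str] | None:
    best = None
    for suf, rep in rules:
        if word.endswith(suf) and (best is None or len(suf) > len(best[0])):
            best = (suf, rep)
    return best


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
        return word[:-1] if _measure(stem) > 0 else word
    fired = False
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        word, fired = word[:-2], True
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        word, fired = word[:-3], True
    if fired:
        if word.endswith(("at", "bl", "iz")):
            return word + "e"
        if _ends_double_cons(word) and word[-1] not in "lsz":
            return word[:-1]
        if _measure(word) == 1 and _ends_cvc(word):
            return word + "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


def _step2(word: str) -> str:
    rule = _longest_rule(word, _STEP2)
    if rule is not None:
        suf, rep = rule
        stem = word[: len(word) - len(suf)]
        if _measure(stem) > 0:
            return stem + rep
    return word


def _step3(word: str) -> str:
    rule = _longest_rule(word, _STEP3)
    if rule is not None:
        suf, rep = rule
        stem = word[: len(word) - len(suf)]
        if _measure(stem) > 0:
            return stem + rep
    return word


def _step4(word: str) -> str:
    rule = _longest_rule(word, [(s, "") for s in _STEP4])
    if rule is not None:
        suf, _ = rule
        stem = word[: len(word) - len(suf)]
        if _measure(stem) > 1:
            if suf == "ion" and not stem.endswith(("s", "t")):
                return word
            return stem
    return word


def _step5(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            word = stem
    if _ends_double_cons(word) and word.endswith("l") and _measure(word[:-1]) > 1:
        word = word[:-1]
    return word


@lru_cache(maxsize=65536)
def stem(token: str) -> str:
    """Reduce a lowercase alphabetic token to its stem.

    Tokens of length <= 2 are returned unchanged, per the original algorithm.
    """
    if len(token) <= 2:
        return token
    if token.endswith("sis") and len(token) > 4:
        token = token[:-3] + "ses"  # Greek plural: stenosis -> stenoses
    word = _step1a(token)
    word = _step1b(word)
    word = _step1c(word)
    word = _step2(word)
    word = _step3(word)
    word = _step4(word)
    word = _step5(word)
    return word
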