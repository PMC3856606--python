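"""Panel-label alphabets shared by the caption and in-image analyzers.

A panel label is a single Latin letter, a Roman numeral up to XII, or an
integer 1-20. Each label has a 1-based *position* in its alphabet, e.g.
``position('b') == 2`` and ``position('D') == 4``; positions drive sequence
ordering, gap counting, and range expansion.
"""

from __future__ import annotations

__all__ = [
    "ALPHABET_PRIORITY",
    "label_position",
    "parse_label",
    "label_at_position",
    "roman_to_int",
    "int_to_roman",
]

#: Priority order used whenever label groups from different alphabets compete.
ALPHABET_PRIORITY: tuple[str, ...] = ("latin", "roman", "arabic")

_ROMAN_MAX = 12
_ARABIC_MAX = 20

_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10}

_ROMANS = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
]


def roman_to_int(s: str) -> int | None:
    """Value of a Roman numeral written with I, V, X; None if malformed
    or above the supported bound (XII)."""
    s = s.upper()
    if not s or any(c not in _ROMAN_VALUES for c in s):
        return None
    total = 0
    for i, c in enumerate(s):
        v = _ROMAN_VALUES[c]
        if i + 1 < len(s) and _ROMAN_VALUES[s[i + 1]] > v:
            total -= v
        else:
            total += v
    if not (1 <= total <= _ROMAN_MAX) or _ROMANS[total - 1] != s:
        return None
    return total


def int_to_roman(n: int) -> str:
    if not 1 <= n <= _ROMAN_MAX:
        raise ValueError(f"roman numerals supported only up to {_ROMAN_MAX}, got {n}")
    return _ROMANS[n - 1]


def parse_label(text: str) -> tuple[str, int, str] | None:
    """Parse a bare label string into ``(alphabet, position, canonical)``.

    Canonical form is uppercase for Latin and Roman labels. Strings that
    could be either a Latin letter or a Roman numeral (``I``, ``V``, ``X``,
    lone single characters) parse as Latin; callers wanting the Roman
    reading use :func:`roman_to_int` directly.
    """
    if not text:
        return None
    if len(text) == 1 and text.isalpha() and text.isascii():
        c = text.upper()
        return ("latin", ord(c) - ord("A") + 1, c)
    r = roman_to_int(text)
    if r is not None:
        return ("roman", r, text.upper())
    if text.isdigit():
        n = int(text)
        if 1 <= n <= _ARABIC_MAX:
            return ("arabic", n, str(n))
    return None


def label_position(char: str, alphabet: str = "latin") -> int:
    """1-based alphabetical/numeric rank of a label character.

    >>> label_position('b'), label_position('D')
    (2, 4)
    """
    if alphabet == "latin":
        if len(char) != 1 or not char.isalpha():
            raise ValueError(f"not a latin label: {char!r}")
        return ord(char.upper()) - ord("A") + 1
    if alphabet == "roman":
        v = roman_to_int(char)
        if v is None:
            raise ValueError(f"not a roman label: {char!r}")
        return v
    if alphabet == "arabic":
        return int(char)
    raise ValueError(f"unknown alphabet: {alphabet}")


def label_at_position(alphabet: str, position: int) -> str:
    """Canonical label character at a 1-based position of an alphabet."""
    if position < 1:
        raise ValueError("positions are 1-based")
    if alphabet == "latin":
        if position > 26:
            raise ValueError("latin labels end at Z")
        return chr(ord("A") + position - 1)
    if alphabet == "roman":
        return int_to_roman(position)
    if alphabet == "arabic":
        return str(position)
    raise ValueError(f"unknown alphabet: {alphabet}")
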