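"""Caption lexing, panel-label filtering, and subcaption splitting.

A figure caption such as ``"Figure 1. (A) Gel. (B-D) Blots."`` is scanned
for panel-label tokens (parenthesized singles, parenthesized ranges, and
bare forms like ``"A."``), false positives are removed by a sequence
filter, and the caption is split at the surviving tokens into one
subcaption per panel, duplicating range-token text across its labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from figseg.labels import (
    ALPHABET_PRIORITY,
    label_at_position,
    parse_label,
    roman_to_int,
)

__all__ = [
    "LabelToken",
    "AcceptedLabel",
    "SubCaption",
    "CaptionResult",
    "lex_caption_labels",
    "filter_label_candidates",
    "split_subcaptions",
    "segment_caption",
    "NO_LABEL",
]

#: Label assigned to the single subcaption of an unlabeled caption.
NO_LABEL = "∅"

_FIG_CUE = re.compile(r"(?:fig\.?|figure)\s*$", re.IGNORECASE)

# A label atom: one Latin letter, a multi-char Roman numeral, or 1-2 digits.
_ATOM = r"(?:[A-Za-z]|[IVXivx]{2,4}|\d{1,2})"

_RANGE_SEP = r"(?:\s*[-–—]\s*|\s+to\s+)"

_PAT_RANGE_DASH = re.compile(rf"\(\s*({_ATOM}){_RANGE_SEP}({_ATOM})\s*\)")
_PAT_LIST = re.compile(
    rf"\(\s*({_ATOM}(?:\s*,\s*{_ATOM})*(?:\s*,?\s*and\s+{_ATOM})?)\s*\)"
)
_PAT_SINGLE = re.compile(rf"\(\s*({_ATOM})\s*\)")
_PAT_BARE = re.compile(rf"({_ATOM})([.\),;])")


@dataclass(frozen=True)
class LabelToken:
    """A panel-label mention found in the caption text."""

    surface: str
    span: tuple[int, int]
    style: str  # paren_single | paren_range | bare
    labels: tuple[str, ...]  # canonical label characters, ordered
    alphabet: str  # latin | roman | arabic

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError("empty token span")
        if not self.labels:
            raise ValueError("token without labels")


@dataclass(frozen=True)
class AcceptedLabel:
    """One accepted panel label, pointing back at its source token."""

    label: str
    alphabet: str
    position: int
    token: LabelToken


@dataclass(frozen=True)
class SubCaption:
    """Caption fragment assigned to one panel.

    ``text`` is the stripped fragment; ``shared`` marks fragments
    duplicated from a range token across several labels.
    """

    label: str
    text: str
    shared: bool = False


@dataclass
class CaptionResult:
    """Full output of caption segmentation for one caption."""

    caption: str
    preamble: str
    tokens: list[LabelToken]
    accepted: list[AcceptedLabel]
    subcaptions: list[SubCaption]
    #: raw text segments following each accepted token, in span order,
    #: one per distinct accepted token (unstripped; for reconstruction).
    segments: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [sc.label for sc in self.subcaptions if sc.label != NO_LABEL]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "subcaptions": [
                {"label": sc.label, "text": sc.text, "shared": sc.shared}
                for sc in self.subcaptions
            ],
        }


def _alphabet_of_parts(parts: list[str]) -> tuple[str, list[int]] | None:
    """Find one alphabet in which every part parses, preferring
    latin > roman > arabic; returns (alphabet, positions)."""
    for alphabet in ALPHABET_PRIORITY:
        positions = []
        for p in parts:
            pos = _parse_in(p, alphabet)
            if pos is None:
                break
            positions.append(pos)
        else:
            return alphabet, positions
    return None


def _parse_in(text: str, alphabet: str) -> int | None:
    if alphabet == "latin":
        if len(text) == 1 and text.isalpha() and text.isascii():
            return ord(text.upper()) - ord("A") + 1
        return None
    if alphabet == "roman":
        return roman_to_int(text)
    if alphabet == "arabic":
        if text.isdigit() and 1 <= int(text) <= 20:
            return int(text)
        return None
    return None


def _range_token(m: re.Match, a: str, b: str) -> LabelToken | None:
    for alphabet in ALPHABET_PRIORITY:
        pa, pb = _parse_in(a, alphabet), _parse_in(b, alphabet)
        if pa is not None and pb is not None and pa < pb:
            labels = tuple(label_at_position(alphabet, p) for p in range(pa, pb + 1))
            return LabelToken(m.group(0), m.span(), "paren_range", labels, alphabet)
    return None


def _list_token(m: re.Match) -> LabelToken | None:
    inner = m.group(1)
    parts = [p for p in re.split(r"[,\s]+", inner) if p and p.lower() != "and"]
    if len(parts) < 2:
        return None
    got = _alphabet_of_parts(parts)
    if got is None:
        return None
    alphabet, positions = got
    labels = tuple(label_at_position(alphabet, p) for p in positions)
    return LabelToken(m.group(0), m.span(), "paren_range", labels, alphabet)


def _single_token(m: re.Match) -> LabelToken | None:
    parsed = parse_label(m.group(1))
    if parsed is None:
        return None
    alphabet, pos, canon = parsed
    return LabelToken(m.group(0), m.span(), "paren_single", (canon,), alphabet)


def _bare_token(m: re.Match, text: str) -> LabelToken | None:
    start = m.start()
    if start > 0 and (text[start - 1].isalnum() or text[start - 1] in ".-"):
        return None  # inside a word or abbreviation
    parsed = parse_label(m.group(1))
    if parsed is None:
        return None
    alphabet, pos, canon = parsed
    # A bare number right after a figure cue is the figure number.
    if alphabet == "arabic" and _FIG_CUE.search(text, 0, start):
        return None
    return LabelToken(m.group(0), m.span(), "bare", (canon,), alphabet)


def lex_caption_labels(text: str) -> list[LabelToken]:
    """Scan a caption for panel-label tokens.

    Recognizes parenthesized singles ``(A)``, ranges ``(A-C)``, ``(i to iv)``,
    comma lists ``(I, II, and III)``, and bare forms ``A.``, ``b)``, ``C,``,
    ``d;``. Tokens are returned in span order; overlaps are resolved in
    favor of the earliest-starting, then longest, match.
    """
    candidates: list[tuple[int, int, int, LabelToken]] = []

    def add(tok: LabelToken | None, priority: int) -> None:
        if tok is not None:
            candidates.append((tok.span[0], -len(tok.surface), priority, tok))

    for m in _PAT_RANGE_DASH.finditer(text):
        add(_range_token(m, m.group(1), m.group(2)), 0)
    for m in _PAT_LIST.finditer(text):
        add(_list_token(m), 1)
    for m in _PAT_SINGLE.finditer(text):
        add(_single_token(m), 2)
    for m in _PAT_BARE.finditer(text):
        add(_bare_token(m, text), 3)

    candidates.sort()
    tokens: list[LabelToken] = []
    last_end = -1
    for _, _, _, tok in candidates:
        if tok.span[0] >= last_end:
            tokens.append(tok)
            last_end = tok.span[1]

    return _resolve_roman_i(tokens)


def _resolve_roman_i(tokens: list[LabelToken]) -> list[LabelToken]:
    """Reinterpret single-character I/V/X tokens as Roman numerals when the
    caption contains an unambiguous multi-character Roman token; otherwise
    they stay Latin (guards against the English pronoun "I")."""
    has_multichar_roman = any(
        t.alphabet == "roman" and any(len(lb) > 1 for lb in t.labels) for t in tokens
    )
    if not has_multichar_roman:
        return tokens
    out = []
    for t in tokens:
        if t.alphabet == "latin" and all(lb in "IVX" for lb in t.labels):
            out.append(
                LabelToken(t.surface, t.span, t.style, t.labels, "roman")
            )
        else:
            out.append(t)
    return out


def _lis_earliest(positions: list[int]) -> list[int]:
    """Indices of the longest strictly-increasing subsequence, with ties
    broken by earliest start (then earliest subsequent elements)."""
    n = len(positions)
    if n == 0:
        return []
    f = [1] * n  # longest increasing subsequence starting at i
    for i in range(n - 2, -1, -1):
        best = 0
        for j in range(i + 1, n):
            if positions[j] > positions[i] and f[j] > best:
                best = f[j]
        f[i] = best + 1
    need = max(f)
    chosen: list[int] = []
    last = float("-inf")
    for i in range(n):
        if need == 0:
            break
        if f[i] == need and positions[i] > last:
            chosen.append(i)
            last = positions[i]
            need -= 1
    return chosen


def filter_label_candidates(tokens: list[LabelToken]) -> list[AcceptedLabel]:
    """Remove false-positive labels and return the accepted sequence.

    Labels are clustered by alphabet; within a cluster, repeated labels
    keep only their first occurrence and the longest strictly-increasing
    subsequence of positions (earliest start on ties) survives. Among the
    surviving alphabets, latin > roman > arabic.
    """
    entries: dict[str, list[AcceptedLabel]] = {}
    for tok in tokens:
        for lb in tok.labels:
            pos = _parse_in(lb, tok.alphabet)
            if pos is None:  # pragma: no cover - lexer guarantees parseability
                continue
            entries.setdefault(tok.alphabet, []).append(
                AcceptedLabel(lb, tok.alphabet, pos, tok)
            )

    best: list[AcceptedLabel] = []
    for alphabet in ALPHABET_PRIORITY:
        cluster = entries.get(alphabet, [])
        if not cluster:
            continue
        seen: set[int] = set()
        dedup = []
        for e in cluster:
            if e.position not in seen:
                seen.add(e.position)
                dedup.append(e)
        keep = _lis_earliest([e.position for e in dedup])
        accepted = [dedup[i] for i in keep]
        if accepted:
            best = accepted
            break
    return best


def split_subcaptions(text: str, accepted: list[AcceptedLabel]) -> CaptionResult:
    """Split the caption at accepted label tokens into subcaptions.

    Each subcaption runs from the end of its token to the start of the next
    accepted token (or the caption end). A range token's following text is
    duplicated once per label with ``shared=True``. Text before the first
    token is kept as figure-level preamble, attached to no panel.
    """
    if not accepted:
        sub = SubCaption(NO_LABEL, text.strip(), False)
        return CaptionResult(text, "", [], [], [sub], segments=[])

    # Group accepted labels by their source token, in span order.
    groups: list[tuple[LabelToken, list[AcceptedLabel]]] = []
    for e in accepted:
        if groups and groups[-1][0] is e.token:
            groups[-1][1].append(e)
        else:
            groups.append((e.token, [e]))
    groups.sort(key=lambda g: g[0].span)

    preamble = text[: groups[0][0].span[0]]
    segments: list[str] = []
    subcaptions: list[SubCaption] = []
    for i, (tok, labels) in enumerate(groups):
        seg_start = tok.span[1]
        seg_end = groups[i + 1][0].span[0] if i + 1 < len(groups) else len(text)
        raw = text[seg_start:seg_end]
        segments.append(raw)
        shared = len(labels) > 1
        for e in labels:
            subcaptions.append(SubCaption(e.label, raw.strip(), shared))

    tokens = [g[0] for g in groups]
    return CaptionResult(text, preamble, tokens, accepted, subcaptions, segments)


def segment_caption(text: str) -> CaptionResult:
    """Lex, filter, and split a caption in one call."""
    tokens = lex_caption_labels(text)
    accepted = filter_label_candidates(tokens)
    return split_subcaptions(text, accepted)
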