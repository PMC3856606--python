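"""Panel-label recovery from OCR tokens extracted from the figure image.

OCR tokens are classified into label candidates (simple ``A``,
right-closed ``B)``, closed ``(C)``), clustered into groups by alphabet
and category, and scored by sequence completeness:
``confidence = 1 / (1 + Gaps * Panels)``, where ``Panels`` is the maximum
label position in the group and ``Gaps`` counts the missing positions.
The highest-confidence group is selected as the in-image label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from figseg.geometry import BBox
from figseg.labels import ALPHABET_PRIORITY, parse_label, roman_to_int

__all__ = [
    "OcrToken",
    "PanelLabelCandidate",
    "LabelGroup",
    "classify_tokens",
    "build_groups",
    "score_and_select",
    "recover_labels",
]

_RIGHT_DELIMS = ")].,;"
_CLOSED_PAIRS = {"(": ")", "[": "]", "{": "}"}


@dataclass(frozen=True)
class OcrToken:
    """One recognized text fragment with its position in figure pixels."""

    text: str
    bbox: BBox
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty OCR token")

    @classmethod
    def from_dict(cls, d: dict) -> "OcrToken":
        return cls(d["text"], BBox.from_list(d["bbox"]), d.get("conf"))

    def to_dict(self) -> dict:
        d = {"text": self.text, "bbox": self.bbox.to_list()}
        if self.confidence is not None:
            d["conf"] = self.confidence
        return d


@dataclass(frozen=True)
class PanelLabelCandidate:
    char: str  # canonical label character
    alphabet: str
    category: str  # simple | right_closed | closed
    bbox: BBox
    position: int  # 1-based rank, e.g. position('b') == 2

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class LabelGroup:
    """Candidates of one (alphabet, category) combination, as a sequence."""

    alphabet: str
    category: str
    members: list[PanelLabelCandidate] = field(default_factory=list)

    @property
    def panels(self) -> int:
        """Total panels implied by the group: the maximum label position."""
        return max(m.position for m in self.members) if self.members else 0

    @property
    def gaps(self) -> int:
        """Missing positions in 1..panels."""
        return self.panels - len({m.position for m in self.members})

    @property
    def confidence(self) -> float:
        return 1.0 / (1.0 + self.gaps * self.panels)

    def to_dict(self) -> dict:
        return {
            "labels": [
                {"char": m.char, "bbox": m.bbox.to_list()} for m in self.members
            ],
            "Panels": self.panels,
            "Gaps": self.gaps,
            "confidence": self.confidence,
        }


def _parse_label_text(core: str) -> tuple[str, int, str] | None:
    return parse_label(core)


def classify_tokens(tokens: list[OcrToken]) -> list[PanelLabelCandidate]:
    """Classify OCR tokens into panel-label candidates.

    A token yields a candidate iff its text is a lone label character
    (*simple*), a label character followed by one right delimiter such as
    ``)``, ``]``, ``.``, ``,`` or ``;`` (*right_closed*), or a label
    character surrounded by matching delimiters like ``(A)`` or ``[B]``
    (*closed*). Anything longer is ordinary text and ignored.
    """
    cands: list[PanelLabelCandidate] = []
    for tok in tokens:
        text = tok.text.strip()
        if not text:
            continue
        category = None
        core = None
        if (
            len(text) >= 3
            and text[0] in _CLOSED_PAIRS
            and text[-1] == _CLOSED_PAIRS[text[0]]
        ):
            category, core = "closed", text[1:-1]
        elif len(text) >= 2 and text[-1] in _RIGHT_DELIMS:
            category, core = "right_closed", text[:-1]
        else:
            category, core = "simple", text
        parsed = _parse_label_text(core)
        if parsed is None:
            continue
        alphabet, pos, canon = parsed
        cands.append(PanelLabelCandidate(canon, alphabet, category, tok.bbox, pos))
    return _resolve_roman_singles(cands)


def _resolve_roman_singles(
    cands: list[PanelLabelCandidate],
) -> list[PanelLabelCandidate]:
    """Within each category, reinterpret single I/V/X candidates as Roman
    when the category also holds multi-character Roman numerals, so that
    e.g. tokens I, II, III cluster into one group."""
    roman_cats = {
        c.category for c in cands if c.alphabet == "roman" and len(c.char) > 1
    }
    out = []
    for c in cands:
        if c.alphabet == "latin" and c.char in "IVX" and c.category in roman_cats:
            pos = roman_to_int(c.char)
            out.append(
                PanelLabelCandidate(c.char, "roman", c.category, c.bbox, pos)
            )
        else:
            out.append(c)
    return out


def build_groups(cands: list[PanelLabelCandidate]) -> list[LabelGroup]:
    """Cluster candidates into groups of similar type.

    One group per (alphabet, category) combination with at least one
    member; members are sorted by position. Duplicate candidates at the
    same position keep the top-left-most bounding box.
    """
    buckets: dict[tuple[str, str], dict[int, PanelLabelCandidate]] = {}
    for c in cands:
        key = (c.alphabet, c.category)
        slot = buckets.setdefault(key, {})
        prev = slot.get(c.position)
        if prev is None or (c.bbox.y_min, c.bbox.x_min) < (
            prev.bbox.y_min,
            prev.bbox.x_min,
        ):
            slot[c.position] = c
    groups = []
    for (alphabet, category), slot in buckets.items():
        members = [slot[p] for p in sorted(slot)]
        groups.append(LabelGroup(alphabet, category, members))
    return groups


def score_and_select(groups: list[LabelGroup]) -> LabelGroup | None:
    """Select the group with the highest confidence score.

    Ties are broken toward more panels, then by alphabet priority
    (latin > roman > arabic), then by category name for determinism.
    """
    if not groups:
        return None
    return max(
        groups,
        key=lambda g: (
            g.confidence,
            g.panels,
            -ALPHABET_PRIORITY.index(g.alphabet),
            g.category,
        ),
    )


def recover_labels(tokens: list[OcrToken]) -> LabelGroup | None:
    """Classify, cluster, and select in one call."""
    return score_and_select(build_groups(classify_tokens(tokens)))
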