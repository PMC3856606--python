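"""Synthetic multi-panel figures, captions, OCR tokens, and document
operator streams with exact ground truth.

Every stage of the pipeline is testable offline against these fixtures:
figures are grids (optionally ragged) of framed panels separated by
whitespace gutters, each panel carrying a rendered label glyph whose box
doubles as a clean OCR token; captions are emitted in per-label, range,
or unlabeled styles with known subcaption spans; operator streams add
caption paragraphs split across lines, journal logos outside the text
rectangle, in-text figure citations, and fragmented N-to-1 figures.
All generation is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from figseg.caption_seg import SubCaption
from figseg.geometry import BBox, bbox_union
from figseg.harvest import Operator
from figseg.inimage_text import OcrToken
from figseg.labels import label_at_position
from figseg.panel_seg import CountEvidence

__all__ = [
    "FixtureSpec",
    "PanelTruth",
    "GroundTruth",
    "DocTruth",
    "generate_figure",
    "generate_caption",
    "corrupt_ocr",
    "drop_one_token",
    "generate_operator_stream",
    "make_count_corpus",
    "render_text",
    "TILE",
    "MARGIN",
    "GUTTER",
]

TILE = 150  # tile size of one panel cell, pixels
MARGIN = 6  # content inset from the cell border (gutter = 2 * MARGIN)
GUTTER = 2 * MARGIN

INK = 20
PAPER = 250

# 5x7 bitmap glyphs (rows of '#'/'.'), enough for labels A-P, Roman
# numerals built from I/V/X, digits, and the delimiters ()[].,;
_GLYPHS = {
    "A": [".##.", "#..#", "#..#", "####", "#..#", "#..#", "#..#"],
    "B": ["###.", "#..#", "###.", "#..#", "#..#", "#..#", "###."],
    "C": [".###", "#...", "#...", "#...", "#...", "#...", ".###"],
    "D": ["###.", "#..#", "#..#", "#..#", "#..#", "#..#", "###."],
    "E": ["####", "#...", "###.", "#...", "#...", "#...", "####"],
    "F": ["####", "#...", "###.", "#...", "#...", "#...", "#..."],
    "G": [".###", "#...", "#...", "#.##", "#..#", "#..#", ".###"],
    "H": ["#..#", "#..#", "####", "#..#", "#..#", "#..#", "#..#"],
    "I": ["###", ".#.", ".#.", ".#.", ".#.", ".#.", "###"],
    "J": ["..##", "...#", "...#", "...#", "#..#", "#..#", ".##."],
    "K": ["#..#", "#.#.", "##..", "#.#.", "#..#", "#..#", "#..#"],
    "L": ["#...", "#...", "#...", "#...", "#...", "#...", "####"],
    "M": ["#...#", "##.##", "#.#.#", "#...#", "#...#", "#...#", "#...#"],
    "N": ["#..#", "##.#", "#.##", "#..#", "#..#", "#..#", "#..#"],
    "O": [".##.", "#..#", "#..#", "#..#", "#..#", "#..#", ".##."],
    "P": ["###.", "#..#", "#..#", "###.", "#...", "#...", "#..."],
    "V": ["#...#", "#...#", "#...#", ".#.#.", ".#.#.", "..#..", "..#.."],
    "X": ["#...#", ".#.#.", "..#..", "..#..", "..#..", ".#.#.", "#...#"],
    "0": [".##.", "#..#", "#..#", "#..#", "#..#", "#..#", ".##."],
    "1": [".#.", "##.", ".#.", ".#.", ".#.", ".#.", "###"],
    "2": [".##.", "#..#", "...#", "..#.", ".#..", "#...", "####"],
    "3": ["###.", "...#", ".##.", "...#", "...#", "#..#", ".##."],
    "4": ["#..#", "#..#", "####", "...#", "...#", "...#", "...#"],
    "5": ["####", "#...", "###.", "...#", "...#", "#..#", ".##."],
    "6": [".###", "#...", "###.", "#..#", "#..#", "#..#", ".##."],
    "7": ["####", "...#", "..#.", "..#.", ".#..", ".#..", ".#.."],
    "8": [".##.", "#..#", ".##.", "#..#", "#..#", "#..#", ".##."],
    "9": [".##.", "#..#", "#..#", ".###", "...#", "...#", "##.."],
    "(": ["..#", ".#.", "#..", "#..", "#..", ".#.", "..#"],
    ")": ["#..", ".#.", "..#", "..#", "..#", ".#.", "#.."],
    "[": ["##", "#.", "#.", "#.", "#.", "#.", "##"],
    "]": ["##", ".#", ".#", ".#", ".#", ".#", "##"],
    ".": ["..", "..", "..", "..", "..", "##", "##"],
    ",": ["..", "..", "..", "..", ".#", ".#", "#."],
    ";": [".#", ".#", "..", "..", ".#", ".#", "#."],
}


def render_text(
    canvas: np.ndarray, text: str, x: int, y: int, scale: int = 2
) -> BBox:
    """Draw ``text`` with the bitmap font at (x, y); returns the string box."""
    cx = x
    height = 7 * scale
    for ch in text:
        glyph = _GLYPHS.get(ch.upper())
        if glyph is None:
            raise KeyError(f"no glyph for {ch!r}")
        gw = len(glyph[0])
        for r, row in enumerate(glyph):
            for c, bit in enumerate(row):
                if bit == "#":
                    canvas[
                        y + r * scale : y + (r + 1) * scale,
                        cx + c * scale : cx + (c + 1) * scale,
                    ] = INK
        cx += (gw + 1) * scale
    return BBox(x, y, cx - scale, y + height)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic figure fixture."""

    rows: int = 2
    cols: int = 2
    ragged: tuple[int, ...] | None = None  # panels per row; overrides cols
    label_alphabet: str = "latin"  # latin | roman | arabic
    label_category: str = "closed"  # simple | right_closed | closed
    caption_style: str = "per_label"  # per_label | range | none
    content_kind: str = "blob"  # blob | bars | texture
    ocr_drop_rate: float = 0.0
    ocr_confusion_rate: float = 0.0
    caption_label_corruption: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        shape = self.ragged if self.ragged else (self.cols,) * self.rows
        if sum(shape) > 16:
            raise ValueError("at most 16 panels")
        if not all(1 <= k <= 4 for k in shape):
            raise ValueError("1-4 panels per row")
        for rate in (self.ocr_drop_rate, self.ocr_confusion_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def row_shape(self) -> tuple[int, ...]:
        return self.ragged if self.ragged else (self.cols,) * self.rows

    @property
    def n_panels(self) -> int:
        return sum(self.row_shape)


@dataclass
class PanelTruth:
    label: str
    region: BBox  # the tile region the panel owns after cutting
    content_bbox: BBox  # box of the panel's drawn content
    token: OcrToken  # clean OCR token for the rendered label glyph


@dataclass
class GroundTruth:
    spec: FixtureSpec
    panels: list[PanelTruth]
    caption: str = ""
    subcaptions: list[SubCaption] = field(default_factory=list)
    decoy_span: tuple[int, int] | None = None

    @property
    def n_panels(self) -> int:
        return len(self.panels)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.panels]

    @property
    def tokens(self) -> list[OcrToken]:
        return [p.token for p in self.panels]


def _label_text(label: str, category: str) -> str:
    if category == "simple":
        return label
    if category == "right_closed":
        return label + ")"
    if category == "closed":
        return f"({label})"
    raise ValueError(f"unknown label category {category!r}")


def _draw_content(
    canvas: np.ndarray, box: BBox, kind: str, rng: np.random.Generator
) -> None:
    """Draw a 3 px frame on the content box plus kind-specific interior
    marks; all marks stay inside the frame so component boxes merge."""
    t = 3
    canvas[box.y_min : box.y_min + t, box.x_min : box.x_max] = INK
    canvas[box.y_max - t : box.y_max, box.x_min : box.x_max] = INK
    canvas[box.y_min : box.y_max, box.x_min : box.x_min + t] = INK
    canvas[box.y_min : box.y_max, box.x_max - t : box.x_max] = INK

    ix0, iy0 = box.x_min + 26, box.y_min + 30
    ix1, iy1 = box.x_max - 10, box.y_max - 10
    if ix1 - ix0 < 12 or iy1 - iy0 < 12:
        return
    if kind == "blob":
        cx, cy = (ix0 + ix1) // 2, (iy0 + iy1) // 2
        ry, rx = (iy1 - iy0) // 3, (ix1 - ix0) // 3
        yy, xx = np.ogrid[iy0:iy1, ix0:ix1]
        mask = ((xx - cx) / max(rx, 1)) ** 2 + ((yy - cy) / max(ry, 1)) ** 2 <= 1.0
        canvas[iy0:iy1, ix0:ix1][mask] = INK
    elif kind == "bars":
        n = int(rng.integers(3, 6))
        bw = max(4, (ix1 - ix0) // (2 * n))
        for k in range(n):
            x = ix0 + k * 2 * bw
            top = iy0 + int(rng.integers(0, max(1, (iy1 - iy0) // 2)))
            canvas[top:iy1, x : min(x + bw, ix1)] = INK
    elif kind == "texture":
        yy, xx = np.mgrid[iy0:iy1, ix0:ix1]
        canvas[iy0:iy1, ix0:ix1][((yy // 6) + (xx // 6)) % 2 == 0] = INK
    else:
        raise ValueError(f"unknown content kind {kind!r}")


def generate_figure(spec: FixtureSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the fixture image and its ground truth.

    Panels sit in TILE-sized cells with whitespace gutters of
    ``2 * MARGIN`` pixels; each panel's content is a framed box whose
    bounding box is exactly the cell inset by MARGIN, so the expected cut
    between adjacent panels lands on the content edge nearest the label
    anchors (labels render at the top-left of each panel).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.row_shape
    n_cols = max(shape)
    width, height = n_cols * TILE, len(shape) * TILE
    canvas = np.full((height, width), PAPER, dtype=np.uint8)

    row_cuts = [(r + 1) * TILE - MARGIN for r in range(len(shape) - 1)]
    panels: list[PanelTruth] = []
    pos = 0
    for r, k in enumerate(shape):
        pw = width // k
        col_cuts = [(c + 1) * pw - MARGIN for c in range(k - 1)]
        y0, y1 = r * TILE + MARGIN, (r + 1) * TILE - MARGIN
        ry0 = 0 if r == 0 else row_cuts[r - 1]
        ry1 = height if r == len(shape) - 1 else row_cuts[r]
        for c in range(k):
            pos += 1
            label = label_at_position(spec.label_alphabet, pos)
            x0 = c * pw + MARGIN
            x1 = (c + 1) * pw - MARGIN if c < k - 1 else width - MARGIN
            content = BBox(x0, y0, x1, y1)
            _draw_content(canvas, content, spec.content_kind, rng)
            tb = render_text(
                canvas, _label_text(label, spec.label_category), x0 + 8, y0 + 8
            )
            token = OcrToken(_label_text(label, spec.label_category), tb)
            rx0 = 0 if c == 0 else col_cuts[c - 1]
            rx1 = width if c == k - 1 else col_cuts[c]
            panels.append(
                PanelTruth(label, BBox(rx0, ry0, rx1, ry1), content, token)
            )

    truth = GroundTruth(spec, panels)
    generate_caption(spec, truth)
    return canvas, truth


_FILLERS = [
    "Binding assay of the purified complex",
    "Immunoblot of the eluted fractions",
    "Quantification of three replicates",
    "Co-precipitation with the tagged bait",
    "Gel filtration elution profile",
    "Fluorescence localization pattern",
    "Densitometric analysis of the bands",
    "Two-hybrid growth selection",
    "Time course of the interaction",
    "Control reaction without lysate",
    "Crosslinked species on native gel",
    "Mutant construct comparison",
    "Overlay assay with labeled probe",
    "Competition with unlabeled ligand",
    "Input lysate loading control",
    "Sedimentation velocity profile",
]


def generate_caption(spec: FixtureSpec, truth: GroundTruth) -> str:
    """Compose the caption text and subcaption ground truth in place."""
    rng = np.random.default_rng(spec.seed + 1)
    fig_no = int(rng.integers(1, 10))
    labels = truth.labels
    order = rng.permutation(len(_FILLERS))
    fillers = [_FILLERS[i] for i in order]

    parts: list[str] = [f"Figure {fig_no}."]
    subcaptions: list[SubCaption] = []
    decoy_span = None

    if spec.caption_style == "none" or not labels:
        body = fillers[0] + " and " + fillers[1].lower() + "."
        parts.append(body)
        caption = " ".join(parts)
        truth.caption = caption
        truth.subcaptions = []
        truth.decoy_span = None
        return caption

    if spec.caption_style == "range" and len(labels) >= 3:
        shared_text = fillers[0] + "."
        parts.append(f"({labels[0]}-{labels[2]}) {shared_text}")
        for lb in labels[:3]:
            subcaptions.append(SubCaption(lb, shared_text, shared=True))
        rest = labels[3:]
        for i, lb in enumerate(rest):
            text = fillers[(i + 1) % len(fillers)] + "."
            parts.append(f"({lb}) {text}")
            subcaptions.append(SubCaption(lb, text, shared=False))
    else:
        for i, lb in enumerate(labels):
            text = fillers[i % len(fillers)] + "."
            parts.append(f"({lb}) {text}")
            subcaptions.append(SubCaption(lb, text, shared=False))

    caption = " ".join(parts)

    if spec.caption_label_corruption and len(labels) >= 3:
        # Duplicate mention of the third label mid-sentence, mimicking an
        # abbreviation like "(C) for carbon".
        decoy = f" (as measured for ({labels[2]}))"
        caption = caption + decoy
        start = caption.rindex(f"({labels[2]})")
        decoy_span = (start, start + len(labels[2]) + 2)
        # The decoy text trails the final subcaption.
        last = subcaptions[-1]
        subcaptions[-1] = SubCaption(
            last.label, (last.text + decoy).strip(), last.shared
        )

    truth.caption = caption
    truth.subcaptions = subcaptions
    truth.decoy_span = decoy_span
    return caption


#: Visually-similar character confusions (both directions where sensible).
_CONFUSIONS = {
    "D": "O",
    "O": "D",
    "I": "L",
    "L": "I",
    "B": "E",
    "E": "B",
    "C": "G",
    "G": "C",
    "F": "P",
    "P": "F",
    "1": "7",
    "7": "1",
    "3": "8",
    "8": "3",
}


def corrupt_ocr(
    tokens: list[OcrToken],
    drop_rate: float,
    confusion_rate: float,
    seed: int,
) -> tuple[list[OcrToken], list[int], list[int]]:
    """Apply OCR noise: independent drops, then character confusions.

    Returns ``(noisy tokens, dropped indices, confused indices)``;
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    out: list[OcrToken] = []
    dropped: list[int] = []
    confused: list[int] = []
    for i, tok in enumerate(tokens):
        if rng.random() < drop_rate:
            dropped.append(i)
            continue
        text = tok.text
        if rng.random() < confusion_rate:
            chars = list(text)
            idx = [k for k, c in enumerate(chars) if c.isalnum()]
            if idx:
                k = idx[int(rng.integers(len(idx)))]
                chars[k] = _CONFUSIONS.get(
                    chars[k].upper(), chr(ord("A") + (ord(chars[k].upper()) - ord("A") + 1) % 26)
                )
                text = "".join(chars)
                confused.append(i)
        out.append(OcrToken(text, tok.bbox, tok.confidence))
    return out, dropped, confused


def drop_one_token(
    tokens: list[OcrToken], seed: int
) -> tuple[list[OcrToken], int]:
    """Drop exactly one token (seeded choice); returns (tokens, index)."""
    rng = np.random.default_rng(seed)
    idx = int(rng.integers(len(tokens)))
    return [t for i, t in enumerate(tokens) if i != idx], idx


# ---------------------------------------------------------------------------
# Operator streams


@dataclass
class DocTruth:
    """Ground truth for one synthetic operator-stream document."""

    caption_texts: list[str]  # one per figure, in figure order
    figure_pages: list[int]
    figure_images: list[np.ndarray]  # original (pre-fragmentation) pixels
    logo_pages: list[int]
    canvas_sizes: list[tuple[int, int]]  # expected (w, h) after harvest
    text_rects: dict[int, BBox]
    n_citation_lines: int


def _split_lines(text: str, width: int = 45) -> list[str]:
    words = text.split()
    lines: list[list[str]] = [[]]
    n = 0
    for word in words:
        if n + len(word) + 1 > width and lines[-1]:
            lines.append([])
            n = 0
        lines[-1].append(word)
        n += len(word) + 1
    return [" ".join(ln) for ln in lines]


def generate_operator_stream(
    n_pages: int,
    seed: int,
    logos: bool = False,
    fragmented: bool = False,
    citations: bool = False,
) -> tuple[list[Operator], DocTruth]:
    """Emit a synthetic document as an operator stream plus ground truth.

    One figure-caption pair per page, captions split across single-line
    text operators, optional out-of-text-rectangle logos, optional
    in-text figure citations, and (when ``fragmented``) the first page's
    figure emitted as three placed fragments at half scale.
    """
    rng = np.random.default_rng(seed)
    text_rect = BBox(50, 60, 560, 760)
    ops: list[Operator] = []
    truth = DocTruth([], [], [], [], [], {p: text_rect for p in range(n_pages)}, 0)

    for page in range(n_pages):
        fig_spec = FixtureSpec(
            rows=1, cols=2, seed=seed * 1000 + page, label_category="closed"
        )
        img, fig_truth = generate_figure(fig_spec)
        caption = f"Fig. {page + 1}. " + " ".join(
            f"({p.label}) {sc.text}"
            for p, sc in zip(fig_truth.panels, fig_truth.subcaptions)
        )

        if logos:
            logo = np.full((40, 40), 0, dtype=np.uint8)
            ops.append(Operator("image", page, BBox(600, 8, 640, 48), image=logo))
            truth.logo_pages.append(page)

        fh, fw = img.shape
        # Placed at half scale in the left column.
        px0, py0 = 60, 100
        pw, ph = fw // 2, fh // 2
        fragment_this = fragmented and page == 0
        if fragment_this:
            cut1, cut2 = fh // 3, 2 * fh // 3
            pieces = [img[:cut1], img[cut1:cut2], img[cut2:]]
            y = py0
            for piece in pieces:
                pph = piece.shape[0] // 2
                ops.append(
                    Operator(
                        "image",
                        page,
                        BBox(px0, y, px0 + pw, y + pph),
                        image=piece,
                    )
                )
                y += pph
        else:
            ops.append(
                Operator("image", page, BBox(px0, py0, px0 + pw, py0 + ph), image=img)
            )
        truth.figure_pages.append(page)
        truth.figure_images.append(img)
        # A lone image operator passes through untouched (original pixels);
        # fragments at half scale reconstruct to the full original size.
        truth.canvas_sizes.append((fw, fh))
        truth.caption_texts.append(caption)

        # Caption paragraph just below the figure, same (left) column.
        y = py0 + ph + 16
        for line in _split_lines(caption):
            ops.append(
                Operator(
                    "text", page, BBox(px0, y, px0 + 230, y + 12), text=line
                )
            )
            y += 14

        if citations:
            ops.append(
                Operator(
                    "text",
                    page,
                    BBox(300, 650, 540, 662),
                    text="Figure 1 shows the interaction in detail",
                )
            )
            truth.n_citation_lines += 1

    return ops, truth


# ---------------------------------------------------------------------------
# Count-model corpus


def make_count_corpus(
    n: int, seed: int = 13
) -> list[tuple[CountEvidence, int]]:
    """Simulate (evidence, true count) pairs with realistic noise.

    Subcaption counts are usually right (captions are the most reliable
    witness); label counts suffer OCR drops, recorded partly as gaps;
    component counts suffer merges and splits.
    """
    rng = np.random.default_rng(seed)
    corpus: list[tuple[CountEvidence, int]] = []
    for _ in range(n):
        true = int(rng.integers(1, 10))

        # Captions are the most reliable witness; when they fail it is
        # almost always a multi-panel figure with an unlabeled caption.
        ns = true if rng.random() < 0.97 else 1

        gaps = 0
        r = rng.random()
        if r < 0.65 or true == 1:
            nl = true
        elif r < 0.92:  # an interior OCR drop leaves a gap behind
            nl = true - 1
            gaps = 1
        else:  # trailing drop: the gap is invisible
            nl = true - 1

        # Components over-segment more often than they merge.
        nc = true if rng.random() < 0.5 else max(1, true + int(rng.choice([1, 2, 3])))

        corpus.append((CountEvidence(ns, nl, nc, gaps), true))
    return corpus
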