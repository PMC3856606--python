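"""End-to-end orchestration: caption, OCR labels, image prep, panel cuts.

`segment_figure` runs the full per-figure pipeline and returns labeled
panel records paired with subcaptions plus a report row with the decision
provenance. `evaluate_corpus` scores a fixture set against ground truth
using the success definitions of the per-stage evaluations (a caption
counts as successfully segmented when it yields the gold number of
subcaptions, and so on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from figseg.caption_seg import NO_LABEL, CaptionResult, segment_caption
from figseg.image_prep import DEFAULT_MIN_AREA, preprocess_figure
from figseg.inimage_text import LabelGroup, OcrToken, recover_labels
from figseg.panel_seg import (
    CountEvidence,
    CountModel,
    PanelRecord,
    associate,
    build_layout_graph,
    estimate_panel_count,
    fill_label_gaps,
    partition_figure,
    train_count_model,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FigureReport",
    "RunReport",
    "segment_figure",
    "evaluate_corpus",
    "default_count_model",
]

_DEFAULT_MODEL: CountModel | None = None
_DEFAULT_MODEL_SEED = 13
_DEFAULT_MODEL_SIZE = 400


def default_count_model() -> CountModel:
    """The shipped count model: trained deterministically on the synthetic
    noisy evidence corpus (fixed seed) at first use."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        from figseg.synth import make_count_corpus

        corpus = make_count_corpus(_DEFAULT_MODEL_SIZE, seed=_DEFAULT_MODEL_SEED)
        _DEFAULT_MODEL = train_count_model(corpus, seed=_DEFAULT_MODEL_SEED)
    return _DEFAULT_MODEL


@dataclass
class PipelineConfig:
    penalty_factor: float = 10.0
    min_cc_area: int = DEFAULT_MIN_AREA
    connectivity: int = 4
    text_box_padding: int = 0
    alphabet_priority: tuple[str, ...] = ("latin", "roman", "arabic")

    def __post_init__(self) -> None:
        if self.connectivity != 4:
            raise ValueError("only 4-connectivity is supported")
        if tuple(self.alphabet_priority) != ("latin", "roman", "arabic"):
            raise ValueError("alphabet priority is fixed to latin,roman,arabic")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a simple key=value config file."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key in ("penalty_factor",):
                    kwargs[key] = float(value)
                elif key in ("min_cc_area", "connectivity", "text_box_padding"):
                    kwargs[key] = int(value)
                elif key == "alphabet_priority":
                    kwargs[key] = tuple(v.strip() for v in value.split(","))
                else:
                    raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class FigureReport:
    """Per-figure decision provenance and counts."""

    n_subcaptions: int
    n_labels: int
    n_cc: int
    gaps: int
    n_panels: int
    decision: str
    degraded: bool = False
    unplaced_subcaptions: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RunReport:
    """Corpus-level tallies mirroring the per-stage error taxonomies."""

    n_figures: int = 0
    caption_success: int = 0
    label_success: int = 0
    gap_fix_success: int = 0
    gap_fix_total: int = 0
    panel_success: int = 0
    count_success: int = 0
    decisions: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def rate(self, numer: int) -> float:
        return numer / self.n_figures if self.n_figures else 0.0

    def to_dict(self) -> dict:
        return {
            "n_figures": self.n_figures,
            "caption_segmentation_rate": self.rate(self.caption_success),
            "label_identification_rate": self.rate(self.label_success),
            "panel_segmentation_rate": self.rate(self.panel_success),
            "panel_count_rate": self.rate(self.count_success),
            "gap_fix_rate": (
                self.gap_fix_success / self.gap_fix_total if self.gap_fix_total else None
            ),
            "decisions": self.decisions,
            "errors": self.errors,
        }


def segment_figure(
    image: np.ndarray,
    caption_text: str,
    tokens: list[OcrToken],
    config: PipelineConfig | None = None,
    model: CountModel | None = None,
) -> tuple[list[PanelRecord], FigureReport, CaptionResult, LabelGroup | None]:
    """Run the per-figure pipeline; returns (panels, report, caption, group)."""
    config = config or PipelineConfig()
    if model is None:
        model = default_count_model()

    cap = segment_caption(caption_text)
    labeled_subs = [sc for sc in cap.subcaptions if sc.label != NO_LABEL]
    n_sub = len(labeled_subs)

    group = recover_labels(tokens)
    n_labels = len(group.members) if group else 0
    gaps = group.gaps if group else 0

    h, w = image.shape[:2]
    _, _, components = preprocess_figure(
        image,
        text_boxes=[t.bbox for t in tokens],
        min_area=config.min_cc_area,
        text_box_padding=config.text_box_padding,
    )
    ev = CountEvidence(n_sub, n_labels, len(components), gaps)
    count, decision = estimate_panel_count(ev, model)

    if group is None or not group.members or count <= 1:
        from figseg.geometry import BBox
        from figseg.panel_seg import LayoutGraph, LayoutNode

        if group and group.members and count == 1:
            m = group.members[0]
            nodes = [LayoutNode(m.char, m.position, m.bbox)]
        else:
            nodes = []
        graph = LayoutGraph(nodes, [])
        box = BBox(0, 0, w, h)
        label = nodes[0].char if nodes else NO_LABEL
        records = [PanelRecord(box, label, region_rects=[box])]
        if count > 1:
            log.warning("estimated %d panels but no label nodes; single panel", count)
    else:
        nodes, unfillable = fill_label_gaps(
            group, (w, h), components, target_panels=count
        )
        graph = build_layout_graph(nodes)
        records = partition_figure((w, h), graph, components)

    records, unplaced = associate(records, cap.subcaptions)
    report = FigureReport(
        n_subcaptions=n_sub,
        n_labels=n_labels,
        n_cc=len(components),
        gaps=gaps,
        n_panels=len(records),
        decision=decision,
        degraded=any(r.degraded for r in records),
        unplaced_subcaptions=len(unplaced),
    )
    return records, report, cap, group


def evaluate_corpus(
    fixtures,
    config: PipelineConfig | None = None,
    model: CountModel | None = None,
    noisy_tokens: dict | None = None,
) -> RunReport:
    """Score the pipeline on (image, GroundTruth) fixtures.

    ``noisy_tokens`` may map fixture index -> token list to override the
    clean ground-truth tokens (for robustness runs).
    """
    report = RunReport()
    for i, (image, truth) in enumerate(fixtures):
        tokens = (noisy_tokens or {}).get(i, truth.tokens)
        try:
            records, row, cap, group = segment_figure(
                image, truth.caption, tokens, config=config, model=model
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("fixture %d failed: %s", i, exc)
            report.n_figures += 1
            report.errors["exception"] = report.errors.get("exception", 0) + 1
            continue
        report.n_figures += 1
        report.decisions[row.decision] = report.decisions.get(row.decision, 0) + 1

        expected_subs = len(truth.subcaptions)
        got_subs = len([s for s in cap.subcaptions if s.label != NO_LABEL])
        if got_subs == expected_subs:
            report.caption_success += 1
        else:
            report.errors["caption"] = report.errors.get("caption", 0) + 1

        got_labels = [m.char for m in group.members] if group else []
        if got_labels == truth.labels:
            report.label_success += 1
        else:
            report.errors["labels"] = report.errors.get("labels", 0) + 1

        if row.n_panels == truth.n_panels:
            report.count_success += 1

        truth_map = {p.label: p.region for p in truth.panels}
        got_map = {r.label: r.bbox for r in records}
        pairing_ok = all(
            r.label in truth_map
            and (r.subcaption is not None) == any(s.label == r.label for s in truth.subcaptions)
            for r in records
        ) or (truth.n_panels == 1 and len(records) == 1)
        if (
            row.n_panels == truth.n_panels
            and got_map.keys() == truth_map.keys()
            and all(got_map[k] == truth_map[k] for k in truth_map)
            and pairing_ok
        ):
            report.panel_success += 1
        else:
            report.errors["panels"] = report.errors.get("panels", 0) + 1
    return report
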