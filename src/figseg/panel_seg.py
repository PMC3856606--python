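"""Panel-count estimation and layout-graph figure partitioning.

The number of panels is estimated from three independent witnesses
(subcaptions, in-image labels, connected components) by consensus, then
CC arbitration, then a decision-tree fallback. Missing labels are placed
by sequence/grid interpolation, a layout graph links each label to its
closest horizontal and vertical neighbors, each edge induces a
perpendicular full-span cut at the pixel of minimum crossing cost (the
summed extent of intersected components along the edge axis), crossing
cuts stop the costlier one at the intersection, and the resulting faces
become panels joined with subcaptions by label.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from statistics import median

import numpy as np

from figseg.caption_seg import NO_LABEL, SubCaption
from figseg.geometry import BBox, bbox_union
from figseg.image_prep import ConnectedComponent
from figseg.inimage_text import LabelGroup

__all__ = [
    "CountEvidence",
    "CountModel",
    "LayoutNode",
    "LayoutEdge",
    "LayoutGraph",
    "CutLine",
    "PanelRecord",
    "estimate_panel_count",
    "train_count_model",
    "fill_label_gaps",
    "build_layout_graph",
    "compute_cut",
    "partition_figure",
    "associate",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Panel-count estimation


@dataclass(frozen=True)
class CountEvidence:
    """The three panel-count witnesses plus the label-sequence gap count."""

    n_subcaptions: int
    n_labels: int
    n_cc: int
    gaps: int = 0

    def features(self) -> list[int]:
        return [self.n_subcaptions, self.n_labels, self.n_cc, self.gaps]


class CountModel:
    """Decision-tree panel-count fallback, JSON-serializable.

    Internally stores the array form of a trained sklearn decision tree
    (children, split feature, threshold, leaf class) so that models ship
    as plain text and predict without sklearn at run time.
    """

    FEATURE_NAMES = ("n_subcaptions", "n_labels", "n_cc", "gaps")

    def __init__(
        self,
        children_left: list[int],
        children_right: list[int],
        feature: list[int],
        threshold: list[float],
        leaf_class: list[int],
        classes: list[int],
    ) -> None:
        self.children_left = children_left
        self.children_right = children_right
        self.feature = feature
        self.threshold = threshold
        self.leaf_class = leaf_class
        self.classes = classes

    def predict(self, ev: CountEvidence) -> int:
        x = ev.features()
        node = 0
        while self.children_left[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return self.classes[self.leaf_class[node]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "children_left": self.children_left,
                "children_right": self.children_right,
                "feature": self.feature,
                "threshold": self.threshold,
                "leaf_class": self.leaf_class,
                "classes": self.classes,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CountModel":
        d = json.loads(text)
        return cls(
            d["children_left"],
            d["children_right"],
            d["feature"],
            d["threshold"],
            d["leaf_class"],
            d["classes"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CountModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_count_model(
    corpus: list[tuple[CountEvidence, int]], seed: int = 13
) -> CountModel:
    """Train the decision-tree count fallback on (evidence, true count) pairs.

    Deterministic given the seed; a single-class corpus degenerates to a
    constant model with a warning.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    y = [true for _, true in corpus]
    if len(set(y)) == 1:
        warnings.warn("degenerate corpus with a single count class; constant model")
        return CountModel([-1], [-1], [-2], [0.0], [0], [y[0]])

    from sklearn.tree import DecisionTreeClassifier

    X = np.array([ev.features() for ev, _ in corpus], dtype=float)
    clf = DecisionTreeClassifier(random_state=seed)
    clf.fit(X, y)
    t = clf.tree_
    leaf_class = np.argmax(t.value[:, 0, :], axis=1)
    return CountModel(
        t.children_left.tolist(),
        t.children_right.tolist(),
        t.feature.tolist(),
        t.threshold.tolist(),
        leaf_class.tolist(),
        [int(c) for c in clf.classes_],
    )


def estimate_panel_count(
    ev: CountEvidence, model: CountModel | None = None
) -> tuple[int, str]:
    """Estimate the panel count; returns ``(count, decision)``.

    Subcaptions agreeing with labels win outright (*consensus*); otherwise
    a CC count equal to exactly one of them arbitrates (*cc_arbitrated*);
    otherwise the decision tree decides (*model*). All-zero evidence means
    a single-panel figure.
    """
    ns, nl, nc = ev.n_subcaptions, ev.n_labels, ev.n_cc
    if ns == 0 and nl == 0 and nc == 0:
        return 1, "default"
    if ns > 0 and ns == nl:
        return ns, "consensus"
    if nc > 0:
        hit_s = nc == ns
        hit_l = nc == nl
        if hit_s != hit_l:  # exactly one witness agrees with the CC count
            return nc, "cc_arbitrated"
    if model is None:
        # No fallback model: trust the most confident non-zero witness.
        return max(1, ns or nl or nc), "default"
    return max(1, model.predict(ev)), "model"


# ---------------------------------------------------------------------------
# Layout graph


@dataclass
class LayoutNode:
    """A panel-label position in the figure (detected or estimated)."""

    char: str
    position: int
    bbox: BBox
    estimated: bool = False

    @property
    def anchor(self) -> tuple[float, float]:
        return self.bbox.center


@dataclass(frozen=True)
class LayoutEdge:
    a: int  # node index
    b: int
    orientation: str  # "horizontal" | "vertical"


@dataclass
class LayoutGraph:
    nodes: list[LayoutNode]
    edges: list[LayoutEdge] = field(default_factory=list)


def _row_overlap(a: BBox, b: BBox) -> bool:
    return a.y_min < b.y_max and b.y_min < a.y_max


def _col_overlap(a: BBox, b: BBox) -> bool:
    return a.x_min < b.x_max and b.x_min < a.x_max


def build_layout_graph(nodes: list[LayoutNode]) -> LayoutGraph:
    """Link every node to its closest horizontal and vertical neighbors.

    Horizontal neighbors share a row band (overlapping y-intervals) and
    are searched separately to the left and to the right, keeping the
    nearest on each side so that a row of labels forms a chain; vertical
    neighbors work the same way within column bands. Duplicate edges
    collapse. A single node yields an empty edge set.
    """
    if not nodes:
        raise ValueError("layout graph needs at least one node")
    edges: set[tuple[int, int, str]] = set()
    for i, ni in enumerate(nodes):
        best: dict[str, tuple[float, int] | None] = {
            "left": None, "right": None, "up": None, "down": None,
        }
        for j, nj in enumerate(nodes):
            if i == j:
                continue
            if _row_overlap(ni.bbox, nj.bbox):
                dx = nj.anchor[0] - ni.anchor[0]
                side = "right" if dx > 0 else "left"
                if dx != 0 and (best[side] is None or abs(dx) < best[side][0]):
                    best[side] = (abs(dx), j)
            if _col_overlap(ni.bbox, nj.bbox):
                dy = nj.anchor[1] - ni.anchor[1]
                side = "down" if dy > 0 else "up"
                if dy != 0 and (best[side] is None or abs(dy) < best[side][0]):
                    best[side] = (abs(dy), j)
        for side, hit in best.items():
            if hit is not None:
                a, b = sorted((i, hit[1]))
                edges.add((a, b, "horizontal" if side in ("left", "right") else "vertical"))
    return LayoutGraph(nodes, [LayoutEdge(a, b, o) for a, b, o in sorted(edges)])


# ---------------------------------------------------------------------------
# Gap filling


def _cluster_1d(values: list[float], tol: float) -> list[float]:
    """Cluster sorted scalars within tolerance; returns cluster centers."""
    centers: list[list[float]] = []
    for v in sorted(values):
        if centers and v - centers[-1][-1] <= tol:
            centers[-1].append(v)
        else:
            centers.append([v])
    return [sum(c) / len(c) for c in centers]


def _nearest_index(centers: list[float], v: float) -> int:
    return min(range(len(centers)), key=lambda i: abs(centers[i] - v))


def fill_label_gaps(
    group: LabelGroup,
    figure_size: tuple[int, int],
    components: list[ConnectedComponent] | None = None,
    target_panels: int | None = None,
) -> tuple[list[LayoutNode], list[int]]:
    """Insert estimated nodes for missing label positions.

    The figure is discretized into row/column blocks from the detected
    label positions. In a single row or column the missing label goes at
    the (position-weighted) midpoint of its sequence neighbors, with end
    gaps extrapolated by the mean neighbor spacing. In consistent 2-D
    grids the missing label takes its column from the aligned label in an
    adjacent row and its row from its sequence neighbors — only when the
    estimated block holds no other label. Returns the completed node list
    (position-sorted) and any unfillable positions.
    """
    from figseg.labels import label_at_position

    w, h = figure_size
    members = {m.position: m for m in group.members}
    if not members:
        return [], list(range(1, (target_panels or 0) + 1))
    panels = max(group.panels, target_panels or 0)

    nodes = [
        LayoutNode(m.char, m.position, m.bbox) for m in group.members if m.position <= panels
    ]
    missing = [p for p in range(1, panels + 1) if p not in members]
    if not missing:
        return sorted(nodes, key=lambda n: n.position), []

    med_w = int(median(m.bbox.width for m in members.values()))
    med_h = int(median(m.bbox.height for m in members.values()))
    tol_x = max(8.0, 0.03 * w)
    tol_y = max(8.0, 0.03 * h)
    anchors = {p: m.bbox.center for p, m in members.items()}
    row_centers = _cluster_1d([a[1] for a in anchors.values()], tol_y)
    col_centers = _cluster_1d([a[0] for a in anchors.values()], tol_x)
    n_rows, n_cols = len(row_centers), len(col_centers)

    def make_node(p: int, x: float, y: float) -> LayoutNode:
        x0 = int(round(min(max(x - med_w / 2, 0), w - med_w)))
        y0 = int(round(min(max(y - med_h / 2, 0), h - med_h)))
        char = label_at_position(group.alphabet, p)
        return LayoutNode(char, p, BBox(x0, y0, x0 + med_w, y0 + med_h), estimated=True)

    # Try the row-major grid hypothesis: position p sits in cell
    # ((p-1) // n_cols, (p-1) % n_cols).
    grid_ok = n_cols >= 1 and panels <= n_rows * n_cols
    if grid_ok:
        for p, (ax, ay) in anchors.items():
            r, c = divmod(p - 1, n_cols)
            if r >= n_rows or _nearest_index(row_centers, ay) != r or _nearest_index(
                col_centers, ax
            ) != c:
                grid_ok = False
                break

    unfillable: list[int] = []
    if grid_ok and (n_rows > 1 and n_cols > 1):
        occupied = {
            (_nearest_index(row_centers, ay), _nearest_index(col_centers, ax))
            for ax, ay in anchors.values()
        }
        for p in missing:
            r, c = divmod(p - 1, n_cols)
            if (r, c) in occupied:
                unfillable.append(p)
                continue
            nodes.append(make_node(p, col_centers[c], row_centers[r]))
            occupied.add((r, c))
        nodes.sort(key=lambda n: n.position)
        if unfillable:
            log.warning("unfillable label positions: %s", unfillable)
        return nodes, unfillable

    # 1-D fallback: interpolate/extrapolate along the label sequence.
    present = sorted(anchors)
    spacings = []
    for a, b in zip(present, present[1:]):
        dx = (anchors[b][0] - anchors[a][0]) / (b - a)
        dy = (anchors[b][1] - anchors[a][1]) / (b - a)
        spacings.append((dx, dy))
    if spacings:
        step = (
            sum(s[0] for s in spacings) / len(spacings),
            sum(s[1] for s in spacings) / len(spacings),
        )
    else:
        step = (float(w), 0.0)

    for p in missing:
        prevs = [q for q in present if q < p]
        nexts = [q for q in present if q > p]
        if prevs and nexts:
            q0, q1 = prevs[-1], nexts[0]
            f = (p - q0) / (q1 - q0)
            x = anchors[q0][0] + f * (anchors[q1][0] - anchors[q0][0])
            y = anchors[q0][1] + f * (anchors[q1][1] - anchors[q0][1])
        elif prevs:
            q0 = prevs[-1]
            x = anchors[q0][0] + step[0] * (p - q0)
            y = anchors[q0][1] + step[1] * (p - q0)
        elif nexts:
            q1 = nexts[0]
            x = anchors[q1][0] - step[0] * (q1 - p)
            y = anchors[q1][1] - step[1] * (q1 - p)
        else:  # pragma: no cover - members is non-empty
            unfillable.append(p)
            continue
        if not (0 <= x <= w and 0 <= y <= h):
            unfillable.append(p)
            continue
        nodes.append(make_node(p, x, y))

    if unfillable and components:
        unfillable = _fill_from_components(
            nodes, unfillable, components, make_node, tol_y
        )
    nodes.sort(key=lambda n: n.position)
    if unfillable:
        log.warning("unfillable label positions: %s", unfillable)
    return nodes, unfillable


def _fill_from_components(
    nodes: list[LayoutNode],
    missing: list[int],
    components: list[ConnectedComponent],
    make_node,
    tol_y: float,
) -> list[int]:
    """Last resort for gaps interpolation cannot reach: panels usually map
    one-to-one onto large components, so missing labels go to the
    components holding no label anchor, paired in reading order."""
    free = [
        c
        for c in components
        if not any(c.bbox.contains_point(*n.anchor) for n in nodes)
    ]
    if len(free) != len(missing):
        return missing
    free.sort(key=lambda c: (int(c.bbox.y_min / max(tol_y, 1)), c.bbox.x_min))
    # Labels sit at a consistent offset inside their panel's component
    # (typically the top-left corner); reuse the median observed offset.
    offsets = []
    for n in nodes:
        for c in components:
            if c.bbox.contains_point(*n.anchor):
                offsets.append(
                    (n.anchor[0] - c.bbox.x_min, n.anchor[1] - c.bbox.y_min)
                )
                break
    for p, comp in zip(sorted(missing), free):
        if offsets:
            dx = median(o[0] for o in offsets)
            dy = median(o[1] for o in offsets)
            nodes.append(make_node(p, comp.bbox.x_min + dx, comp.bbox.y_min + dy))
        else:
            nodes.append(make_node(p, *comp.bbox.center))
    return []


# ---------------------------------------------------------------------------
# Cuts


@dataclass
class CutLine:
    """A straight cut: vertical (x = coordinate) or horizontal (y = ...)."""

    orientation: str  # of the cut line itself
    coordinate: int
    span: tuple[int, int]  # covered interval along the line
    cost: float
    #: coordinate of the generating edge corridor along the cut line's
    #: axis; used to decide which side survives a truncation.
    anchor_along: float = 0.0


def compute_cut(
    edge: LayoutEdge,
    nodes: list[LayoutNode],
    components: list[ConnectedComponent],
    figure_size: tuple[int, int],
) -> CutLine:
    """Minimum-cost perpendicular cut for one layout edge.

    A horizontal edge yields a vertical cut and vice versa. Candidate
    coordinates are every integer pixel strictly between the two anchor
    points along the edge axis; the cost at a candidate is the summed
    extent, along the edge axis, of components whose box the full-span
    perpendicular line intersects. Ties go to the candidate nearest the
    corridor midpoint, then to the smaller coordinate.
    """
    w, h = figure_size
    na, nb = nodes[edge.a], nodes[edge.b]
    if edge.orientation == "horizontal":
        a, b = sorted((na.anchor[0], nb.anchor[0]))
        lo, hi = int(np.floor(a)) + 1, int(np.ceil(b)) - 1
        if hi < lo:
            raise ValueError("label anchors too close to cut between")
        extents = [(c.bbox.x_min, c.bbox.x_max, c.bbox.width) for c in components]
        span_len, orientation = h, "vertical"
        anchor_along = (na.anchor[1] + nb.anchor[1]) / 2.0
    elif edge.orientation == "vertical":
        a, b = sorted((na.anchor[1], nb.anchor[1]))
        lo, hi = int(np.floor(a)) + 1, int(np.ceil(b)) - 1
        if hi < lo:
            raise ValueError("label anchors too close to cut between")
        extents = [(c.bbox.y_min, c.bbox.y_max, c.bbox.height) for c in components]
        span_len, orientation = w, "horizontal"
        anchor_along = (na.anchor[0] + nb.anchor[0]) / 2.0
    else:
        raise ValueError(f"unknown edge orientation {edge.orientation!r}")

    mid = (a + b) / 2.0
    best = None
    for coord in range(lo, hi + 1):
        cost = sum(ext for c0, c1, ext in extents if c0 <= coord < c1)
        key = (cost, abs(coord - mid), coord)
        if best is None or key < best[0]:
            best = (key, coord, cost)
    _, coord, cost = best
    return CutLine(orientation, coord, (0, span_len), float(cost), anchor_along)


def _crosses(v: CutLine, hcut: CutLine) -> bool:
    return (
        v.span[0] < hcut.coordinate < v.span[1]
        and hcut.span[0] < v.coordinate < hcut.span[1]
    )


def _truncate(cut: CutLine, at: int) -> None:
    """Stop ``cut`` at coordinate ``at`` along its line, keeping the side
    containing its generating corridor."""
    lo, hi = cut.span
    if cut.anchor_along >= at:
        cut.span = (at, hi)
    else:
        cut.span = (lo, at)


def resolve_crossings(cuts: list[CutLine]) -> list[CutLine]:
    """Apply the stopping rule: where a horizontal and a vertical cut
    cross, the strictly costlier one terminates at the crossing."""
    vcuts = [c for c in cuts if c.orientation == "vertical"]
    hcuts = [c for c in cuts if c.orientation == "horizontal"]
    changed = True
    while changed:
        changed = False
        for v in vcuts:
            for hc in hcuts:
                if _crosses(v, hc):
                    if v.cost > hc.cost:
                        _truncate(v, hc.coordinate)
                        changed = True
                    elif hc.cost > v.cost:
                        _truncate(hc, v.coordinate)
                        changed = True
                    # Equal costs: both cuts continue through the crossing.
    return vcuts + hcuts


# ---------------------------------------------------------------------------
# Partition


@dataclass
class PanelRecord:
    """One output panel: its region, label, and paired subcaption."""

    bbox: BBox
    label: str = NO_LABEL
    subcaption: SubCaption | None = None
    region_rects: list[BBox] = field(default_factory=list)
    region_map_id: int = 0
    degraded: bool = False

    @property
    def region_area(self) -> int:
        return sum(r.area for r in self.region_rects)

    def to_dict(self) -> dict:
        d = {"bbox": self.bbox.to_list(), "label": self.label}
        if self.subcaption is not None:
            d["subcaption"] = self.subcaption.text
            d["shared"] = self.subcaption.shared
        else:
            d["subcaption"] = None
            d["shared"] = False
        return d


def _faces_from_cuts(
    figure_size: tuple[int, int], cuts: list[CutLine]
) -> list[list[BBox]]:
    """Decompose the figure into faces bounded by the (possibly truncated)
    cut segments, as lists of coarse rectangles."""
    w, h = figure_size
    vcuts = [c for c in cuts if c.orientation == "vertical"]
    hcuts = [c for c in cuts if c.orientation == "horizontal"]
    xs = sorted({0, w} | {c.coordinate for c in vcuts if 0 < c.coordinate < w})
    ys = sorted({0, h} | {c.coordinate for c in hcuts if 0 < c.coordinate < h})
    # Also register truncation endpoints so walls align with cell borders.
    ys = sorted(set(ys) | {e for c in vcuts for e in c.span if 0 < e < h} | {0, h})
    xs = sorted(set(xs) | {e for c in hcuts for e in c.span if 0 < e < w} | {0, w})
    nx, ny = len(xs) - 1, len(ys) - 1

    def blocked_v(x: int, y0: int, y1: int) -> bool:
        return any(
            c.coordinate == x and c.span[0] <= y0 and c.span[1] >= y1 for c in vcuts
        )

    def blocked_h(y: int, x0: int, x1: int) -> bool:
        return any(
            c.coordinate == y and c.span[0] <= x0 and c.span[1] >= x1 for c in hcuts
        )

    # Union-find over coarse cells.
    parent = list(range(nx * ny))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for j in range(ny):
        for i in range(nx):
            cell = j * nx + i
            if i + 1 < nx and not blocked_v(xs[i + 1], ys[j], ys[j + 1]):
                union(cell, cell + 1)
            if j + 1 < ny and not blocked_h(ys[j + 1], xs[i], xs[i + 1]):
                union(cell, cell + nx)

    faces: dict[int, list[BBox]] = {}
    for j in range(ny):
        for i in range(nx):
            root = find(j * nx + i)
            faces.setdefault(root, []).append(
                BBox(xs[i], ys[j], xs[i + 1], ys[j + 1])
            )
    return list(faces.values())


def _bbox_of_rects(rects: list[BBox]) -> BBox:
    box = rects[0]
    for r in rects[1:]:
        box = bbox_union(box, r)
    return box


def _block_partition(
    figure_size: tuple[int, int], nodes: list[LayoutNode]
) -> list[PanelRecord]:
    """Degraded fallback: rectangular blocks around label anchors, with
    boundaries midway between adjacent row/column anchor clusters."""
    w, h = figure_size
    tol_x, tol_y = max(8.0, 0.03 * w), max(8.0, 0.03 * h)
    rows = _cluster_1d([n.anchor[1] for n in nodes], tol_y)
    cols = _cluster_1d([n.anchor[0] for n in nodes], tol_x)
    ys = [0] + [int((a + b) / 2) for a, b in zip(rows, rows[1:])] + [h]
    xs = [0] + [int((a + b) / 2) for a, b in zip(cols, cols[1:])] + [w]
    records = []
    for n in nodes:
        r = _nearest_index(rows, n.anchor[1])
        c = _nearest_index(cols, n.anchor[0])
        box = BBox(xs[c], ys[r], xs[c + 1], ys[r + 1])
        records.append(
            PanelRecord(box, n.char, region_rects=[box], degraded=True)
        )
    return records


def partition_figure(
    figure_size: tuple[int, int],
    graph: LayoutGraph,
    components: list[ConnectedComponent],
) -> list[PanelRecord]:
    """Cut the figure along the layout-graph edges into labeled regions.

    Every pixel ends up in exactly one region. A face holding zero or
    several label nodes triggers the degraded block-partition fallback.
    """
    w, h = figure_size
    if len(graph.nodes) <= 1:
        node = graph.nodes[0] if graph.nodes else None
        box = BBox(0, 0, w, h)
        return [
            PanelRecord(
                box,
                node.char if node else NO_LABEL,
                region_rects=[box],
            )
        ]

    cuts: list[CutLine] = []
    seen: set[tuple[str, int]] = set()
    for edge in graph.edges:
        cut = compute_cut(edge, graph.nodes, components, figure_size)
        key = (cut.orientation, cut.coordinate)
        if key not in seen:
            seen.add(key)
            cuts.append(cut)
    cuts = resolve_crossings(cuts)
    faces = _faces_from_cuts(figure_size, cuts)

    records: list[PanelRecord] = []
    claimed: set[int] = set()
    ok = True
    for rects in faces:
        inside = [
            i
            for i, n in enumerate(graph.nodes)
            if any(r.contains_point(*n.anchor) for r in rects)
        ]
        if len(inside) != 1:
            ok = False
            break
        claimed.add(inside[0])
        node = graph.nodes[inside[0]]
        records.append(
            PanelRecord(_bbox_of_rects(rects), node.char, region_rects=rects)
        )
    if not ok or len(claimed) != len(graph.nodes):
        log.warning("face/label mismatch; falling back to block partition")
        records = _block_partition(figure_size, graph.nodes)
    records.sort(key=lambda r: r.label)
    for i, rec in enumerate(records):
        rec.region_map_id = i
    return records


def associate(
    panels: list[PanelRecord], subcaptions: list[SubCaption]
) -> tuple[list[PanelRecord], list[SubCaption]]:
    """Join panels with subcaptions on the canonical label character.

    Panels without a subcaption keep ``None``; subcaptions without a
    panel are returned as unplaced.
    """
    by_label: dict[str, SubCaption] = {}
    for sc in subcaptions:
        if sc.label in by_label:
            raise ValueError(f"duplicate subcaption label {sc.label!r}")
        by_label[sc.label] = sc
    seen_panel: set[str] = set()
    for p in panels:
        if p.label != NO_LABEL and p.label in seen_panel:
            raise ValueError(f"duplicate panel label {p.label!r}")
        seen_panel.add(p.label)
        sc = by_label.pop(p.label, None)
        if sc is None and p.label != NO_LABEL and len(panels) == 1:
            # Single unlabeled-caption panel: attach the whole-caption text.
            sc = by_label.pop(NO_LABEL, None)
        if sc is None and p.label == NO_LABEL:
            sc = by_label.pop(NO_LABEL, None)
        p.subcaption = sc
    unplaced = list(by_label.values())
    return panels, unplaced
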