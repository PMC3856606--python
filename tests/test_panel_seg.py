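import numpy as np
import pytest

from figseg.geometry import BBox
from figseg.image_prep import ConnectedComponent
from figseg.inimage_text import OcrToken, recover_labels
from figseg.caption_seg import SubCaption
from figseg.panel_seg import (
    CountEvidence,
    CountModel,
    LayoutEdge,
    LayoutNode,
    associate,
    build_layout_graph,
    compute_cut,
    estimate_panel_count,
    fill_label_gaps,
    partition_figure,
    train_count_model,
)


def comp(x0, y0, x1, y1, cid=0):
    return ConnectedComponent(cid, (x1 - x0) * (y1 - y0), BBox(x0, y0, x1, y1))


def node(char, pos, x, y, w=10, h=14):
    return LayoutNode(char, pos, BBox(x, y, x + w, y + h))


def group_from(texts_at):
    toks = [OcrToken(t, BBox(x, y, x + 12, y + 14)) for t, x, y in texts_at]
    return recover_labels(toks)


class TestEstimateCount:
    def test_consensus(self):
        assert estimate_panel_count(CountEvidence(4, 4, 9, 0)) == (4, "consensus")

    def test_cc_arbitrates_subcaptions(self):
        assert estimate_panel_count(CountEvidence(4, 3, 4, 1)) == (4, "cc_arbitrated")

    def test_cc_arbitrates_labels(self):
        assert estimate_panel_count(CountEvidence(3, 5, 5, 0)) == (5, "cc_arbitrated")

    def test_all_zero_single_panel(self):
        count, _ = estimate_panel_count(CountEvidence(0, 0, 0, 0))
        assert count == 1

    def test_model_branch(self):
        corpus = [
            (CountEvidence(k, max(1, k - 1), k + 2, 1), k) for k in range(1, 10)
        ] * 12
        model = train_count_model(corpus, seed=0)
        count, decision = estimate_panel_count(CountEvidence(2, 3, 7, 1), model)
        assert decision == "model"
        assert count >= 1


class TestTrainCountModel:
    def test_separable_data_perfect_training(self):
        corpus = []
        rng = np.random.default_rng(4)
        for _ in range(100):
            true = int(rng.integers(1, 10))
            corpus.append((CountEvidence(true, int(rng.integers(1, 10)), int(rng.integers(1, 12)), 0), true))
        model = train_count_model(corpus, seed=1)
        assert all(model.predict(ev) == y for ev, y in corpus)

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train_count_model([])

    def test_single_class_constant(self):
        corpus = [(CountEvidence(2, 2, 2, 0), 2)] * 60
        with pytest.warns(UserWarning):
            model = train_count_model(corpus)
        assert model.predict(CountEvidence(5, 5, 5, 0)) == 2

    def test_json_roundtrip(self, tmp_path):
        corpus = [
            (CountEvidence(k, k, k, 0), k) for k in range(1, 10)
        ] * 10
        model = train_count_model(corpus, seed=13)
        path = tmp_path / "tree.json"
        model.save(path)
        back = CountModel.load(path)
        for ev, _ in corpus:
            assert back.predict(ev) == model.predict(ev)

    def test_deterministic(self):
        from figseg.synth import make_count_corpus

        corpus = make_count_corpus(100, seed=3)
        m1 = train_count_model(corpus, seed=3)
        m2 = train_count_model(corpus, seed=3)
        assert m1.to_json() == m2.to_json()


class TestFillGaps:
    def test_row_midpoint(self):
        grp = group_from([("A", 50, 20), ("C", 350, 20)])
        nodes, unfillable = fill_label_gaps(grp, (500, 100))
        assert not unfillable
        b = [n for n in nodes if n.char == "B"][0]
        assert b.estimated
        assert b.anchor[0] == pytest.approx(206, abs=2)  # midpoint of anchors
        assert b.anchor[1] == pytest.approx(27, abs=2)

    def test_grid_row_and_column(self):
        # Rows (A,B,C) at y=40 and (_,E,F) at y=420, D missing.
        grp = group_from(
            [("A", 50, 40), ("B", 250, 40), ("C", 450, 40),
             ("E", 250, 420), ("F", 450, 420)]
        )
        nodes, unfillable = fill_label_gaps(grp, (600, 600))
        assert not unfillable
        d = [n for n in nodes if n.char == "D"][0]
        assert d.estimated
        assert d.anchor[0] == pytest.approx(56, abs=2)  # column of A
        assert d.anchor[1] == pytest.approx(427, abs=2)  # row of E

    def test_complete_group_unchanged(self):
        grp = group_from([("A", 10, 10), ("B", 200, 10)])
        nodes, unfillable = fill_label_gaps(grp, (400, 100))
        assert not unfillable
        assert all(not n.estimated for n in nodes)
        assert len(nodes) == 2

    def test_trailing_gap_extrapolated(self):
        grp = group_from([("A", 10, 10), ("B", 210, 10)])
        nodes, _ = fill_label_gaps(grp, (700, 100), target_panels=3)
        c = [n for n in nodes if n.char == "C"][0]
        assert c.anchor[0] == pytest.approx(416, abs=2)

    def test_component_fallback_for_leading_gap(self):
        grp = group_from([("B", 160, 10)])
        comps = [comp(6, 6, 144, 94), comp(156, 6, 294, 94)]
        nodes, unfillable = fill_label_gaps(grp, (300, 100), comps, target_panels=2)
        assert not unfillable
        a = [n for n in nodes if n.char == "A"][0]
        assert a.anchor[0] < 144


class TestLayoutGraph:
    def test_2x2_grid(self):
        g = build_layout_graph(
            [node("A", 1, 10, 10), node("B", 2, 200, 10),
             node("C", 3, 10, 200), node("D", 4, 200, 200)]
        )
        kinds = sorted(e.orientation for e in g.edges)
        assert kinds == ["horizontal", "horizontal", "vertical", "vertical"]

    def test_single_node_no_edges(self):
        g = build_layout_graph([node("A", 1, 10, 10)])
        assert g.edges == []

    def test_1x3_row(self):
        g = build_layout_graph(
            [node("A", 1, 10, 10), node("B", 2, 200, 10), node("C", 3, 400, 10)]
        )
        assert len(g.edges) == 2
        assert all(e.orientation == "horizontal" for e in g.edges)

    def test_1x4_chain(self):
        g = build_layout_graph(
            [node(c, i + 1, 10 + 150 * i, 10) for i, c in enumerate("ABCD")]
        )
        assert len(g.edges) == 3


class TestComputeCut:
    def _graph2(self):
        return build_layout_graph([node("A", 1, 45, 10), node("B", 2, 155, 10)])

    def test_whitespace_corridor(self):
        g = self._graph2()
        comps = [comp(0, 0, 90, 100), comp(110, 0, 200, 100)]
        cut = compute_cut(g.edges[0], g.nodes, comps, (200, 100))
        assert cut.orientation == "vertical"
        assert 90 <= cut.coordinate < 110
        assert cut.cost == 0

    def test_unavoidable_component_tie_midcorridor(self):
        g = self._graph2()
        comps = [comp(0, 0, 200, 100)]  # spans everything
        cut = compute_cut(g.edges[0], g.nodes, comps, (200, 100))
        assert cut.cost == 200  # the component's width
        mid = (g.nodes[0].anchor[0] + g.nodes[1].anchor[0]) / 2
        assert abs(cut.coordinate - mid) <= 0.5

    def test_no_components_midpoint(self):
        g = self._graph2()
        cut = compute_cut(g.edges[0], g.nodes, [], (200, 100))
        assert cut.cost == 0
        mid = (g.nodes[0].anchor[0] + g.nodes[1].anchor[0]) / 2
        assert abs(cut.coordinate - mid) <= 0.5

    def test_cost_profile_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        comps = []
        for i in range(6):
            x0 = int(rng.integers(0, 180))
            w = int(rng.integers(5, 40))
            comps.append(comp(x0, 10, min(x0 + w, 199), 60, cid=i))
        g = self._graph2()
        cut = compute_cut(g.edges[0], g.nodes, comps, (200, 100))
        a = g.nodes[0].anchor[0]
        b = g.nodes[1].anchor[0]
        mid = (a + b) / 2

        def cost(x):
            return sum(c.bbox.width for c in comps if c.bbox.x_min <= x < c.bbox.x_max)

        best = min(
            (cost(x), abs(x - mid), x)
            for x in range(int(a) + 1, int(np.ceil(b)))
        )
        assert (cut.cost, cut.coordinate) == (best[0], best[2])

    def test_close_anchors_error(self):
        g = build_layout_graph([node("A", 1, 50, 10), node("B", 2, 51, 10)])
        with pytest.raises(ValueError):
            compute_cut(g.edges[0], g.nodes, [], (200, 100))

    def test_vertical_edge_gives_horizontal_cut(self):
        g = build_layout_graph([node("A", 1, 10, 10), node("B", 2, 10, 150)])
        cut = compute_cut(g.edges[0], g.nodes, [], (100, 300))
        assert cut.orientation == "horizontal"


class TestPartition:
    def test_2x2_clean(self):
        nodes = [node("A", 1, 14, 14), node("B", 2, 164, 14),
                 node("C", 3, 14, 164), node("D", 4, 164, 164)]
        comps = [comp(6, 6, 144, 144), comp(156, 6, 294, 144),
                 comp(6, 156, 144, 294), comp(156, 156, 294, 294)]
        g = build_layout_graph(nodes)
        records = partition_figure((300, 300), g, comps)
        got = {r.label: r.bbox for r in records}
        assert got["A"] == BBox(0, 0, 144, 144)
        assert got["D"] == BBox(144, 144, 300, 300)
        assert sum(r.region_area for r in records) == 300 * 300

    def test_single_label_whole_figure(self):
        from figseg.panel_seg import LayoutGraph

        g = LayoutGraph([node("A", 1, 10, 10)], [])
        records = partition_figure((200, 100), g, [])
        assert len(records) == 1
        assert records[0].bbox == BBox(0, 0, 200, 100)

    def test_ragged_costlier_cut_stopped(self):
        # Wide top panel A; bottom panels B, C. The vertical cut between
        # B and C would slice A, so it stops at the horizontal cut.
        nodes = [node("A", 1, 14, 14), node("B", 2, 14, 164), node("C", 3, 164, 164)]
        comps = [comp(6, 6, 294, 144),  # top panel spans the full width
                 comp(6, 156, 144, 294), comp(156, 156, 294, 294)]
        g = build_layout_graph(nodes)
        records = partition_figure((300, 300), g, comps)
        got = {r.label: r.bbox for r in records}
        assert got["A"] == BBox(0, 0, 300, 144)  # full width preserved
        assert got["B"] == BBox(0, 144, 144, 300)
        assert got["C"] == BBox(144, 144, 300, 300)
        assert sum(r.region_area for r in records) == 300 * 300

    def test_regions_disjoint_cover(self):
        nodes = [node(c, i + 1, 14 + 150 * (i % 2), 14 + 150 * (i // 2))
                 for i, c in enumerate("ABCD")]
        g = build_layout_graph(nodes)
        records = partition_figure((300, 300), g, [])
        # Pairwise-disjoint rects covering every pixel.
        seen = np.zeros((300, 300), dtype=int)
        for r in records:
            for rect in r.region_rects:
                seen[rect.y_min : rect.y_max, rect.x_min : rect.x_max] += 1
        assert (seen == 1).all()

    def test_zero_cost_cuts_avoid_components(self):
        nodes = [node("A", 1, 14, 14), node("B", 2, 164, 14)]
        comps = [comp(6, 6, 144, 94), comp(156, 6, 294, 94)]
        g = build_layout_graph(nodes)
        records = partition_figure((300, 100), g, comps)
        for r in records:
            for c in comps:
                inter_x = max(r.bbox.x_min, c.bbox.x_min) < min(r.bbox.x_max, c.bbox.x_max)
                inter_y = max(r.bbox.y_min, c.bbox.y_min) < min(r.bbox.y_max, c.bbox.y_max)
                if inter_x and inter_y:
                    # component fully inside the region, not sliced
                    assert r.bbox.x_min <= c.bbox.x_min and c.bbox.x_max <= r.bbox.x_max


class TestAssociate:
    def _panels(self, labels):
        return [
            __import__("figseg.panel_seg", fromlist=["PanelRecord"]).PanelRecord(
                BBox(0, 0, 10, 10), lb, region_rects=[BBox(0, 0, 10, 10)]
            )
            for lb in labels
        ]

    def test_complete_join(self):
        panels, unplaced = associate(
            self._panels(["A", "B"]),
            [SubCaption("A", "one"), SubCaption("B", "two")],
        )
        assert [p.subcaption.text for p in panels] == ["one", "two"]
        assert unplaced == []

    def test_panel_without_subcaption(self):
        panels, unplaced = associate(
            self._panels(["A", "B", "C"]),
            [SubCaption("A", "one"), SubCaption("B", "two")],
        )
        assert panels[2].subcaption is None
        assert unplaced == []

    def test_unplaced_subcaption_reported(self):
        panels, unplaced = associate(self._panels(["A"]), [
            SubCaption("A", "one"), SubCaption("B", "two"),
        ])
        assert [s.label for s in unplaced] == ["B"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            associate(self._panels(["A", "A"]), [SubCaption("A", "x")])
        with pytest.raises(ValueError):
            associate(self._panels(["A"]), [SubCaption("A", "x"), SubCaption("A", "y")])
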