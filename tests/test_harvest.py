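import numpy as np
import pytest

from figseg.geometry import BBox
from figseg.harvest import (
    CaptionObject,
    FigureObject,
    Operator,
    assign_column_tag,
    caption_descriptor,
    extract_objects,
    filter_logos,
    harvest_document,
    match_document,
    merge_subfigures,
    read_operator_stream,
    select_caption_group,
    write_operator_stream,
)
from figseg.synth import generate_operator_stream


def img(h=20, w=30, fill=100):
    return np.full((h, w), fill, dtype=np.uint8)


def text_op(page, y, text, x=50, w=200, h=12):
    return Operator("text", page, BBox(x, y, x + w, y + h), text=text)


def image_op(page, bbox, pixels=None):
    return Operator("image", page, bbox, image=pixels if pixels is not None else img())


class TestExtractFSM:
    def test_caption_line_merge(self):
        stream = [
            text_op(0, 100, "Fig. 1 Interaction of"),
            text_op(0, 114, "A and B."),
            image_op(0, BBox(50, 200, 250, 300)),
        ]
        captions, figures = extract_objects(stream)
        assert len(captions) == 1 and len(figures) == 1
        assert captions[0].text == "Fig. 1 Interaction of A and B."
        assert captions[0].figure_number == 1

    def test_image_only(self):
        captions, figures = extract_objects([image_op(0, BBox(0, 0, 30, 20))])
        assert captions == [] and len(figures) == 1

    def test_empty_stream(self):
        assert extract_objects([]) == ([], [])

    def test_stream_ending_in_caption(self):
        captions, _ = extract_objects([text_op(0, 10, "Figure 2. Tail caption")])
        assert len(captions) == 1

    def test_body_text_ignored(self):
        captions, _ = extract_objects(
            [text_op(0, 10, "The results show binding."), text_op(0, 24, "More text.")]
        )
        assert captions == []

    def test_distant_text_breaks_paragraph(self):
        stream = [
            text_op(0, 100, "Fig. 1 Part one."),
            text_op(0, 400, "Unrelated paragraph far below"),
        ]
        captions, _ = extract_objects(stream)
        assert len(captions) == 1
        assert captions[0].text == "Fig. 1 Part one."

    def test_generator_stream_ground_truth(self):
        ops, truth = generate_operator_stream(3, seed=7)
        captions, figures = extract_objects(ops)
        assert len(figures) == 3
        assert [c.text for c in captions] == truth.caption_texts


class TestFilterLogos:
    RECT = BBox(50, 80, 550, 750)

    def test_outside_removed(self):
        figs = [FigureObject(img(), 0, BBox(600, 0, 700, 40))]
        assert filter_logos(figs, {0: self.RECT}) == []

    def test_contained_kept(self):
        figs = [FigureObject(img(), 0, BBox(60, 100, 500, 400))]
        assert len(filter_logos(figs, {0: self.RECT})) == 1

    def test_straddling_kept(self):
        figs = [FigureObject(img(), 0, BBox(500, 60, 600, 120))]
        assert len(filter_logos(figs, {0: self.RECT})) == 1

    def test_missing_rect_keeps(self):
        figs = [FigureObject(img(), 3, BBox(600, 0, 700, 40))]
        assert len(filter_logos(figs, {})) == 1


class TestMergeSubfigures:
    def test_identity_single(self):
        pixels = img(40, 60)
        fig = FigureObject(pixels, 0, BBox(10, 10, 70, 50))
        out = merge_subfigures([fig])
        assert out is fig
        assert not out.is_reconstructed

    def test_three_stacked_equal_scaling(self):
        rng = np.random.default_rng(2)
        full = rng.integers(0, 255, (90, 60)).astype(np.uint8)
        parts = [full[0:30], full[30:60], full[60:90]]
        figs = [
            FigureObject(p, 0, BBox(100, 200 + 15 * i, 130, 200 + 15 * (i + 1)))
            for i, p in enumerate(parts)  # placed at scale 0.5
        ]
        out = merge_subfigures(figs)
        assert out.is_reconstructed
        assert out.image.shape == (90, 60)
        np.testing.assert_array_equal(out.image, full)

    def test_smallest_scaling_sets_canvas(self):
        # Two fragments, scalings 0.5 and 0.25: canvas at the 0.25 factor.
        a = FigureObject(img(40, 40), 0, BBox(0, 0, 20, 20))  # s = 0.5
        b = FigureObject(img(80, 80), 0, BBox(20, 0, 40, 20))  # s = 0.25
        out = merge_subfigures([a, b])
        # Union is 40x20 page units at 1/0.25 resolution -> 160x80 pixels.
        assert out.image.shape == (80, 160)

    def test_orientation_rotates(self):
        pixels = np.arange(12, dtype=np.uint8).reshape(3, 4)
        fig = FigureObject(pixels, 0, BBox(0, 0, 3, 4), orientation=90)
        filler = FigureObject(img(4, 3), 0, BBox(3, 0, 6, 4))
        out = merge_subfigures([fig, filler])
        np.testing.assert_array_equal(out.image[0:4, 0:3], np.rot90(pixels))


class TestCaptionDescriptor:
    @pytest.mark.parametrize("text,want", [
        ("Figure 2. Binding assay of the complex", "Figure #."),
        ("Fig. 10, lanes 1-4", "Fig. #,"),
        ("(Fig. 3) as shown", "(Fig. #)"),
        ("Figure", "Figure"),
    ])
    def test_examples(self, text, want):
        assert caption_descriptor(text) == want

    def test_idempotent(self):
        d = caption_descriptor("Figure 12. Results")
        assert caption_descriptor(d) == d


def cap(text, page=0, y=0, number=None):
    c = CaptionObject(text, page, BBox(10, y or 10, 200, (y or 10) + 12))
    c.figure_number = number
    return c


class TestSelectCaptionGroup:
    def test_max_unique_links_wins(self):
        real = [cap(f"Figure {i}. Legend text", y=20 * i, number=i) for i in (1, 2, 3, 4)]
        cites = [cap("Figure 1 shows", y=300 + 10 * i, number=1) for i in range(3)]
        for c in cites:
            c.text = "Figure 1 shows more"
        kept = select_caption_group(real + cites)
        assert kept == real

    def test_single_cluster_unchanged(self):
        caps = [cap(f"Figure {i}. Text", number=i, y=15 * i) for i in (1, 2)]
        assert select_caption_group(caps) == caps

    def test_duplicates_retained_in_winner(self):
        caps = [
            cap("Figure 1. First", number=1, y=10),
            cap("Figure 1. Again", number=1, y=30),
            cap("Figure 2. Second", number=2, y=50),
        ]
        assert len(select_caption_group(caps)) == 3


class TestColumnTag:
    RECT = BBox(50, 80, 550, 750)

    def test_left_right_double(self):
        assert assign_column_tag(BBox(60, 100, 290, 200), self.RECT) == "left"
        assert assign_column_tag(BBox(310, 100, 540, 200), self.RECT) == "right"
        assert assign_column_tag(BBox(60, 100, 540, 200), self.RECT) == "double"


class TestMatching:
    def _fig(self, page, bbox, tag="left"):
        f = FigureObject(img(), page, bbox)
        f.column_tag = tag
        return f

    def _cap(self, page, bbox, tag="left"):
        c = CaptionObject("Fig. 1. x", page, bbox)
        c.column_tag = tag
        return c

    def test_one_to_one_base_case(self):
        f = self._fig(0, BBox(10, 10, 100, 100))
        c = self._cap(0, BBox(10, 500, 100, 520))
        matches, lf, lc = match_document([f], [c])
        assert len(matches) == 1 and not lf and not lc

    def test_two_by_two_identity(self):
        f1 = self._fig(0, BBox(10, 10, 100, 100), "left")
        f2 = self._fig(0, BBox(300, 10, 400, 100), "right")
        c1 = self._cap(0, BBox(10, 110, 100, 130), "left")
        c2 = self._cap(0, BBox(300, 110, 400, 130), "right")
        matches, _, _ = match_document([f1, f2], [c1, c2])
        pairs = {(id(m.figure), id(m.caption)) for m in matches}
        assert pairs == {(id(f1), id(c1)), (id(f2), id(c2))}

    def test_cross_page_disparity(self):
        f1 = self._fig(1, BBox(10, 10, 100, 100))
        f2 = self._fig(2, BBox(10, 10, 100, 100))
        c1 = self._cap(1, BBox(10, 110, 100, 130))
        c3 = self._cap(3, BBox(10, 110, 100, 130))
        matches, lf, lc = match_document([f1, f2], [c1, c3])
        cross = [m for m in matches if m.figure is f2]
        assert cross and cross[0].caption is c3
        assert cross[0].disparity == 2.0  # 1 + |2 - 3|
        assert cross[0].cost == cross[0].distance * cross[0].penalty * 2.0

    def test_penalty_factor_cross_column(self):
        f = self._fig(0, BBox(10, 10, 100, 100), "left")
        c = self._cap(0, BBox(107, 10, 200, 100), "right")
        matches, _, _ = match_document([f], [c])
        m = matches[0]
        assert m.distance == 7.0
        assert m.cost / m.distance == 10.0

    def test_partial_injection(self):
        figs = [self._fig(0, BBox(10 + 120 * i, 10, 100 + 120 * i, 100)) for i in range(3)]
        caps = [self._cap(0, BBox(10, 110, 100, 130))]
        matches, lf, lc = match_document(figs, caps)
        assert len(matches) == 1
        assert len(lf) == 2 and not lc

    def test_empty(self):
        assert match_document([], []) == ([], [], [])


class TestHarvestDocuments:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_documents(self, seed):
        ops, truth = generate_operator_stream(
            2, seed, logos=True, fragmented=True, citations=True
        )
        matches, lf, lc = harvest_document(ops, truth.text_rects)
        assert len(matches) == 2 and not lf
        for m in matches:
            assert m.caption.text == truth.caption_texts[m.figure.page]
            cw, ch = truth.canvas_sizes[m.figure.page]
            assert m.figure.image.shape[:2] == (ch, cw)

    def test_reconstructed_pixels_exact(self):
        ops, truth = generate_operator_stream(1, 3, fragmented=True)
        matches, _, _ = harvest_document(ops, truth.text_rects)
        np.testing.assert_array_equal(matches[0].figure.image, truth.figure_images[0])
        assert matches[0].figure.is_reconstructed


class TestStreamIO:
    def test_jsonl_roundtrip(self, tmp_path):
        ops, _ = generate_operator_stream(1, 5, logos=True)
        path = tmp_path / "doc.jsonl"
        write_operator_stream(ops, path)
        back = read_operator_stream(path)
        assert len(back) == len(ops)
        for a, b in zip(ops, back):
            assert (a.kind, a.page, a.bbox) == (b.kind, b.page, b.bbox)
            if a.kind == "text":
                assert a.text == b.text
            else:
                np.testing.assert_array_equal(a.image, b.image)
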