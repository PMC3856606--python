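# figseg

Segmentation of multi-panel ("compound") biomedical figures into unimodal
panels paired with their subcaptions.

The pipeline combines three independent witnesses of the panel structure:

1. **Caption analysis** — panel-label tokens (`(A)`, `(B-D)`, `c)`, `II.`)
   are lexed from the caption, false positives are removed by a
   sequence-consistency filter with alphabet priority
   (letters > Roman numerals > Arabic numbers), and the caption is split
   into one subcaption per label, duplicating range-token text.
2. **In-image text analysis** — OCR tokens from the figure are classified
   into simple / right-closed / closed label candidates, clustered by
   alphabet and category, and scored by sequence completeness,
   `confidence = 1 / (1 + Gaps * Panels)`.
3. **Pixel analysis** — the figure is binarized with the triangle
   histogram-threshold method, text regions are cleared, 4-connected
   components below 50 px are dropped, and overlapping component boxes
   merge transitively.

The panel count is estimated by consensus of subcaptions and labels, then
by connected-component arbitration, then by a decision-tree fallback.
Missing labels (OCR gaps) are re-inserted by sequence/grid interpolation.
A layout graph links each label to its closest horizontal and vertical
neighbors; each edge induces a perpendicular full-span cut at the pixel
of minimum cost (the summed extent of intersected components along the
edge axis), crossing cuts stop the costlier one at the intersection, and
the resulting faces become panels joined with subcaptions by label.

A harvesting front end recovers figure–caption pairs from a typed
document operator stream (text/image operators with page and bounding
box, as produced by a PDF layout parser): caption paragraphs are merged
by a small state machine, logos outside the page text rectangle are
dropped, fragmented figures are reconstructed at the resolution implied
by their smallest placement scaling, in-text figure citations are removed
by descriptor clustering, and figures are matched to captions by greedy
minimum-cost assignment (`C = d * p * disparity`, cross-column penalty 10).

A synthetic fixture generator (`figseg.synth`) produces figures,
captions, OCR tokens, and operator streams with exact ground truth, so
the whole pipeline is testable without external data or an OCR engine.

## CLI

```sh
# Generate a 2x2 fixture (image + caption + OCR tokens + truth)
figseg synth figure --rows 2 --cols 2 --seed 42 --out fixtures/

# Segment a figure
figseg segment --image fixtures/fig_2x2_s42.png \
               --caption fixtures/fig_2x2_s42.caption.txt \
               --ocr fixtures/fig_2x2_s42.tokens.json \
               --out out/ [--min-area 50] [--model tree.json]

# Split a caption into subcaptions
figseg caption --text-file cap.txt

# Harvest figure-caption pairs from a JSONL operator stream
figseg harvest --operators doc.jsonl --out harvested/ --penalty 10

# Evaluate on synthetic fixtures / retrain the count model
figseg eval --n 100 --seed 0
figseg train-count-model --n 400 --seed 13 --out tree.json
```

Configuration (`--config file`, `key=value` lines): `penalty_factor=10`,
`min_cc_area=50`, `connectivity=4`, `text_box_padding=0`,
`alphabet_priority=latin,roman,arabic`.

## Layout

```
src/figseg/
  geometry.py      axis-aligned boxes, distance/overlap/union
  labels.py        label alphabets and positions
  caption_seg.py   caption lexing, filtering, subcaption splitting
  inimage_text.py  OCR-token label recovery and confidence scoring
  image_prep.py    triangle threshold, binarization, components
  panel_seg.py     count estimation, gap filling, layout-graph cuts
  harvest.py       operator-stream FSM, logo filter, matcher
  synth.py         synthetic fixtures with ground truth
  pipeline.py      per-figure orchestration and corpus evaluation
  cli.py           click command line
```
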