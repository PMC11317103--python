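# platewatch

Passive food-safety surveillance from restaurant reviews.

Regulators in settings without routine inspection disclosure have little
signal about which food establishments pose a public-health risk. Consumer
reviews are a continuously generated, freely available proxy: complaints
about pests, undercooked food, or stomach aches are food-safety signals
hiding in sentiment data. `platewatch` turns a stream of hygiene-labelled
restaurant reviews into per-restaurant risk assessments that a food-safety
authority can act on, with the noise-screening needed to make such passive
signals credible.

## The method

For each eligible restaurant (≥ 1000 reviews, listed > 2 years), over an
assessment window (default: the most recent 12 months):

1. **Duplicate screening.** All pairs of hygiene reviews are compared with
   three lexical pattern metrics — type-token ratio (TTR = unique/total
   tokens), Jaccard similarity of word sets, and shared-bigram count. A
   pair with Jaccard ≥ 0.6 or ≥ 3 shared bigrams is treated as plausibly
   same-author; within each flagged cluster only the earliest review is
   kept. A restaurant losing more than half its hygiene reviews to
   duplicates is excluded as a data-quality failure.
2. **Temporal chance screen.** Monthly negative-hygiene counts are tested
   against expectations proportional to monthly review volume with a
   chi-square goodness-of-fit test (dof = months − 1). Small p-values mark
   genuine temporal clustering; months with standardized residual > 2 are
   annotated as spikes.
3. **Causality Assessment Index.**

   CAI = (negative hygiene reviews) / (positive hygiene reviews)

   CAI > 1 — negative hygiene sentiment outnumbering positive — establishes
   a genuine food-safety concern.
4. **Severity Assessment Score.** Negative reviews are classified into
   eight sub-aspects derived from the FSSAI inspection checklist
   (cleanliness of the dining area, food handling, food packaging, pest
   control, external objects in food, infrastructure upkeep,
   undercooked/rotten/smelly food, unintended health outcomes) by a keyword
   lexicon, then

   SAS = Σ (negative reviews in sub-aspect × sub-aspect weight)

   with default weights 2, 2, 1, 3, 3, 2, 3 and 4 points respectively.
   SAS maps to five risk bands: ≤ 5 low, 6–10 slightly higher, 11–15 high,
   16–20 higher, > 20 highest risk to public health.
5. **Reporting.** Per-restaurant assessments, category aggregates, and a
   GeoJSON map whose coordinates are randomly displaced by 5–10 m to
   protect establishment identity.

A seeded synthetic-suburb generator with exact ground truth (planted
elevated-risk restaurants, spike months, duplicate clusters) makes every
stage testable end to end.

## Worked example

```bash
python examples/worked_scoring.py
```

```
Buffet          CAI 3.00  SAS 14  -> HIGH
Casual dining   CAI 1.50  SAS 17  -> HIGHER
Quick service   CAI 3.00  SAS  6  -> SLIGHTLY_HIGHER
Food truck      CAI 2.00  SAS 17  -> HIGHER
```

Each line scores one illustrative restaurant: the buffet drew 6 negative
and 2 positive hygiene reviews (CAI 3.00, causality established), and its
sub-aspect tally (3 cleanliness, 1 handling, 2 undercooked) weighs in at
SAS 14, a high risk to public health. The temporal screen example:

```bash
python examples/temporal_screen.py
```

```
positive  chi2 =  5.02  dof = 7  p = 0.658  verdict = chance  spikes: none
negative  chi2 = 34.56  dof = 7  p = 1.35e-05  verdict = genuine  spikes: Jun
```

The June spike in negative reviews (15 of 30) is far beyond what review
volume explains; the positive series fluctuates by chance. See
`examples/pattern_screen.py` (same-author screening) and
`examples/synthetic_suburb.py` (full pipeline on a synthetic suburb with
recovery metrics against ground truth).

## Command line

A thin CLI wraps the library: `platewatch screen | score | report |
export-geo | simulate`. For example:

```bash
platewatch simulate --seed 3 --out sim/            # synthetic suburb
platewatch report --reviews sim/reviews.csv --profiles sim/profiles.csv --out out/
platewatch export-geo --reviews sim/reviews.csv --profiles sim/profiles.csv \
    --seed 2 --out map.geojson
```

## Layout

- `src/platewatch/` — library: `text_metrics`, `lexicon`, `temporal`,
  `scoring`, `pipeline`, `synth`, `config`, `cli`
- `src/platewatch/data/default_lexicon.yaml` — the shipped sub-aspect lexicon
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — unit, property and acceptance tests
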