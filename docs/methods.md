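# Methods

## Problem setting

`platewatch` implements a passive surveillance framework for food safety:
instead of inspections or consumer complaints filed with a regulator, the
data source is the stream of restaurant reviews that consumers already
write. Upstream aspect-based sentiment analysis is assumed to have labelled
each review's *hygiene aspect* as positive or negative; this package treats
those labels as input (an optional keyword fallback labeller exists for
unlabelled data, and is flagged as lower-fidelity in report provenance).
The package's job is everything after sentiment: separating genuine signals
from noise, attributing causality, quantifying severity, and reporting.

## Eligibility

Restaurants enter assessment with at least 1000 total reviews and a listing
age above two years (both configurable). The volume floor ensures enough
hygiene-aspect reviews for ratios to be meaningful; the age floor guards
against new listings whose review base is dominated by launch-period
promotion.

## Duplicate screening (pattern recognition)

A single motivated author posting near-copies of one complaint can fabricate
a signal. Every pair of a restaurant's hygiene reviews in the window is
compared exactly (no approximate shortcut — streams are at most a few
hundred reviews) on:

- **Type-token ratio** (unique/total tokens) — a lexical-diversity profile,
  reported per text; undefined on empty text.
- **Jaccard similarity** — |A ∩ B| / |A ∪ B| over unique word sets.
- **Bigram overlap** — count of distinct adjacent word pairs shared by both
  texts. Shared phrasing is a far stronger same-author cue than shared
  vocabulary.

Tokenization is lowercase, punctuation stripped to spaces, whitespace
split; alphanumeric tokens like "50off" survive. The policy is deliberately
simple and configurable — pattern counts depend on it, so it must be
auditable.

A pair is flagged same-author when Jaccard ≥ 0.6 **or** bigram overlap ≥ 3
(both configurable). The defaults separate clearly different-author pairs
(typical Jaccard ≈ 0.1–0.2, overlap 0) from verbatim and lightly mutated
copies (Jaccard ≥ 0.8, overlap ≫ 3); values between are genuinely ambiguous
and the thresholds are conservative in the flagging direction. Flagged
pairs are merged into connected components (union-find); the earliest
review by date survives, ties broken by input order for determinism.
Removed reviews get the `excluded_duplicate` disposition. A restaurant
losing more than 50% of its hygiene reviews this way is excluded outright
as a data-quality failure rather than assessed on the residue.

Like any textual screen, this one has a small false-positive floor: two
independently written short reviews occasionally share three bigrams by
coincidence (empirically ~1 per 2000 reviews on synthetic streams). This is
accepted behavior, not a bug; raising the bigram threshold trades it
against missed near-copies.

## Temporal chance screen

For each restaurant the window is bucketed into calendar months (empty
months included). The negative-hygiene series is tested against the null
that negatives occur in proportion to each month's total review volume:

    expected[m] = total[m] × (Σ negatives / Σ totals)
    X² = Σ (obs[m] − expected[m])² / expected[m],  dof = months − 1

with an upper-tail p-value from the χ² distribution. p < α (default 0.05)
yields verdict **genuine** — the clustering is not attributable to chance —
and months with standardized residual (obs − exp)/√exp above 2.0 are
annotated as spikes. p ≥ α yields **chance**, with no spike annotation.
CAI is still computed either way; the temporal verdict contextualizes the
signal rather than gating it, while the duplicate-fraction rule above is
the only exclusion path.

Numerical notes. The statistic is exactly 0 under perfect proportionality,
and scales linearly when all counts and totals are scaled by the same
factor (χ²(k·obs, k·tot) = k·χ²(obs, tot)). Expected cells below 1 log a
small-sample warning but do not abort. Because the test conditions on the
realized total count, it is exactly calibrated under its own null (total
negatives distributed across months ∝ volume: measured type-I ≈ 0.045 at
α = 0.05 over 2000 simulations) and mildly *conservative* under
unconditional month-by-month binomial sampling (measured ≈ 0.026, the
usual (1 − p) variance effect); it is never anti-conservative. An all-zero
negative series short-circuits to verdict chance with statistic 0.

## Sub-aspect classification

Negative hygiene reviews are classified into eight sub-aspects derived from
the FSSAI catering-inspection checklist, plus an added
unintended-health-outcome category (direct consumer reports of vomiting,
acidity, etc. can flag an emergency and sit outside the checklist). The
shipped lexicon (`data/default_lexicon.yaml`) maps each sub-aspect to
exemplar phrases and single-word triggers; matching is normalized
phrase/substring matching with a light stem rule (trigger "rat" matches
"rats"; suffixes s/es/d/ed/ing). Multi-label matches are allowed and each
matched sub-aspect is tallied. Negative reviews with no lexicon hit still
count toward the CAI numerator (polarity is upstream's call) but contribute
nothing to severity. Positive reviews are never sub-classified.

A rule-based polarity override repairs a known upstream failure mode:
reviews labelled positive because of food-quality adjectives ("fresh",
"crispy") while actually reporting stale or spoiled food. The upstream
positive flips to negative when a spoilage cue ("stale", "week ago",
"hard", "fungus"…) co-occurs with a food noun and no positive cue is
present; override events are recorded in the review's disposition path.

The lexicon classifier is a deterministic stand-in for the manual
two-reader classification this kind of program would run at desk scale; it
is auditable from the lexicon file but will miss paraphrases a human
catches. On synthetic reviews generated from the lexicon itself its recall
is exact, which is what the recovery tests exploit — and precisely why
those tests say nothing about recall on free-text reviews.

## CAI, SAS and grading

CAI = negatives/positives over the cleaned window. CAI > 1 (strictly)
establishes causality; a restaurant with negatives but zero positives
reports an infinite CAI (flagged, treated as causal, excluded from means);
zero hygiene reviews is not assessable. CAI is displayed at two decimals,
kept exact internally.

Severity is assessed only upon establishment of causality. SAS is the
integer dot product of sub-aspect counts and weights. Default weights
(points per negative review): cleanliness 2, external objects 3, handling
2, packaging 1, pest control 3, undercooked/rotten/smelly 3, upkeep 2,
unintended health outcome 4 — proportional to the checklist's emphasis on
each area; one review in every sub-aspect scores 20. An alternate preset
`worked_example_variant` (cleanliness 1, upkeep 1) is shipped because the
framework's own per-category worked examples are internally consistent
only under that weighting; the two presets are never merged and the
default follows the stated weights. Grade bands (upper edges configurable):
≤ 5 low, 6–10 slightly higher, 11–15 high, 16–20 higher, > 20 highest.
Restaurants without causality, or excluded, carry `NOT_GRADED`.

## Reporting and geo export

Category summaries report restaurant counts, qualified counts, counts with
CAI > 1, mean finite CAI, and mean SAS over graded restaurants only. The
GeoJSON export displaces each point by a uniformly random distance in
[5, 10] m at a uniformly random bearing (seeded) so establishments cannot
be re-identified from the map; displacement uses a local equirectangular
approximation on the mean-radius sphere, whose error at 10 m is far below
a millimeter. Causal restaurants are styled distinctly with marker size
increasing in SAS. Output is byte-identical for a fixed seed.

## Synthetic suburb generator

The generator emulates the data regime the framework targets: a suburb of
156 listed restaurants of which 93 are eligible (63 casual dining, 2 fine
dining, 4 buffet, 13 quick service, 11 food truck/dhaba), 12 monthly
buckets, per-restaurant monthly volumes Poisson with mean 45 (configurable,
fixed totals also supported), hygiene-negative baseline 10% of monthly
volume and hygiene-positive 12% — the negative baseline matching the
illustrative monthly stream's flat months, the positive rate its observed
average. Planted elevated-risk restaurants set the negative rate to a
target multiple of the positive rate (3:1 is the strong-effect condition);
spike events multiply one month's negative rate; duplicate clusters emit a
base negative review plus verbatim or token-mutated copies dated after it.

Texts are template-based: a short sub-aspect trigger embedded in shuffled
neutral filler. This keeps ground truth exact — the planted sub-aspect of
every negative is recoverable by the lexicon classifier with recall 1 —
at the cost of realism: synthetic reviews have no paraphrase, misspelling,
code-switching or topic drift, so passing recovery tests demonstrate the
pipeline's mechanics, not NLP robustness on real reviews. Filler words are
checked against the lexicon so no filler can trigger a classification;
generation phrases are capped at two tokens so independently generated
reviews do not systematically trip the same-author screen.

`ground_truth_compare` scores a report against the generator's records:
causality sensitivity/specificity against the planted regime, duplicate
detection rate, spike-month recall, and exact sub-aspect count agreement.
Under the null (no planted effects) the rate of CAI > 1 is governed by the
binomial race between negatives (10%) and positives (12%) among a
restaurant's hygiene reviews — the analytic bound the false-positive test
checks against. At these rates a null restaurant exceeds CAI 1 roughly a
fifth of the time at typical volumes; the framework's answer to that noise
is the severity grade and the temporal context, not the causality flag
alone.

## Problem sizes in tests

The default test run uses suburbs of 4–10 restaurants over 6–12 months
(a few thousand reviews), 2000-series null calibrations, and 50-seed
power replicates; the full 156-restaurant suburb is exercised at reduced
monthly volume for the eligibility check. These sizes were chosen to keep
every statistical check well-powered at desk scale.

## Known limitations

- The hygiene polarity labels are upstream input; nothing here validates
  them beyond the narrow spoilage-cue override.
- The lexicon classifier is exemplar-based; its recall on real free text is
  unmeasured and surely below 1.
- The same-author screen detects textual duplication only — coordinated
  distinct-text campaigns and cross-restaurant duplicates are out of scope.
- CAI compares counts, not rates: it inherits whatever selection bias
  review-writing has, and a 3:1 ratio on 4 reviews is weaker evidence than
  on 40, which the index does not express.
- Temporal screening assumes monthly bucketing in local time with no
  seasonal adjustment; scan statistics and change-point methods are out of
  scope.
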