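"""Same-author screening of two review texts.

Compares two reviews of the same restaurant with the three pattern
metrics: type-token ratio (lexical diversity of each text), Jaccard
similarity of their word sets, and the count of shared bigrams.  High
Jaccard or several shared bigrams suggest one author posting near-copies,
which the surveillance pipeline excludes as noise.
"""

import datetime as dt

from platewatch import screen_pair
from platewatch.types import ReviewRecord

A = ("It was my first time to taste this dish and totally satisfied. I cut down "
     "that 5th star because it lacks spice and realized that there are spicy "
     "sauces that can be added to the dish, after our plates were empty. "
     "Good ambience and service.")
B = ("Whoever people looking for delicious food and humble service at the place "
     "of absolute sizzler only i can say that I had good experience there "
     "especially i heard about that discount on ala carte menu and on the buffet "
     "50off that was really cool and great dine to have, at that reasonable "
     "price number of buffet items which were making us feel tasty thanks to "
     "absolute Sizzlers ....")

today = dt.date.today()
pair = screen_pair(
    ReviewRecord("R1", today, A),
    ReviewRecord("R1", today, B),
)
print(f"TTR A           : {pair.ttr_a:.2f}")
print(f"TTR B           : {pair.ttr_b:.2f}")
print(f"Jaccard         : {pair.jaccard:.2f} ({pair.common_word_count}/{pair.union_word_count} words)")
print(f"Bigram overlap  : {pair.bigram_overlap}")
print(f"Same author?    : {pair.same_author_flag}")
print("\nHigh diversity, low word overlap and zero shared bigrams: these two")
print("reviews were plausibly written by different people, so both are kept.")
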