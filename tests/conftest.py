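import datetime as dt

import pytest

from platewatch import load_lexicon
from platewatch.types import ReviewRecord, Polarity

# The two illustrative review sentences used throughout the pattern-
# recognition worked example (high lexical diversity, low overlap, zero
# shared bigrams -> different authors).
SENTENCE_1 = (
    "It was my first time to taste this dish and totally satisfied. I cut "
    "down that 5th star because it lacks spice and realized that there are "
    "spicy sauces that can be added to the dish, after our plates were "
    "empty. Good ambience and service."
)
SENTENCE_2 = (
    "Whoever people looking for delicious food and humble service at the "
    "place of absolute sizzler only i can say that I had good experience "
    "there especially i heard about that discount on ala carte menu and on "
    "the buffet 50off that was really cool and great dine to have, at that "
    "reasonable price number of buffet items which were making us feel "
    "tasty thanks to absolute Sizzlers ...."
)

# Eight months of illustrative temporal-assessment data for one casual
# dining restaurant: monthly totals, hygiene-positive and hygiene-negative
# counts, with a June spike in negatives.
ILLUSTRATION_MONTHS = ("January", "February", "March", "April", "May", "June", "July", "August")
ILLUSTRATION_TOTALS = (50, 40, 60, 45, 55, 30, 50, 40)
ILLUSTRATION_POSITIVE = (4, 7, 6, 8, 5, 3, 4, 3)
ILLUSTRATION_NEGATIVE = (5, 4, 6, 4, 5, 15, 5, 4)

# Worked per-category scoring example: hygiene review counts and sub-aspect
# tallies for one restaurant of each category with CAI above one.
WORKED_EXAMPLES = {
    "BUFFET": {
        "n_negative": 6, "n_positive": 2,
        "counts": {"CLEANLINESS_DINING": 3, "FOOD_HANDLING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 2},
    },
    "CASUAL_DINING": {
        "n_negative": 6, "n_positive": 4,
        "counts": {"FOOD_HANDLING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 5},
    },
    "QUICK_SERVICE": {
        "n_negative": 3, "n_positive": 1,
        "counts": {"EXTERNAL_OBJECTS": 1, "FOOD_PACKAGING": 1, "UPKEEP_INFRA": 1},
    },
    "FOOD_TRUCK_DHABA": {
        "n_negative": 6, "n_positive": 3,
        "counts": {"CLEANLINESS_DINING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 5},
    },
}


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def make_review():
    def _make(text, polarity=Polarity.NEGATIVE, restaurant_id="R1",
              date=dt.date(2025, 6, 15), review_id=None):
        return ReviewRecord(
            restaurant_id=restaurant_id, date=date, text=text,
            hygiene_polarity=polarity, review_id=review_id,
        )
    return _make
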