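"""Score one restaurant per category: CAI, SAS and the risk grade.

Inputs are the hygiene review counts and sub-aspect tallies of four
illustrative restaurants (one per category with more negative than positive
hygiene sentiment).  CAI is the negative:positive ratio — above 1 it
establishes a genuine concern; SAS weights each sub-aspect's negative count
by its checklist-derived severity; the grade maps SAS to five risk bands.
"""

from platewatch import compute_cai, compute_sas, grade_sas
from platewatch.types import SubAspectCounts

RESTAURANTS = {
    "Buffet": (6, 2, {"CLEANLINESS_DINING": 3, "FOOD_HANDLING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 2}),
    "Casual dining": (6, 4, {"FOOD_HANDLING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 5}),
    "Quick service": (3, 1, {"EXTERNAL_OBJECTS": 1, "FOOD_PACKAGING": 1, "UPKEEP_INFRA": 1}),
    "Food truck": (6, 3, {"CLEANLINESS_DINING": 1, "UNDERCOOKED_ROTTEN_SMELLY": 5}),
}

for name, (neg, pos, counts) in RESTAURANTS.items():
    cai = compute_cai(neg, pos)
    sas = compute_sas(SubAspectCounts(counts))
    print(f"{name:14s}  CAI {cai:.2f}  SAS {sas:2d}  -> {grade_sas(sas).value}")

print("\nCAI > 1 means negative hygiene reviews outnumber positive ones;")
print("SAS bands: <=5 low, 6-10 slightly higher, 11-15 high, 16-20 higher, >20 highest risk.")
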