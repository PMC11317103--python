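# Default hygiene sub-aspect lexicon.
#
# Eight sub-aspects derived from the FSSAI catering-inspection checklist,
# plus the unintended-health-outcome category added because direct consumer
# reporting of a health outcome can signal a public-health emergency.
# Each entry lists exemplar phrases and short single-word triggers; triggers
# are matched with a light stem rule (e.g. "rat" also matches "rats").
# Every phrase belongs to exactly one sub-aspect.

CLEANLINESS_DINING:
  - unclean tables
  - dirty floors
  - dirty
  - unclean
  - filthy
FOOD_HANDLING:
  - dipped hands in drinks
  - waiter looked unhealthy
  - served with bare hands
  - no gloves
  - gloves
  - unwashed
FOOD_PACKAGING:
  - wrapped food in old newspaper
  - container was leaking
  - leaking
  - badly packed
PEST_CONTROL:
  - saw a rat in the washroom
  - found a fly in the soup
  - rat
  - fly
  - cockroach
  - insect
EXTERNAL_OBJECTS:
  - stone in the rice
  - hair in the curry
  - hair
  - stone
  - plastic piece
UPKEEP_INFRA:
  - poorly ventilated
  - ac not working
  - ventilated
  - damp
  - broken chairs
UNDERCOOKED_ROTTEN_SMELLY:
  - chicken was undercooked
  - cheese was smelly
  - bread had fungus developed
  - undercooked
  - stale
  - smelly
  - fungus
  - rotten
  - burnt
UNINTENDED_HEALTH_OUTCOME:
  - vomited after eating mayonnaise
  - stomach ache due to biryani
  - vomit
  - acidity
  - stomach ache
  - loose motion
  - food poisoning
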