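"""Closed categorical vocabularies shared across the models.

All tabular inputs and model parameter bundles use these spellings.  Age
groups are adult bins matching census cross-tabulations; the extra "<18"
level exists only in the house-type model (whose source survey includes
minors) and is never consumed by the risk engine, which is adults-only.
"""

AGE_GROUPS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")
AGE_REF = "45-54"
HOUSING_AGE_GROUPS = ("<18",) + AGE_GROUPS

SEXES = ("male", "female")
SEX_REF = "female"

RACES = ("white", "black", "asian", "native", "islander", "other")
RACE_REF = "white"
# the house-type survey does not distinguish Pacific islanders
HOUSING_RACES = ("white", "black", "asian", "native", "other")

POVERTY = ("below", "above")
POVERTY_REF = "above"

REGIONS = ("Northeast", "Midwest", "South", "West")
RADON_REGION_REF = "Midwest"
HOUSING_REGION_REF = "South"

GEO_POTENTIAL = ("Low", "Medium", "High")
GEO_REF = "Low"

HOUSE_TYPES = ("detached_with_basement", "attached", "crawl_space", "slab",
               "other_detached")
HOUSE_TYPE_REF = "detached_with_basement"
# non-reference outcomes of the multinomial house-type model, fixed order
HOUSE_TYPE_OUTCOMES = ("attached", "crawl_space", "slab", "other_detached")
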