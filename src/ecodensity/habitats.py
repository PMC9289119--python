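"""Habitat and diet taxonomies used throughout the package.

Three class systems coexist:

* the 12 biotope categories recorded in the field at each census point;
* the 7 aggregated biotope classes the analysis works in;
* the 15 habitat-preference and 9 diet-preference classes of the
  European-scale species trait catalogue, from which specialization
  indices are computed.

The field classes and the preference classes each map onto the 7
aggregated classes, so that per-point habitat composition and per-species
suitability live in the same space.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Aggregated analysis classes (the working space)

AGGREGATED_CLASSES: list[str] = [
    "deciduous_forest",
    "coniferous_forest",
    "mixed_forest",
    "shrub",
    "open",
    "water",
    "urban",
]

# ---------------------------------------------------------------------------
# Field census biotope categories (recorded within 100 m of each point)

FIELD_CLASSES: list[str] = [
    "coniferous_forest",
    "deciduous_forest",
    "mixed_forest",
    "shrubs",
    "meadows",
    "fields",
    "alpine",
    "rocks",
    "water_bodies",
    "marshes",
    "urban",
    "suburban",
]

#: meadows, fields, alpine and rocks collapse to open habitats; water bodies
#: and marshes to water; urban and suburban to urban.
FIELD_TO_AGGREGATED: dict[str, str] = {
    "coniferous_forest": "coniferous_forest",
    "deciduous_forest": "deciduous_forest",
    "mixed_forest": "mixed_forest",
    "shrubs": "shrub",
    "meadows": "open",
    "fields": "open",
    "alpine": "open",
    "rocks": "open",
    "water_bodies": "water",
    "marshes": "water",
    "urban": "urban",
    "suburban": "urban",
}

# ---------------------------------------------------------------------------
# Species-preference taxonomies (European-scale trait catalogue)

HABITAT_PREFERENCE_CLASSES: list[str] = [
    "coniferous_forest",
    "deciduous_forest",
    "woodland",
    "shrub",
    "savanna",
    "tundra",
    "grassland",
    "reed",
    "mountain_meadows",
    "swamp",
    "desert",
    "freshwater",
    "marine",
    "rocks",
    "human_settlements",
]

#: Rock, savanna, tundra, grassland, mountain and desert preferences count as
#: open biotopes; reed, swamp, freshwater and marsh-like classes as water;
#: settlements as urban.  Woodland is treated as mixed forest and marine as
#: water (both overridable by passing a custom map downstream).
PREFERENCE_TO_AGGREGATED: dict[str, str] = {
    "coniferous_forest": "coniferous_forest",
    "deciduous_forest": "deciduous_forest",
    "woodland": "mixed_forest",
    "shrub": "shrub",
    "savanna": "open",
    "tundra": "open",
    "grassland": "open",
    "mountain_meadows": "open",
    "desert": "open",
    "rocks": "open",
    "reed": "water",
    "swamp": "water",
    "freshwater": "water",
    "marine": "water",
    "human_settlements": "urban",
}

DIET_CLASSES: list[str] = [
    "folivore",
    "frugivore",
    "granivore",
    "insectivore",
    "other_invertebrates",
    "piscivore",
    "other_vertebrates",
    "scavenger",
    "omnivore",
]

#: Nest placement categories; ground (G) is the reference level in models.
#: Closed-arboreal nests are merged into OA with open-arboreal ones.
NEST_TYPES: list[str] = ["G", "GC", "H", "OA"]

#: Census point radius is 100 m, so each point covers pi * (0.1 km)^2 hectares.
POINT_AREA_HA: float = 3.14159

#: Aggregation map that leaves classes unchanged (synthetic communities carry
#: preferences directly over the aggregated classes).
IDENTITY_AGGREGATION: dict[str, str] = {c: c for c in AGGREGATED_CLASSES}
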