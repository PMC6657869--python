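"""NLCD-style land-cover legend used throughout the package.

Codes follow the National Land Cover Database numbering so that synthetic
rasters read naturally to anyone used to NLCD products: three forest
classes, four developed-intensity classes, two agriculture classes and a
residual "other" class (barren).
"""

DEVELOPED_OPEN = 21
DEVELOPED_LOW = 22
DEVELOPED_MEDIUM = 23
DEVELOPED_HIGH = 24
BARREN = 31
DECIDUOUS_FOREST = 41
EVERGREEN_FOREST = 42
MIXED_FOREST = 43
PASTURE_HAY = 81
CULTIVATED_CROPS = 82

DEVELOPED = frozenset({DEVELOPED_OPEN, DEVELOPED_LOW, DEVELOPED_MEDIUM, DEVELOPED_HIGH})
FOREST = frozenset({DECIDUOUS_FOREST, EVERGREEN_FOREST, MIXED_FOREST})
AGRICULTURE = frozenset({PASTURE_HAY, CULTIVATED_CROPS})
OTHER = frozenset({BARREN})

LEGEND = frozenset(DEVELOPED | FOREST | AGRICULTURE | OTHER)

#: forest groups selectable as a species' habitat affinity; ``total`` is the
#: fallback for generalists or species with unknown affinity
FOREST_GROUPS = {
    "deciduous": frozenset({DECIDUOUS_FOREST}),
    "evergreen": frozenset({EVERGREEN_FOREST}),
    "mixed": frozenset({MIXED_FOREST}),
    "total": FOREST,
}

HABITAT_LABELS = {
    DECIDUOUS_FOREST: "deciduous forest",
    EVERGREEN_FOREST: "coniferous forest",
    MIXED_FOREST: "mixed forest",
}
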