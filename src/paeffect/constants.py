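"""Controlled vocabularies and fixed thresholds shared across the pipeline."""

# The eight land-use classes recorded for every sampled site, in the order
# used as factor levels (primary vegetation is the model reference level).
LAND_USES: tuple[str, ...] = (
    "primary vegetation",
    "mature secondary vegetation",
    "intermediate secondary vegetation",
    "young secondary vegetation",
    "plantation",
    "cropland",
    "pasture",
    "urban",
)

# Three within-land-use human-use intensity levels (reference: minimal).
INTENSITIES: tuple[str, ...] = ("minimal", "light", "intense")

# Protected-area management groups, ordered from reference level upward and,
# among protected groups, from least to most restrictive management.
MANAGEMENT_GROUPS: tuple[str, ...] = ("unprotected", "III-VI", "unknown", "I-II")

# IUCN categories collapsing onto the management groups above.
IUCN_TO_GROUP: dict[str, str] = {
    "Ia": "I-II",
    "Ib": "I-II",
    "II": "I-II",
    "III": "III-VI",
    "IV": "III-VI",
    "V": "III-VI",
    "VI": "III-VI",
}

SIZE_AGE_CLASSES: tuple[str, ...] = (
    "unprotected",
    "young-small",
    "young-large",
    "old-small",
    "old-large",
)

# Protected-area age (years since establishment) below which a PA counts as
# "young", and area (km^2) below which it counts as "small".
YOUNG_AGE_YEARS: float = 20.0
SMALL_AREA_KM2: float = 400.0
# The sampled PAs' ranges; values beyond these are accepted with a warning.
MAX_TYPICAL_AGE_YEARS: float = 85.0
MAX_TYPICAL_AREA_KM2: float = 12_000.0

# Year of the protected-area database snapshot; ages are computed against it.
DEFAULT_REFERENCE_YEAR: int = 2014

# Latitude of the tropics of Cancer/Capricorn; |lat| <= this is "tropical".
TROPIC_LATITUDE: float = 23.43665

TAXONOMIC_GROUPS: tuple[str, ...] = ("plants", "invertebrates", "vertebrates")

MEASURES: tuple[str, ...] = (
    "richness",
    "abundance",
    "rarefied_richness",
    "endemicity",
)
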