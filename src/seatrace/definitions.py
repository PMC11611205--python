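"""Shared vocabulary: product groups, geo-regions, column schemas.

Quantities are tonnes live weight throughout unless a column name says
otherwise (``product_weight_t`` is tonnes *product* weight).  Files whose
headers declare other units (e.g. ``production_kg``) fail schema validation
rather than being converted silently.
"""

from __future__ import annotations

#: The eight coarse ISSCAAP product groups used by national food balance
#: sheets for fish and fishery products.  This set is closed: balance rows
#: and classified trade records must use exactly these labels.
ISSCAAP_GROUPS: tuple[str, ...] = (
    "Freshwater & Diadromous Fish",
    "Pelagic Fish",
    "Demersal Fish",
    "Marine Fish NEI",
    "Crustaceans",
    "Cephalopods",
    "Molluscs excl. Cephalopods",
    "Aquatic Animals NEI",
)

#: Fixed label set for the UN-geo-region-style categorical covariate used by
#: the gap-filling regression (synthetic worlds cycle through these).
GEO_REGIONS: tuple[str, ...] = (
    "Northern Europe",
    "Eastern Asia",
    "South America",
    "Sub-Saharan Africa",
    "Oceania",
)

#: Label for the all-groups aggregate row in consumption results.
AGGREGATE = "AGGREGATE"

BALANCE_COLUMNS = (
    "country_id",
    "product_group",
    "year",
    "production_t",
    "imports_t",
    "exports_t",
)
#: optional balance column (reported food supply, live weight)
BALANCE_OPTIONAL = ("food_supply_t",)

TRADE_COLUMNS = (
    "reporter_id",
    "partner_id",
    "direction",
    "product_code",
    "product_desc",
    "year",
    "product_weight_t",
    "is_food",
    "farmed_flag",
)

HARMONIZATION_COLUMNS = ("raw_name", "canonical_id", "kind", "members")

FARMED_FLAGS = ("farmed", "not_farmed", "unknown")
DIRECTIONS = ("import", "export")
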