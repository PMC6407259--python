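"""The 41-trait PTA catalogue used for Holstein association scans.

Traits are grouped into four blocks — production (6), reproduction (9),
health (8) and body conformation / type (18) — which also drive the default
block-correlation structure of the phenotype simulator.
"""

from __future__ import annotations

PRODUCTION_TRAITS = [
    "Milk", "Fat", "Protein", "Fat_Percent", "Pro_Percent", "Net_Merit",
]

REPRODUCTION_TRAITS = [
    "Prod_Life", "Sire_Calv_Ease", "Dtr_Calv_Ease", "Sire_Still_Birth",
    "Dtr_Still_Birth", "Dtr_Preg_Rate", "Heifer_Conc_Rate", "Cow_Conc_Rate",
    "gestleng",
]

HEALTH_TRAITS = [
    "SCS", "CALC", "DSAB", "KETO", "MAST", "METR", "RETP", "livability",
]

TYPE_TRAITS = [
    "final_score", "stature", "strength", "dairy_form", "foot_angle",
    "Rear_legs_side", "body_depth", "rump_angle", "rump_width",
    "Fore_udder_att", "rear_ud_height", "udder_depth", "udder_cleft",
    "Front_teat_pla", "teat_length", "Rear_legs_rear", "Feet_and_legs",
    "Rear_teat_pla",
]

TRAIT_BLOCKS: dict[str, list[str]] = {
    "production": PRODUCTION_TRAITS,
    "reproduction": REPRODUCTION_TRAITS,
    "health": HEALTH_TRAITS,
    "type": TYPE_TRAITS,
}

ALL_TRAITS: list[str] = (
    PRODUCTION_TRAITS + REPRODUCTION_TRAITS + HEALTH_TRAITS + TYPE_TRAITS
)

BLOCK_SIZES = tuple(len(v) for v in TRAIT_BLOCKS.values())  # (6, 9, 8, 18)

assert len(ALL_TRAITS) == 41


def block_of(trait: str) -> str:
    """Return the block name a trait belongs to."""
    for block, names in TRAIT_BLOCKS.items():
        if trait in names:
            return block
    raise KeyError(trait)
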