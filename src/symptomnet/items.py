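"""The 12 EURO-D depressive-symptom items.

The EURO-D scale is a 12-item binary instrument for depressive symptoms in
older Europeans. Item order is fixed throughout the package: symptom vectors,
CSV columns and pair enumerations all follow this canonical order.
"""

from __future__ import annotations

#: Short codes in canonical EURO-D order. Used as CSV column stems
#: (``dep_w6`` ... ``tea_w8``) and as network node identifiers.
ITEM_CODES: tuple[str, ...] = (
    "dep", "pes", "sui", "gui", "sle", "int",
    "irr", "app", "fat", "con", "enj", "tea",
)

#: Human-readable item names, keyed by code.
ITEM_NAMES: dict[str, str] = {
    "dep": "depressed mood",
    "pes": "pessimism",
    "sui": "suicidality",
    "gui": "guilt",
    "sle": "sleep",
    "int": "interest",
    "irr": "irritability",
    "app": "appetite",
    "fat": "fatigue",
    "con": "concentration",
    "enj": "enjoyment",
    "tea": "tearfulness",
}

N_ITEMS = len(ITEM_CODES)

#: All C(12,2) = 66 unordered item pairs, in canonical order.
ITEM_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (ITEM_CODES[i], ITEM_CODES[j])
    for i in range(N_ITEMS)
    for j in range(i + 1, N_ITEMS)
)


def item_index(code: str) -> int:
    """Position of an item code in the canonical order."""
    try:
        return ITEM_CODES.index(code)
    except ValueError:
        raise KeyError(f"unknown EURO-D item code: {code!r}") from None


def symptom_columns(wave: int) -> list[str]:
    """CSV column names for one wave's 12 symptom indicators."""
    if wave not in (6, 8):
        raise ValueError(f"wave must be 6 or 8, got {wave}")
    return [f"{c}_w{wave}" for c in ITEM_CODES]
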