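"""Scoring of the self-injury function questionnaires.

Two instruments feed the correlation analyses:

* **OSI** (Ottawa Self Injury Inventory, functions section): items on a
  0-4 scale, summed into four subscales — internal emotional regulation
  (8 items, 0-32), external emotional regulation (3 items, 0-12), social
  influence (9 items, 0-36) and sensation seeking (3 items, 0-12).
* **ISAS** (Inventory of Statements About Self-Injury, section II): 39
  items on a 0-2 scale, three per each of 13 functions (each function
  scored 0-6). The functions aggregate into an interpersonal factor
  (8 functions) and an intrapersonal factor (5 functions).

Item wording is not reproduced here; item identifiers are positional
(``item_01`` ...), and the item-to-subscale map is configuration data
that can be overridden from a TSV file.
"""

from __future__ import annotations

import pandas as pd

#: Default OSI item map: 23 function items in positional order.
OSI_SUBSCALES: dict[str, list[str]] = {
    "internal_regulation": [f"item_{i:02d}" for i in range(1, 9)],
    "external_regulation": [f"item_{i:02d}" for i in range(9, 12)],
    "social_influence": [f"item_{i:02d}" for i in range(12, 21)],
    "sensation_seeking": [f"item_{i:02d}" for i in range(21, 24)],
}

OSI_ITEM_MAX = 4
ISAS_ITEM_MAX = 2

#: ISAS function order; item k (1-based) belongs to function (k-1) mod 13,
#: so each function is scored from three items spaced 13 apart.
ISAS_FUNCTIONS: tuple[str, ...] = (
    "affect_regulation", "interpersonal_boundaries", "self_punishment",
    "self_care", "anti_dissociation", "anti_suicide", "sensation_seeking",
    "peer_bonding", "interpersonal_influence", "toughness",
    "marking_distress", "revenge", "autonomy",
)

ISAS_INTERPERSONAL: tuple[str, ...] = (
    "autonomy", "interpersonal_boundaries", "interpersonal_influence",
    "peer_bonding", "self_care", "revenge", "sensation_seeking", "toughness",
)

ISAS_INTRAPERSONAL: tuple[str, ...] = (
    "affect_regulation", "anti_dissociation", "anti_suicide",
    "marking_distress", "self_punishment",
)

ISAS_ITEM_MAP: dict[str, list[str]] = {
    fn: [f"item_{i + 1 + 13 * rep:02d}" for rep in range(3)]
    for i, fn in enumerate(ISAS_FUNCTIONS)
}


def load_item_map(path) -> dict[str, list[str]]:
    """Read a custom item map from a two-column TSV (subscale, item)."""
    df = pd.read_csv(path, sep="\t")
    if not {"subscale", "item"} <= set(df.columns):
        raise ValueError("item map TSV needs columns 'subscale' and 'item'")
    out: dict[str, list[str]] = {}
    for sub, item in zip(df["subscale"], df["item"]):
        out.setdefault(str(sub), []).append(str(item))
    return out


def _check_items(row: pd.Series, items: list[str], item_max: int, who: str) -> None:
    for item in items:
        if item not in row.index or pd.isna(row[item]):
            raise ValueError(f"{who}: missing response for {item}")
        v = row[item]
        if v != int(v) or not 0 <= int(v) <= item_max:
            raise ValueError(f"{who}: response {v!r} for {item} outside 0..{item_max}")


def score_osi(responses: pd.DataFrame,
              item_map: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Score OSI function subscales (one row per participant).

    ``responses`` needs a ``participant`` column plus all mapped items;
    a missing or out-of-range item raises (no imputation).
    """
    item_map = item_map or OSI_SUBSCALES
    out = []
    for _, row in responses.iterrows():
        pid = row.get("participant", "?")
        rec = {"participant": pid}
        for sub, items in item_map.items():
            _check_items(row, items, OSI_ITEM_MAX, f"participant {pid}")
            rec[sub] = int(sum(int(row[i]) for i in items))
        out.append(rec)
    return pd.DataFrame(out)


def score_isas(responses: pd.DataFrame,
               item_map: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Score the 13 ISAS functions (0-6 each) and the two factors.

    The interpersonal factor sums its 8 member functions, the
    intrapersonal factor its 5; all 39 items must be answered.
    """
    item_map = item_map or ISAS_ITEM_MAP
    out = []
    for _, row in responses.iterrows():
        pid = row.get("participant", "?")
        rec = {"participant": pid}
        for fn, items in item_map.items():
            _check_items(row, items, ISAS_ITEM_MAX, f"participant {pid}")
            rec[fn] = int(sum(int(row[i]) for i in items))
        rec["interpersonal"] = sum(rec[f] for f in ISAS_INTERPERSONAL if f in rec)
        rec["intrapersonal"] = sum(rec[f] for f in ISAS_INTRAPERSONAL if f in rec)
        out.append(rec)
    return pd.DataFrame(out)
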