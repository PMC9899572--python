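"""Convert semi-quantitative FFQ responses into daily diet profiles.

A food-frequency questionnaire (FFQ) records, for each food or beverage
item, one of nine ordered consumption-frequency categories.  Daily nutrient
intake is obtained by multiplying the nutrient composition of the item's
typical portion by the daily-serving equivalent of the reported frequency.
This module also derives the quantities the Carbohydrate Quality Index
needs: the carbohydrate-weighted dietary glycaemic index (glucose = 100
scale) and the whole-grain / total-grain and solid / liquid carbohydrate
sub-fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("carbquality")

# --------------------------------------------------------------------------
# Frequency categories
# --------------------------------------------------------------------------

#: The nine ordered consumption-frequency labels, lowest to highest.
FREQUENCY_LABELS: tuple[str, ...] = (
    "never",
    "1-3/month",
    "1/week",
    "2-4/week",
    "5-6/week",
    "1/day",
    "2-3/day",
    "4-6/day",
    "6+/day",
)

#: Servings/day assigned to each frequency category (midpoint convention:
#: e.g. "2-4/week" -> 3 servings per 7 days).  A single configurable table.
FREQUENCY_SERVINGS_PER_DAY: dict[str, float] = {
    "never": 0.0,
    "1-3/month": 2.0 / 30.0,
    "1/week": 1.0 / 7.0,
    "2-4/week": 3.0 / 7.0,
    "5-6/week": 5.5 / 7.0,
    "1/day": 1.0,
    "2-3/day": 2.5,
    "4-6/day": 5.0,
    "6+/day": 6.0,
}

#: Food groups recognised by the Mediterranean-diet adherence score.
FOOD_GROUPS: tuple[str, ...] = (
    "vegetables",
    "legumes",
    "fruit_nuts",
    "cereals",
    "fish",
    "meat",
    "dairy",
    "other",
)

#: Nutrient columns carried per portion in the item catalogue and per day in
#: the diet profile (grams except energy).
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "carb_g",
    "fiber_g",
    "protein_g",
    "fat_g",
    "mufa_g",
    "pufa_g",
    "sfa_g",
    "trans_g",
    "alcohol_g",
)


def frequency_to_daily(category: str | int) -> float:
    """Servings/day for one of the nine frequency categories.

    ``category`` may be the label (see :data:`FREQUENCY_LABELS`) or its
    ordinal 0-8.  Unknown labels raise ``ValueError``.
    """
    if isinstance(category, (int, np.integer)) and not isinstance(category, bool):
        if not 0 <= int(category) <= 8:
            raise ValueError(f"frequency ordinal out of range 0-8: {category!r}")
        return FREQUENCY_SERVINGS_PER_DAY[FREQUENCY_LABELS[int(category)]]
    try:
        return FREQUENCY_SERVINGS_PER_DAY[str(category)]
    except KeyError:
        raise ValueError(f"unknown frequency category: {category!r}") from None


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FFQItem:
    """One food/beverage line of the questionnaire.

    Nutrient amounts are per typical portion.  ``glycaemic_index`` is on the
    glucose = 100 scale and may be ``None`` for carbohydrate-free items.
    """

    item_id: str
    name: str = ""
    portion_g: float = 100.0
    energy_kcal: float = 0.0
    carb_g: float = 0.0
    fiber_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    sfa_g: float = 0.0
    trans_g: float = 0.0
    alcohol_g: float = 0.0
    glycaemic_index: float | None = None
    is_grain: bool = False
    is_whole_grain: bool = False
    is_liquid_carb: bool = False
    food_group: str = "other"

    def __post_init__(self) -> None:
        if self.portion_g <= 0:
            raise ValueError(f"{self.item_id}: portion_g must be > 0")
        for f in NUTRIENT_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{self.item_id}: {f} must be >= 0")
        gi = self.glycaemic_index
        if gi is not None and not (0.0 <= gi <= 150.0):
            raise ValueError(f"{self.item_id}: glycaemic_index {gi} outside [0, 150]")
        if self.is_whole_grain and not self.is_grain:
            raise ValueError(f"{self.item_id}: is_whole_grain requires is_grain")
        if self.food_group not in FOOD_GROUPS:
            raise ValueError(f"{self.item_id}: unknown food_group {self.food_group!r}")


@dataclass(frozen=True)
class FrequencyResponse:
    """One participant's answer for one FFQ item."""

    item_id: str
    category: str | int

    @property
    def servings_per_day(self) -> float:
        return frequency_to_daily(self.category)


@dataclass
class DietProfile:
    """Daily nutrient summary for one FFQ administration."""

    participant_id: str
    energy_kcal_d: float = 0.0
    carb_g_d: float = 0.0
    fiber_g_d: float = 0.0
    protein_g_d: float = 0.0
    fat_g_d: float = 0.0
    mufa_g_d: float = 0.0
    pufa_g_d: float = 0.0
    sfa_g_d: float = 0.0
    trans_g_d: float = 0.0
    alcohol_g_d: float = 0.0
    dietary_gi: float | None = None
    wholegrain_carb_g_d: float = 0.0
    totalgrain_carb_g_d: float = 0.0
    solid_carb_g_d: float = 0.0
    liquid_carb_g_d: float = 0.0
    per_group_servings_d: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Catalogue and response I/O
# --------------------------------------------------------------------------

_BOOL_COLS = ("is_grain", "is_whole_grain", "is_liquid_carb")


def catalogue_from_frame(frame: pd.DataFrame) -> dict[str, FFQItem]:
    """Build an item_id -> :class:`FFQItem` catalogue from a DataFrame.

    Booleans may be 0/1; a missing glycaemic index is an empty cell / NaN.
    """
    items: dict[str, FFQItem] = {}
    for row in frame.to_dict("records"):
        gi = row.get("glycaemic_index")
        if gi is not None and (gi != gi):  # NaN
            gi = None
        kwargs = {
            "item_id": str(row["item_id"]),
            "name": str(row.get("name", "")),
            "portion_g": float(row.get("portion_g", 100.0)),
            "glycaemic_index": None if gi is None else float(gi),
            "food_group": str(row.get("food_group", "other")),
        }
        for col in NUTRIENT_FIELDS:
            kwargs[col] = float(row.get(col, 0.0))
        for col in _BOOL_COLS:
            kwargs[col] = bool(int(row.get(col, 0)))
        item = FFQItem(**kwargs)
        if item.item_id in items:
            raise ValueError(f"duplicate item_id in catalogue: {item.item_id}")
        items[item.item_id] = item
    return items


def read_item_catalogue(path) -> dict[str, FFQItem]:
    """Read an item catalogue CSV (one header row, FFQItem columns)."""
    return catalogue_from_frame(pd.read_csv(path, dtype={"item_id": str}))


def read_responses(path) -> pd.DataFrame:
    """Read long-format responses CSV: participant_id,item_id,category."""
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str})
    missing = {"participant_id", "item_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"responses file missing columns: {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Profile computation
# --------------------------------------------------------------------------


def dietary_glycaemic_index(
    responses: list[FrequencyResponse], items: dict[str, FFQItem]
) -> float | None:
    """Carbohydrate-weighted mean glycaemic index of the consumed items.

    Items with a missing GI, or with no carbohydrate, contribute nothing to
    the weighted mean.  Returns ``None`` (undefined, not zero) when no
    GI-bearing carbohydrate is consumed.
    """
    num = 0.0
    den = 0.0
    for resp in responses:
        item = items.get(resp.item_id)
        if item is None:
            raise KeyError(f"unknown item_id in responses: {resp.item_id}")
        carb = resp.servings_per_day * item.carb_g
        if carb > 0 and item.glycaemic_index is not None:
            num += carb * item.glycaemic_index
            den += carb
    if den <= 0:
        return None
    return num / den


def compute_diet_profile(
    responses: list[FrequencyResponse],
    items: dict[str, FFQItem],
    participant_id: str = "",
    missing_as_never: bool = True,
) -> DietProfile:
    """Aggregate one participant's responses into a :class:`DietProfile`.

    Each daily nutrient is the sum over items of servings/day times the
    per-portion amount.  Items absent from the response set are treated as
    "never" when ``missing_as_never`` (the count of imputed items is logged);
    otherwise their absence is an error.  Unresolvable item ids and empty
    response sets are rejected.
    """
    if not responses:
        raise ValueError("empty response set")
    seen: set[str] = set()
    for resp in responses:
        if resp.item_id not in items:
            raise KeyError(f"unknown item_id in responses: {resp.item_id}")
        if resp.item_id in seen:
            raise ValueError(f"duplicate response for item {resp.item_id}")
        seen.add(resp.item_id)
    n_imputed = len(items) - len(seen)
    if n_imputed:
        if not missing_as_never:
            raise ValueError(f"{n_imputed} catalogue items without a response")
        logger.debug(
            "participant %s: %d items without a response imputed as 'never'",
            participant_id,
            n_imputed,
        )

    profile = DietProfile(participant_id=participant_id)
    groups = {g: 0.0 for g in FOOD_GROUPS}
    for resp in responses:
        item = items[resp.item_id]
        s = resp.servings_per_day
        if s == 0.0:
            continue
        profile.energy_kcal_d += s * item.energy_kcal
        profile.carb_g_d += s * item.carb_g
        profile.fiber_g_d += s * item.fiber_g
        profile.protein_g_d += s * item.protein_g
        profile.fat_g_d += s * item.fat_g
        profile.mufa_g_d += s * item.mufa_g
        profile.pufa_g_d += s * item.pufa_g
        profile.sfa_g_d += s * item.sfa_g
        profile.trans_g_d += s * item.trans_g
        profile.alcohol_g_d += s * item.alcohol_g
        carb = s * item.carb_g
        if item.is_grain:
            profile.totalgrain_carb_g_d += carb
            if item.is_whole_grain:
                profile.wholegrain_carb_g_d += carb
        if item.is_liquid_carb:
            profile.liquid_carb_g_d += carb
        else:
            profile.solid_carb_g_d += carb
        groups[item.food_group] += s
    profile.per_group_servings_d = groups
    profile.dietary_gi = dietary_glycaemic_index(responses, items)
    return profile


def compute_diet_profiles(
    responses: pd.DataFrame,
    items: dict[str, FFQItem],
    participant_col: str = "participant_id",
) -> pd.DataFrame:
    """Vectorised bulk version of :func:`compute_diet_profile`.

    ``responses`` is long-format (participant, item_id, category).  Returns a
    DataFrame indexed by participant with the DietProfile fields as columns;
    per-group servings appear as ``servings_<group>`` columns and an
    undefined dietary GI as NaN.
    """
    if responses.empty:
        raise ValueError("empty response set")
    item_ids = list(items)
    item_pos = {iid: k for k, iid in enumerate(item_ids)}
    unknown = set(responses["item_id"].astype(str)) - set(item_pos)
    if unknown:
        raise KeyError(f"unknown item_id(s) in responses: {sorted(unknown)[:5]}")
    dup = responses.duplicated([participant_col, "item_id"])
    if dup.any():
        raise ValueError("duplicate (participant, item) responses")

    participants = pd.Index(responses[participant_col].unique(), name=participant_col)
    p_pos = {p: k for k, p in enumerate(participants)}
    servings = np.zeros((len(participants), len(item_ids)))
    cat = responses["category"]
    freq = np.array([frequency_to_daily(c) for c in cat])
    rows = responses[participant_col].map(p_pos).to_numpy()
    cols = responses["item_id"].astype(str).map(item_pos).to_numpy()
    servings[rows, cols] = freq

    cat_items = [items[i] for i in item_ids]
    nutr = np.array([[getattr(it, f) for f in NUTRIENT_FIELDS] for it in cat_items])
    daily = servings @ nutr  # participants x nutrients
    out = pd.DataFrame(
        daily, index=participants, columns=[f + "_d" for f in NUTRIENT_FIELDS]
    )

    carb = np.array([it.carb_g for it in cat_items])
    gi = np.array(
        [np.nan if it.glycaemic_index is None else it.glycaemic_index for it in cat_items]
    )
    grain = np.array([it.is_grain for it in cat_items])
    whole = np.array([it.is_whole_grain for it in cat_items])
    liquid = np.array([it.is_liquid_carb for it in cat_items])

    carb_d = servings * carb
    out["wholegrain_carb_g_d"] = carb_d[:, whole].sum(axis=1)
    out["totalgrain_carb_g_d"] = carb_d[:, grain].sum(axis=1)
    out["liquid_carb_g_d"] = carb_d[:, liquid].sum(axis=1)
    out["solid_carb_g_d"] = carb_d[:, ~liquid].sum(axis=1)

    has_gi = ~np.isnan(gi)
    gi_carb = carb_d[:, has_gi]
    den = gi_carb.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["dietary_gi"] = np.where(
            den > 0, gi_carb @ gi[has_gi] / np.where(den > 0, den, 1.0), np.nan
        )

    group_codes = np.array([FOOD_GROUPS.index(it.food_group) for it in cat_items])
    for g in FOOD_GROUPS:
        out[f"servings_{g}"] = servings[:, group_codes == FOOD_GROUPS.index(g)].sum(axis=1)
    return out
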