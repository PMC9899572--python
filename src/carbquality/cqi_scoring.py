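"""Carbohydrate Quality Index (CQI) scoring and covariate diet scores.

The CQI aggregates four carbohydrate-quality criteria: the dietary
glycaemic index (inversely weighted), the ratio of whole-grain to
total-grain carbohydrate, dietary fibre intake (g/d), and the ratio of
solid to total carbohydrate.  Each component is scored 1-5 by quintiles of
the reference population (GI scored 5-1), the four scores are summed to a
4-20 total, and the total is categorised 4-9 / 10-14 / 15-20.

Also implemented here: the carbohydrate-quantity category (percent of total
energy from carbohydrate: <=40 %, >40-<50 %, >=50 %) and a modified
Mediterranean-diet adherence score (the nine-item median-based score with
the cereals and alcohol items removed, leaving seven items).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CQI_COMPONENTS: tuple[str, ...] = ("gi", "wholegrain_ratio", "fiber_g_d", "solid_ratio")

#: Components whose quintile score runs 5..1 instead of 1..5.
INVERTED_COMPONENTS: frozenset[str] = frozenset({"gi"})

#: CQI total -> category bounds (inclusive).
CQI_CATEGORY_BOUNDS: dict[str, tuple[int, int]] = {
    "low": (4, 9),
    "mid": (10, 14),
    "high": (15, 20),
}

#: Mediterranean score bands over the 0-7 range (even split of 0-7).
MEDDIET_CATEGORY_BOUNDS: dict[str, tuple[int, int]] = {
    "low": (0, 2),
    "mid": (3, 4),
    "high": (5, 7),
}

ATWATER_CARB_KCAL_PER_G = 4.0


# --------------------------------------------------------------------------
# Components
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CQIComponents:
    """The four raw component values for one diet profile."""

    gi: float | None
    wholegrain_ratio: float
    fiber_g_d: float
    solid_ratio: float

    def __post_init__(self) -> None:
        for name in ("wholegrain_ratio", "solid_ratio"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.fiber_g_d < 0:
            raise ValueError("fiber_g_d must be >= 0")


def components_from_profile(profile) -> CQIComponents:
    """Extract the four CQI components from a :class:`~carbquality.ffq_engine.DietProfile`.

    A grain-free diet has an undefined whole-grain ratio; it is set to 0 (the
    worst value) by convention.  Likewise a carbohydrate-free diet gets
    solid_ratio 0 and an undefined (None) GI.
    """
    total_grain = profile.totalgrain_carb_g_d
    wg_ratio = profile.wholegrain_carb_g_d / total_grain if total_grain > 0 else 0.0
    total_carb = profile.carb_g_d
    solid_ratio = profile.solid_carb_g_d / total_carb if total_carb > 0 else 0.0
    return CQIComponents(
        gi=profile.dietary_gi,
        wholegrain_ratio=min(wg_ratio, 1.0),
        fiber_g_d=profile.fiber_g_d,
        solid_ratio=min(solid_ratio, 1.0),
    )


# --------------------------------------------------------------------------
# Quintile machinery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QuintileCutoffs:
    """Interior 20/40/60/80th-percentile cut points for one component."""

    component: str
    cuts: tuple[float, float, float, float]
    invert: bool = False

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError(f"{self.component}: cut points must be non-decreasing")


def derive_cutoffs(values, component: str = "", invert: bool = False) -> QuintileCutoffs:
    """Empirical 20/40/60/80th percentiles (linear-interpolation estimator).

    At least five non-missing values are required.  Deterministic for fixed
    input; the same linear-interpolation ("type 7") rule is always used so
    cutoffs are bit-for-bit reproducible.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 5:
        raise ValueError(
            f"need >=5 non-missing values to derive quintiles, got {arr.size}"
        )
    cuts = np.percentile(arr, [20, 40, 60, 80], method="linear")
    return QuintileCutoffs(component=component, cuts=tuple(cuts), invert=invert)


def quintile_rank(value: float | None, cutoffs: QuintileCutoffs) -> int | None:
    """Quintile score 1-5 of ``value`` under ``cutoffs``.

    Intervals are lower-open at the top: a value equal to an interior cut
    point falls in the lower quintile.  With ``invert`` the score is
    reflected (6 - rank).  A missing value propagates as ``None``.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    r = 1 + int(np.sum(np.asarray(value) > np.asarray(cutoffs.cuts)))
    return 6 - r if cutoffs.invert else r


# --------------------------------------------------------------------------
# CQI score
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CQIScore:
    component_points: dict[str, int]
    total: int
    category: str

    def __post_init__(self) -> None:
        if self.total != sum(self.component_points.values()):
            raise ValueError("total must equal the sum of component points")
        lo, hi = CQI_CATEGORY_BOUNDS[self.category]
        if not lo <= self.total <= hi:
            raise ValueError(f"total {self.total} outside {self.category} band")


def cqi_category(total: int) -> str:
    """Map a 4-20 CQI total to its low / mid / high category."""
    for cat, (lo, hi) in CQI_CATEGORY_BOUNDS.items():
        if lo <= total <= hi:
            return cat
    raise ValueError(f"CQI total {total} outside 4-20")


def score_cqi(
    components: CQIComponents, cutoffs: dict[str, QuintileCutoffs]
) -> CQIScore:
    """Score the four components against their quintile cutoffs and sum.

    Raises ``ValueError`` when any component value is missing (a missing
    score is never silently treated as 1).
    """
    points: dict[str, int] = {}
    for name in CQI_COMPONENTS:
        rank = quintile_rank(getattr(components, name), cutoffs[name])
        if rank is None:
            raise ValueError(f"missing CQI component: {name}")
        points[name] = rank
    total = sum(points.values())
    return CQIScore(component_points=points, total=total, category=cqi_category(total))


def derive_cqi_cutoffs(components_df: pd.DataFrame) -> dict[str, QuintileCutoffs]:
    """Derive the four component cutoff sets from a reference population.

    ``components_df`` must carry the :data:`CQI_COMPONENTS` columns.
    """
    return {
        name: derive_cutoffs(
            components_df[name], component=name, invert=name in INVERTED_COMPONENTS
        )
        for name in CQI_COMPONENTS
    }


def score_cqi_frame(
    components_df: pd.DataFrame, cutoffs: dict[str, QuintileCutoffs]
) -> pd.DataFrame:
    """Vectorised CQI scoring: adds points_*, cqi_total and cqi_category."""
    out = pd.DataFrame(index=components_df.index)
    for name in CQI_COMPONENTS:
        c = cutoffs[name]
        vals = components_df[name].to_numpy(dtype=float)
        rank = 1 + (vals[:, None] > np.asarray(c.cuts)[None, :]).sum(axis=1)
        if c.invert:
            rank = 6 - rank
        rank = np.where(np.isnan(vals), np.nan, rank)
        out[f"points_{name}"] = rank
    out["cqi_total"] = out[[f"points_{n}" for n in CQI_COMPONENTS]].sum(axis=1)
    out["cqi_category"] = pd.cut(
        out["cqi_total"],
        bins=[3.5, 9.5, 14.5, 20.5],
        labels=["low", "mid", "high"],
    ).astype(object)
    return out


# ----- cutoff serialisation ------------------------------------------------


def save_cutoffs(cutoffs: dict[str, QuintileCutoffs], path) -> None:
    """Write cutoffs to CSV (component, q20, q40, q60, q80, invert)."""
    rows = [
        {"component": c.component, "q20": c.cuts[0], "q40": c.cuts[1],
         "q60": c.cuts[2], "q80": c.cuts[3], "invert": int(c.invert)}
        for c in cutoffs.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cutoffs(path) -> dict[str, QuintileCutoffs]:
    df = pd.read_csv(path)
    return {
        r["component"]: QuintileCutoffs(
            component=r["component"],
            cuts=(r["q20"], r["q40"], r["q60"], r["q80"]),
            invert=bool(r["invert"]),
        )
        for _, r in df.iterrows()
    }


# --------------------------------------------------------------------------
# Carbohydrate quantity
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CarbQuantityCategory:
    carb_energy_pct: float
    category: str  # "le40", "mid", "ge50"


def carb_quantity(profile) -> CarbQuantityCategory:
    """Percent of total energy from carbohydrate (4 kcal/g) and its band.

    Bands: <=40 %, >40-<50 %, >=50 % of total energy.  Zero total energy is
    rejected.
    """
    if profile.energy_kcal_d <= 0:
        raise ValueError("carb_quantity requires positive daily energy")
    pct = 100.0 * ATWATER_CARB_KCAL_PER_G * profile.carb_g_d / profile.energy_kcal_d
    return CarbQuantityCategory(carb_energy_pct=pct, category=carb_quantity_category(pct))


def carb_quantity_category(pct: float) -> str:
    if pct <= 40.0:
        return "le40"
    if pct < 50.0:
        return "mid"
    return "ge50"


# --------------------------------------------------------------------------
# Modified Mediterranean-diet score (Trichopoulou minus cereals and alcohol)
# --------------------------------------------------------------------------

#: Items scored at/above the population median (beneficial) and below it
#: (detrimental).  ``mufa_sfa_ratio`` is computed from the profile's fat
#: sub-fields.
MEDDIET_BENEFICIAL: tuple[str, ...] = (
    "vegetables", "legumes", "fruit_nuts", "fish", "mufa_sfa_ratio",
)
MEDDIET_DETRIMENTAL: tuple[str, ...] = ("meat", "dairy")
MEDDIET_ITEMS: tuple[str, ...] = MEDDIET_BENEFICIAL + MEDDIET_DETRIMENTAL


@dataclass(frozen=True)
class MedDietScore:
    points: int
    category: str

    def __post_init__(self) -> None:
        if not 0 <= self.points <= 7:
            raise ValueError("Mediterranean score outside 0-7")


def meddiet_category(points: int) -> str:
    for cat, (lo, hi) in MEDDIET_CATEGORY_BOUNDS.items():
        if lo <= points <= hi:
            return cat
    raise ValueError(f"points {points} outside 0-7")


def _meddiet_values(profile) -> dict[str, float]:
    g = profile.per_group_servings_d
    if profile.sfa_g_d > 0:
        ratio = profile.mufa_g_d / profile.sfa_g_d
    else:
        # undefined ratio: treat as favourable iff any MUFA is consumed
        ratio = math.inf if profile.mufa_g_d > 0 else 0.0
    return {
        "vegetables": g.get("vegetables", 0.0),
        "legumes": g.get("legumes", 0.0),
        "fruit_nuts": g.get("fruit_nuts", 0.0),
        "fish": g.get("fish", 0.0),
        "mufa_sfa_ratio": ratio,
        "meat": g.get("meat", 0.0),
        "dairy": g.get("dairy", 0.0),
    }


def med_diet_score(profile, medians: dict[str, float]) -> MedDietScore:
    """Seven-item Mediterranean adherence score against population medians.

    One point per beneficial item at/above its median and per detrimental
    item strictly below its median; the cereals and alcohol items of the
    original nine-item score are omitted (cereals would overlap the CQI;
    alcohol is adjusted for separately).
    """
    missing = [k for k in MEDDIET_ITEMS if k not in medians]
    if missing:
        raise ValueError(f"missing Mediterranean-score medians: {missing}")
    vals = _meddiet_values(profile)
    pts = sum(int(vals[k] >= medians[k]) for k in MEDDIET_BENEFICIAL)
    pts += sum(int(vals[k] < medians[k]) for k in MEDDIET_DETRIMENTAL)
    return MedDietScore(points=pts, category=meddiet_category(pts))


def meddiet_medians(profiles: list) -> dict[str, float]:
    """Population medians of the seven scored items."""
    table = pd.DataFrame([_meddiet_values(p) for p in profiles])
    # an all-undefined-ratio population would give an inf median; clip it
    return {k: float(np.median(table[k].replace(math.inf, np.nan).dropna()))
            if np.isfinite(table[k]).any() else 0.0
            for k in MEDDIET_ITEMS}


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------


def fiber_wholegrain_correlation(profiles_df: pd.DataFrame) -> float:
    """Pearson correlation between fibre and whole-grain carbohydrate intake.

    A low value indicates the two CQI components capture different aspects
    of carbohydrate quality rather than measuring the same thing twice.
    """
    return float(
        profiles_df["fiber_g_d"].corr(profiles_df["wholegrain_carb_g_d"])
    )
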