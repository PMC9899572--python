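"""Cohort assembly: exclusion cascade, censoring, exposure updating.

The analysis population is produced by a fixed, order-dependent cascade of
exclusions applied to the full cohort roster (insufficient follow-up time,
men, loss to follow-up, no pregnancy during follow-up, gestational diabetes
before baseline, prevalent diabetes or antidiabetic treatment, implausible
energy intake outside the 1st-99th percentile).  Each retained woman then
contributes one analysis row per incident pregnancy, censored after her
first GDM-positive pregnancy.  Dietary exposure is the baseline FFQ, updated
to the 10-year FFQ for pregnancies occurring more than 10 years after
enrolment when that questionnaire exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cqi_scoring
from .cqi_scoring import (
    CQI_COMPONENTS,
    carb_quantity_category,
    derive_cqi_cutoffs,
    score_cqi_frame,
)

logger = logging.getLogger("carbquality")

#: Minimum months in the cohort required to have had the chance to complete
#: the first follow-up questionnaire (2 years and 9 months).
MIN_MONTHS_IN_COHORT = 33

#: Energy-plausibility percentile bounds.
ENERGY_PCTL_LOW = 1.0
ENERGY_PCTL_HIGH = 99.0

#: Follow-up years after which the 10-year questionnaire replaces baseline
#: exposure.
EXPOSURE_SWITCH_YEARS = 10.0

ROSTER_REQUIRED_COLUMNS = (
    "woman_id",
    "sex",
    "months_in_cohort",
    "followup_status",
    "prior_gdm",
    "prevalent_diabetes_or_treatment",
    "energy_kcal_d",
)


# --------------------------------------------------------------------------
# Exclusion cascade
# --------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    """Ordered record of the exclusion cascade (a textual flow chart)."""

    initial_n: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, label: str, n_excluded: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("n_remaining may not increase along the cascade")
        self.steps.append((label, int(n_excluded), int(n_remaining)))

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_n

    def n_remaining_after(self, label: str) -> int:
        for step_label, _, n_rem in self.steps:
            if step_label == label:
                return n_rem
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "n_excluded", "n_remaining"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"Participants in roster: n = {self.initial_n}"]
        for label, n_exc, n_rem in self.steps:
            lines.append(f"  |-- excluded: {label} (n = {n_exc})")
            lines.append(f"  v   remaining: n = {n_rem}")
        lines.append(f"Final analysis sample: n = {self.final_n}")
        return "\n".join(lines)


EXCLUSION_STEPS = (
    "in cohort < 2 years 9 months",
    "men",
    "lost to follow-up",
    "no pregnancy during follow-up",
    "GDM prior to baseline",
    "prevalent diabetes or antidiabetic treatment",
    "implausible energy intake (outside P1-P99)",
)


def apply_exclusions(
    roster: pd.DataFrame, pregnancies: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the seven-step exclusion cascade over the cohort roster.

    ``roster`` is one row per participant with the
    :data:`ROSTER_REQUIRED_COLUMNS`; whether a participant reported any
    pregnancy during follow-up is taken from a ``reported_pregnancy`` roster
    column or, failing that, from membership in ``pregnancies``
    (woman_id-level long table).  Energy-plausibility percentiles are
    computed on the sample remaining at that step of the cascade.

    Returns the eligible-women roster and an :class:`ExclusionReport` whose
    intermediate counts mirror the study flow chart.
    """
    missing = [c for c in ROSTER_REQUIRED_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"roster missing mandatory columns: {missing}")
    for col in ("months_in_cohort", "energy_kcal_d"):
        bad = roster.loc[roster[col].isna(), "woman_id"]
        if len(bad):
            raise ValueError(
                f"missing {col} for woman_id(s): {list(bad.astype(str)[:5])}"
            )

    report = ExclusionReport(initial_n=len(roster))
    cur = roster

    def drop(mask: pd.Series, label: str) -> pd.DataFrame:
        kept = cur[~mask]
        report.add(label, int(mask.sum()), len(kept))
        return kept

    cur = drop(cur["months_in_cohort"] < MIN_MONTHS_IN_COHORT, EXCLUSION_STEPS[0])
    cur = drop(cur["sex"].astype(str).str.lower().isin({"male", "m"}), EXCLUSION_STEPS[1])
    cur = drop(cur["followup_status"].astype(str).str.lower() == "lost", EXCLUSION_STEPS[2])

    if "reported_pregnancy" in cur.columns:
        has_preg = cur["reported_pregnancy"].astype(bool)
    elif pregnancies is not None:
        has_preg = cur["woman_id"].isin(pregnancies["woman_id"].unique())
    else:
        raise ValueError(
            "need a reported_pregnancy column or a pregnancies table to "
            "apply the no-pregnancy exclusion"
        )
    cur = drop(~has_preg, EXCLUSION_STEPS[3])
    cur = drop(cur["prior_gdm"].astype(bool), EXCLUSION_STEPS[4])
    cur = drop(cur["prevalent_diabetes_or_treatment"].astype(bool), EXCLUSION_STEPS[5])

    if len(cur):
        p1, p99 = np.percentile(
            cur["energy_kcal_d"], [ENERGY_PCTL_LOW, ENERGY_PCTL_HIGH]
        )
        implausible = (cur["energy_kcal_d"] < p1) | (cur["energy_kcal_d"] > p99)
    else:
        implausible = pd.Series(False, index=cur.index)
    cur = drop(implausible, EXCLUSION_STEPS[6])

    return cur.reset_index(drop=True), report


# --------------------------------------------------------------------------
# Censoring and exposure updating
# --------------------------------------------------------------------------


def censor_after_gdm(pregnancies: pd.DataFrame) -> pd.DataFrame:
    """Drop every pregnancy after a woman's first GDM-positive pregnancy.

    ``pregnancies`` must be time-ordered within woman (non-decreasing
    ``years_since_baseline``); unordered input is rejected.  The first
    GDM-positive pregnancy itself is always retained.
    """
    if pregnancies.empty:
        return pregnancies.copy()
    g = pregnancies.groupby("woman_id", sort=False)["years_since_baseline"]
    if not g.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("pregnancies must be time-ordered within each woman")
    gdm = pregnancies["gdm"].astype(bool)
    prior_events = gdm.groupby(pregnancies["woman_id"], sort=False).cumsum() - gdm
    return pregnancies[prior_events == 0].copy()


def assign_exposure(
    years_since_baseline: float, has_ten_year_profile: bool
) -> str:
    """Exposure wave for one pregnancy: ``"baseline"`` or ``"10-year"``.

    The 10-year questionnaire is used only for pregnancies more than
    10 years after enrolment and only when it exists; otherwise the
    baseline questionnaire is carried forward (the fallback is flagged by
    the caller).
    """
    if years_since_baseline > EXPOSURE_SWITCH_YEARS and has_ten_year_profile:
        return "10-year"
    return "baseline"


def compute_activity(activities) -> float:
    """Leisure-time physical activity in MET-h/week.

    ``activities`` is an iterable of (label, hours_per_week, MET) triples;
    the total is the sum of hours x MET.  Negative hours are rejected.
    """
    total = 0.0
    for label, hours, met in activities:
        if hours < 0:
            raise ValueError(f"negative hours for activity {label!r}")
        total += hours * met
    return total


# --------------------------------------------------------------------------
# Analysis-dataset assembly
# --------------------------------------------------------------------------

#: Woman-level covariates copied onto each pregnancy row when present.
COVARIATE_COLUMNS = (
    "age_first_pregnancy",
    "bmi",
    "parity",
    "family_history_dm",
    "activity_met_h_wk",
    "tv_h_d",
    "smoking",
    "energy_kcal_d",
    "fastfood_cat",
    "snacking",
    "special_diet",
    "alcohol_cat",
    "cvd",
    "htn",
)


def build_analysis_dataset(
    women: pd.DataFrame,
    pregnancies: pd.DataFrame,
    baseline_profiles: pd.DataFrame | None = None,
    ten_year_profiles: pd.DataFrame | None = None,
    cutoffs: dict | None = None,
    reuse_baseline_cutoffs: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Assemble one analysis row per retained pregnancy.

    ``women`` is the eligible roster (after :func:`apply_exclusions`);
    ``pregnancies`` the long table (woman_id, years_since_baseline, gdm),
    time-ordered within woman.  When profile tables (indexed by woman_id,
    with the DietProfile columns) are given, the CQI and carbohydrate
    quantity are scored per pregnancy from the exposure wave's profile;
    quintile cutoffs default to the baseline analysis population and are
    re-used for 10-year profiles unless ``reuse_baseline_cutoffs`` is False.
    Alternatively ``pregnancies``/``women`` may already carry
    ``cqi_total``/``cqi_category`` columns (pre-scored input).

    Returns the pregnancy-level DataFrame and a summary dict with n_women,
    n_pregnancies, n_gdm and the crude incidence in percent.
    """
    preg = pregnancies[pregnancies["woman_id"].isin(women["woman_id"])].copy()
    preg = censor_after_gdm(preg)

    zero = set(women["woman_id"]) - set(preg["woman_id"])
    if zero:
        logger.info("%d eligible women have no retained pregnancy; dropped", len(zero))
        women = women[~women["woman_id"].isin(zero)]

    # covariates frozen at baseline
    cov_cols = [c for c in COVARIATE_COLUMNS if c in women.columns]
    rows = preg.merge(women[["woman_id", *cov_cols]], on="woman_id", how="left")

    if baseline_profiles is not None:
        rows = _attach_exposure(
            rows, women, baseline_profiles, ten_year_profiles, cutoffs,
            reuse_baseline_cutoffs,
        )

    rows["pregnancy_index"] = rows.groupby("woman_id").cumcount() + 1
    n_preg = len(rows)
    n_gdm = int(rows["gdm"].astype(bool).sum())
    summary = {
        "n_women": int(rows["woman_id"].nunique()),
        "n_pregnancies": n_preg,
        "n_gdm": n_gdm,
        "crude_incidence_pct": 100.0 * n_gdm / n_preg if n_preg else 0.0,
    }
    return rows.reset_index(drop=True), summary


def _profile_components(profiles: pd.DataFrame) -> pd.DataFrame:
    """CQI component columns from a bulk profile table."""
    comp = pd.DataFrame(index=profiles.index)
    comp["gi"] = profiles["dietary_gi"]
    tg = profiles["totalgrain_carb_g_d"]
    comp["wholegrain_ratio"] = np.where(
        tg > 0, profiles["wholegrain_carb_g_d"] / tg.where(tg > 0, 1.0), 0.0
    )
    comp["fiber_g_d"] = profiles["fiber_g_d"]
    tc = profiles["carb_g_d"]
    comp["solid_ratio"] = np.where(
        tc > 0, profiles["solid_carb_g_d"] / tc.where(tc > 0, 1.0), 0.0
    )
    comp["carb_energy_pct"] = (
        100.0
        * cqi_scoring.ATWATER_CARB_KCAL_PER_G
        * profiles["carb_g_d"]
        / profiles["energy_kcal_d"].where(profiles["energy_kcal_d"] > 0)
    )
    return comp


def _attach_exposure(
    rows: pd.DataFrame,
    women: pd.DataFrame,
    baseline_profiles: pd.DataFrame,
    ten_year_profiles: pd.DataFrame | None,
    cutoffs: dict | None,
    reuse_baseline_cutoffs: bool,
) -> pd.DataFrame:
    base_comp = _profile_components(baseline_profiles)
    if cutoffs is None:
        cutoffs = derive_cqi_cutoffs(base_comp.loc[
            base_comp.index.intersection(women["woman_id"])
        ])
    base_scores = score_cqi_frame(base_comp[list(CQI_COMPONENTS)], cutoffs)

    has_ten = rows["woman_id"].isin(
        ten_year_profiles.index if ten_year_profiles is not None else []
    )
    use_ten = (rows["years_since_baseline"] > EXPOSURE_SWITCH_YEARS) & has_ten
    rows["exposure_wave"] = np.where(use_ten, "10-year", "baseline")
    rows["baseline_fallback"] = (
        rows["years_since_baseline"] > EXPOSURE_SWITCH_YEARS
    ) & ~has_ten
    n_fallback = int(rows["baseline_fallback"].sum())
    if n_fallback:
        logger.info(
            "%d pregnancies past year %.0f lack a 10-year profile; "
            "baseline exposure carried forward",
            n_fallback, EXPOSURE_SWITCH_YEARS,
        )

    if ten_year_profiles is not None and use_ten.any():
        ten_comp = _profile_components(ten_year_profiles)
        if not reuse_baseline_cutoffs:
            ten_cutoffs = derive_cqi_cutoffs(ten_comp.loc[
                ten_comp.index.intersection(women["woman_id"])
            ])
        else:
            ten_cutoffs = cutoffs
        ten_scores = score_cqi_frame(ten_comp[list(CQI_COMPONENTS)], ten_cutoffs)
    else:
        ten_comp = ten_scores = None

    def pick(table_base, table_ten, col):
        v = rows["woman_id"].map(table_base[col])
        if table_ten is not None:
            v = v.where(~use_ten, rows["woman_id"].map(table_ten[col]))
        return v

    for col in ("cqi_total", "cqi_category"):
        rows[col] = pick(base_scores, ten_scores, col)
    for col in CQI_COMPONENTS:
        rows[col] = pick(base_comp, ten_comp, col)
    rows["carb_energy_pct"] = pick(base_comp, ten_comp, "carb_energy_pct")
    rows["carb_quantity"] = rows["carb_energy_pct"].map(
        lambda p: carb_quantity_category(p) if pd.notna(p) else np.nan
    )
    return rows
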