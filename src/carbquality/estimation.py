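"""Repeated-measures logistic models for GDM incidence.

Each pregnancy is an observation; pregnancies of the same woman are
correlated, so models are fitted by generalised estimating equations
(binomial family, logit link) with an exchangeable working correlation and
a cluster-robust (sandwich) variance estimator, reporting odds ratios with
95 % confidence intervals.  Implemented analyses:

* CQI category ORs under nested adjustment sets (crude, models 1-4),
* linear-trend test using per-category CQI medians as a continuous term,
* per-2-point continuous CQI OR,
* per-component tertile models (further adjusted for the other components),
* the 3x3 joint carbohydrate quality x quantity analysis with an
  interaction test,
* a configurable sensitivity-scenario runner.

The estimating-equation machinery is statsmodels' GEE; this module owns the
model specifications, exposure codings, and table-shaped outputs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

#: Normal-approximation multiplier for 95 % confidence intervals.
Z_95 = 1.96

CQI_CATEGORY_LEVELS = ("low", "mid", "high")
CARB_QUANTITY_LEVELS = ("le40", "mid", "ge50")

#: Nested adjustment sets (patsy terms).  Terms whose underlying columns are
#: absent from the data are dropped with a warning, so reduced synthetic
#: datasets can be fitted with the same specifications.
ADJUSTMENT_TERMS: dict[str, tuple[str, ...]] = {
    "crude": (),
    "model1": ("age_first_pregnancy", "bmi"),
    "model2": (
        "age_first_pregnancy",
        "bmi",
        "C(parity)",
        "family_history_dm",
        "C(activity_tertile)",
        "tv_h_d",
        "C(smoking)",
        "energy_kcal_d",
        "C(meddiet_cat)",
        "C(fastfood_cat)",
        "snacking",
        "special_diet",
    ),
}
ADJUSTMENT_TERMS["model3"] = ADJUSTMENT_TERMS["model2"] + (
    "C(alcohol_cat)",
    "cvd",
    "htn",
)
# Table-2 model 4: model 3 without the Mediterranean-diet covariate.
ADJUSTMENT_TERMS["model4"] = tuple(
    t for t in ADJUSTMENT_TERMS["model3"] if t != "C(meddiet_cat)"
)

_TERM_COL = re.compile(r"^(?:C\()?([A-Za-z_][A-Za-z0-9_]*)")


def _term_column(term: str) -> str:
    m = _TERM_COL.match(term)
    if m is None:
        raise ValueError(f"cannot parse term {term!r}")
    return m.group(1)


def _available_terms(terms, data: pd.DataFrame) -> list[str]:
    out, dropped = [], []
    for t in terms:
        (out if _term_column(t) in data.columns else dropped).append(t)
    if dropped:
        warnings.warn(
            f"adjustment terms without data columns dropped: {dropped}",
            stacklevel=3,
        )
    return out


# --------------------------------------------------------------------------
# Model specification and fit container
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One model specification: exposure coding, adjustment, GEE options."""

    exposure: str = "cqi_category"
    adjustment: str = "model3"
    correlation_structure: str = "exchangeable"  # or "independence"
    variance: str = "robust"  # or "naive" (model-based)
    cluster: str = "woman_id"
    extra_terms: tuple[str, ...] = ()


@dataclass
class GEEFit:
    """Estimated odds ratios with robust 95 % CIs for one model."""

    exposure: str
    adjustment: str
    params: pd.DataFrame  # index: exposure level/term
    reference_level: str | None
    n_obs: int
    n_clusters: int
    working_correlation: float | None
    converged: bool
    result: object = field(repr=False, default=None)

    def odds_ratio(self, level: str) -> float:
        return float(self.params.loc[level, "or"])

    def ci(self, level: str) -> tuple[float, float]:
        row = self.params.loc[level]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.params.reset_index(names="exposure_level")
        tidy.insert(0, "exposure", self.exposure)
        tidy["model"] = self.adjustment
        tidy["n_obs"] = self.n_obs
        tidy["n_clusters"] = self.n_clusters
        return tidy[
            ["exposure", "exposure_level", "or", "ci_low", "ci_high",
             "coef", "robust_se", "pvalue", "model", "n_obs", "n_clusters"]
        ]


@dataclass(frozen=True)
class TrendTest:
    """Linear-trend slope (per CQI point) with robust inference."""

    slope: float
    robust_se: float
    pvalue: float


# --------------------------------------------------------------------------
# Core GEE fit
# --------------------------------------------------------------------------


def _raw_fit(
    data: pd.DataFrame,
    rhs_terms: list[str],
    spec: ModelSpec,
    outcome: str = "gdm",
):
    cols = sorted({_term_column(t) for t in rhs_terms} | {outcome, spec.cluster})
    frame = data[cols].dropna()
    if frame.empty:
        raise ValueError("no complete cases for the requested model")
    if frame[spec.cluster].nunique() < 2:
        raise ValueError("GEE requires at least two clusters")
    frame = frame.copy()
    frame[outcome] = frame[outcome].astype(int)

    if spec.correlation_structure == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    elif spec.correlation_structure == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError(
            f"unknown correlation structure {spec.correlation_structure!r}"
        )

    formula = f"{outcome} ~ " + (" + ".join(rhs_terms) if rhs_terms else "1")
    model = sm.GEE.from_formula(
        formula,
        groups=spec.cluster,
        data=frame,
        family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        result = model.fit(maxiter=100, ctol=1e-8)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
        warnings.warn(
            "GEE did not converge within 100 iterations", ConvergenceWarning,
            stacklevel=3,
        )
    return result, frame, converged


def _params_table(result, variance: str, keep_prefixes: tuple[str, ...]) -> pd.DataFrame:
    coefs = result.params
    if variance == "robust":
        ses = result.bse
    elif variance == "naive":
        ses = pd.Series(
            np.sqrt(np.diag(result.cov_naive)), index=coefs.index
        )
    else:
        raise ValueError(f"unknown variance type {variance!r}")
    keep = [
        n for n in coefs.index
        if any(n.startswith(p) for p in keep_prefixes)
    ] if keep_prefixes else list(coefs.index)
    rows = {}
    for name in keep:
        c, s = float(coefs[name]), float(ses[name])
        z = c / s if s > 0 else np.nan
        rows[_pretty_level(name)] = {
            "coef": c,
            "robust_se": s,
            "or": float(np.exp(c)),
            "ci_low": float(np.exp(c - Z_95 * s)),
            "ci_high": float(np.exp(c + Z_95 * s)),
            "pvalue": 2.0 * (1.0 - _norm_cdf(abs(z))) if np.isfinite(z) else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _norm_cdf(x: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(x))


_LEVEL_RE = re.compile(r"\[T\.(.+)\]$")


def _pretty_level(name: str) -> str:
    m = _LEVEL_RE.search(name)
    return m.group(1) if m else name


def _check_separation(frame: pd.DataFrame, col: str, outcome: str = "gdm") -> None:
    tab = pd.crosstab(frame[col], frame[outcome].astype(int))
    if (tab == 0).any().any() or tab.shape[1] < 2:
        warnings.warn(
            f"possible separation: zero-count outcome cell(s) for {col!r}",
            stacklevel=3,
        )


def _working_corr(result, spec: ModelSpec) -> float | None:
    if spec.correlation_structure == "exchangeable":
        return float(result.cov_struct.dep_params)
    return None


def prepare_covariates(data: pd.DataFrame) -> pd.DataFrame:
    """Add derived covariate codings used by the adjustment sets.

    Physical activity enters as data-derived tertiles
    (``activity_tertile``); the Mediterranean score as its three-category
    coding when only points are present.
    """
    out = data.copy()
    if "activity_met_h_wk" in out.columns and "activity_tertile" not in out.columns:
        out["activity_tertile"] = cut_tertiles(out["activity_met_h_wk"])
    if "meddiet_points" in out.columns and "meddiet_cat" not in out.columns:
        from .cqi_scoring import meddiet_category

        out["meddiet_cat"] = out["meddiet_points"].map(
            lambda p: meddiet_category(int(p)) if pd.notna(p) else np.nan
        )
    return out


def fit_gee(data: pd.DataFrame, spec: ModelSpec | None = None, **spec_kwargs) -> GEEFit:
    """Fit one GEE logistic model and return its odds-ratio table.

    ``spec.exposure`` selects the exposure coding:

    * ``"cqi_category"`` - indicator contrasts for the mid and high CQI
      categories (reference: low),
    * ``"cqi_per2"`` - the CQI total divided by 2 as a single continuous
      term (per-2-point OR),
    * any column name - used as given (categorical columns should be wrapped
      by the caller via ``extra_terms``-style C() coding beforehand).
    """
    spec = spec or ModelSpec(**spec_kwargs)
    if spec_kwargs and spec is not None and not isinstance(spec, ModelSpec):
        raise TypeError("pass either a ModelSpec or keyword fields, not both")
    data = prepare_covariates(data)

    reference = None
    if spec.exposure == "cqi_category":
        term = f"C(cqi_category, levels={list(CQI_CATEGORY_LEVELS)!r})"
        prefix = "C(cqi_category"
        reference = "low"
        exposure_col = "cqi_category"
    elif spec.exposure == "cqi_per2":
        data = data.copy()
        data["cqi_per2"] = data["cqi_total"] / 2.0
        if np.nanstd(data["cqi_per2"].to_numpy(dtype=float)) == 0:
            raise ValueError("CQI total has zero variance")
        term, prefix, exposure_col = "cqi_per2", "cqi_per2", None
    else:
        term = spec.exposure
        exposure_col = _term_column(spec.exposure)
        prefix = spec.exposure if "(" not in spec.exposure else f"C({exposure_col}"

    rhs = [term, *_available_terms(
        ADJUSTMENT_TERMS[spec.adjustment] + spec.extra_terms, data
    )]
    result, frame, converged = _raw_fit(data, rhs, spec)
    if exposure_col is not None and frame[exposure_col].nunique() > 1:
        _check_separation(frame, exposure_col)
    params = _params_table(result, spec.variance, (prefix,))
    return GEEFit(
        exposure=spec.exposure,
        adjustment=spec.adjustment,
        params=params,
        reference_level=reference,
        n_obs=len(frame),
        n_clusters=int(frame[spec.cluster].nunique()),
        working_correlation=_working_corr(result, spec),
        converged=converged,
        result=result,
    )


# --------------------------------------------------------------------------
# Trend and continuous-increment analyses
# --------------------------------------------------------------------------


def trend_test(
    data: pd.DataFrame, spec: ModelSpec | None = None, **spec_kwargs
) -> TrendTest:
    """Linear-trend test across CQI categories.

    Replaces the category indicators with the analysis sample's median CQI
    total within each category, entered as a single continuous term; the
    slope's robust p-value is the trend p.  A category with no members is
    rejected.
    """
    spec = spec or ModelSpec(**spec_kwargs)
    data = prepare_covariates(data)
    medians = data.groupby("cqi_category", observed=False)["cqi_total"].median()
    empty = [c for c in CQI_CATEGORY_LEVELS if c not in medians.index or pd.isna(medians.get(c))]
    if empty:
        raise ValueError(f"CQI categories with no members: {empty}")
    data = data.copy()
    data["cqi_trend"] = data["cqi_category"].map(medians).astype(float)
    rhs = ["cqi_trend", *_available_terms(ADJUSTMENT_TERMS[spec.adjustment], data)]
    result, _, _ = _raw_fit(data, rhs, spec)
    table = _params_table(result, spec.variance, ("cqi_trend",))
    row = table.loc["cqi_trend"]
    return TrendTest(
        slope=float(row["coef"]),
        robust_se=float(row["robust_se"]),
        pvalue=float(row["pvalue"]),
    )


def per_increment_or(
    data: pd.DataFrame,
    increment: float = 2.0,
    spec: ModelSpec | None = None,
    **spec_kwargs,
) -> GEEFit:
    """OR for an ``increment``-point increase in the continuous CQI total."""
    spec = spec or ModelSpec(**spec_kwargs)
    data = prepare_covariates(data).copy()
    if np.nanstd(data["cqi_total"].to_numpy(dtype=float)) == 0:
        raise ValueError("CQI total has zero variance")
    data["cqi_increment"] = data["cqi_total"] / float(increment)
    rhs = ["cqi_increment", *_available_terms(ADJUSTMENT_TERMS[spec.adjustment], data)]
    result, frame, converged = _raw_fit(data, rhs, spec)
    params = _params_table(result, spec.variance, ("cqi_increment",))
    return GEEFit(
        exposure=f"cqi_per{increment:g}",
        adjustment=spec.adjustment,
        params=params,
        reference_level=None,
        n_obs=len(frame),
        n_clusters=int(frame[spec.cluster].nunique()),
        working_correlation=_working_corr(result, spec),
        converged=converged,
        result=result,
    )


# --------------------------------------------------------------------------
# Component tertiles
# --------------------------------------------------------------------------


def cut_tertiles(values: pd.Series) -> pd.Series:
    """Tertile labels T1 < T2 < T3 with the same boundary rule as quintiles
    (value equal to an interior cut goes to the lower tertile)."""
    arr = values.to_numpy(dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0 or np.nanstd(finite) == 0:
        raise ValueError("cannot form tertiles of a constant (or empty) variable")
    cuts = np.percentile(finite, [100 / 3, 200 / 3], method="linear")
    rank = 1 + (arr[:, None] > cuts[None, :]).sum(axis=1)
    lab = np.array(["T1", "T2", "T3"])[rank - 1].astype(object)
    out = pd.Series(lab, index=values.index)
    out[np.isnan(arr)] = np.nan
    return out


def component_tertile_analysis(
    data: pd.DataFrame,
    components: tuple[str, ...] = ("gi", "wholegrain_ratio", "fiber_g_d", "solid_ratio"),
    adjustments: tuple[str, ...] = ("model3", "model4_components"),
    spec: ModelSpec | None = None,
) -> dict[tuple[str, str], GEEFit]:
    """Tertile ORs for each CQI component.

    ``model4_components`` is the fully adjusted model additionally adjusted
    for the three other (continuous) components.  Reference is always T1;
    for the GI the lowest tertile is the favourable contrast, for the other
    components the highest.
    """
    spec = spec or ModelSpec()
    data = prepare_covariates(data).copy()
    for comp in components:
        data[f"{comp}_tertile"] = cut_tertiles(data[comp])

    fits: dict[tuple[str, str], GEEFit] = {}
    for comp in components:
        for adj in adjustments:
            if adj == "model4_components":
                base_adj = "model3"
                extra = tuple(c for c in components if c != comp)
            else:
                base_adj, extra = adj, ()
            sub = ModelSpec(
                exposure=f"C({comp}_tertile)",
                adjustment=base_adj,
                correlation_structure=spec.correlation_structure,
                variance=spec.variance,
                cluster=spec.cluster,
                extra_terms=extra,
            )
            fit = fit_gee(data, sub)
            fit.exposure = f"{comp}_tertile"
            fit.adjustment = adj
            fit.reference_level = "T1"
            fits[(comp, adj)] = fit
    return fits


# --------------------------------------------------------------------------
# Joint quality x quantity analysis
# --------------------------------------------------------------------------


@dataclass
class JointAnalysis:
    """3x3 quality-by-quantity odds ratios and the interaction test."""

    or_table: pd.DataFrame  # rows: cqi category, cols: quantity category
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    interaction_pvalue: float
    interaction_df: int
    cell_counts: pd.DataFrame
    fit: GEEFit


def joint_quality_quantity(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    interaction: str = "ordinal",
    **spec_kwargs,
) -> JointAnalysis:
    """Joint 9-cell analysis of CQI category x carbohydrate-quantity band.

    Reference cell: lowest quality and lowest quantity (low CQI, <=40 % of
    energy from carbohydrate).  Empty non-reference cells are reported and
    dropped with a warning.  The interaction p-value comes from a single
    product term of the two ordinal codes (``interaction="ordinal"``, 1 df)
    or from a joint Wald test of the four product contrasts
    (``interaction="joint"``, 4 df).
    """
    spec = spec or ModelSpec(**spec_kwargs)
    data = prepare_covariates(data).copy()
    data = data.dropna(subset=["cqi_category", "carb_quantity"])
    data["joint_cell"] = (
        data["cqi_category"].astype(str) + "|" + data["carb_quantity"].astype(str)
    )
    counts = pd.crosstab(data["cqi_category"], data["carb_quantity"]).reindex(
        index=CQI_CATEGORY_LEVELS, columns=CARB_QUANTITY_LEVELS, fill_value=0
    )
    empty = [
        f"{q}|{c}"
        for q in CQI_CATEGORY_LEVELS
        for c in CARB_QUANTITY_LEVELS
        if counts.loc[q, c] == 0
    ]
    if "low|le40" in empty:
        raise ValueError("reference cell (low quality, <=40 %) is empty")
    if empty:
        warnings.warn(f"empty joint cells dropped from estimation: {empty}")

    levels = [
        f"{q}|{c}"
        for q in CQI_CATEGORY_LEVELS
        for c in CARB_QUANTITY_LEVELS
        if f"{q}|{c}" not in empty
    ]
    term = f"C(joint_cell, levels={levels!r})"
    sub = ModelSpec(
        exposure=term,
        adjustment=spec.adjustment,
        correlation_structure=spec.correlation_structure,
        variance=spec.variance,
        cluster=spec.cluster,
        extra_terms=spec.extra_terms,
    )
    fit = fit_gee(data, sub)
    fit.exposure = "joint_quality_quantity"
    fit.reference_level = "low|le40"

    or_t = pd.DataFrame(np.nan, index=list(CQI_CATEGORY_LEVELS), columns=list(CARB_QUANTITY_LEVELS))
    lo_t = or_t.copy()
    hi_t = or_t.copy()
    or_t.loc["low", "le40"] = 1.0
    for cell in levels[1:]:
        q, c = cell.split("|")
        if cell in fit.params.index:
            or_t.loc[q, c] = fit.params.loc[cell, "or"]
            lo_t.loc[q, c] = fit.params.loc[cell, "ci_low"]
            hi_t.loc[q, c] = fit.params.loc[cell, "ci_high"]

    p_int, df_int = _interaction_test(data, spec, interaction)
    return JointAnalysis(
        or_table=or_t,
        ci_low=lo_t,
        ci_high=hi_t,
        interaction_pvalue=p_int,
        interaction_df=df_int,
        cell_counts=counts,
        fit=fit,
    )


def _interaction_test(
    data: pd.DataFrame, spec: ModelSpec, interaction: str
) -> tuple[float, int]:
    data = data.copy()
    data["quality_code"] = data["cqi_category"].map(
        {l: i for i, l in enumerate(CQI_CATEGORY_LEVELS)}
    ).astype(float)
    data["quantity_code"] = data["carb_quantity"].map(
        {l: i for i, l in enumerate(CARB_QUANTITY_LEVELS)}
    ).astype(float)
    adj = _available_terms(ADJUSTMENT_TERMS[spec.adjustment] + spec.extra_terms, data)
    if interaction == "ordinal":
        data["qq_product"] = data["quality_code"] * data["quantity_code"]
        rhs = ["quality_code", "quantity_code", "qq_product", *adj]
        result, _, _ = _raw_fit(data, rhs, spec)
        table = _params_table(result, spec.variance, ("qq_product",))
        return float(table.loc["qq_product", "pvalue"]), 1
    if interaction == "joint":
        qual = f"C(cqi_category, levels={list(CQI_CATEGORY_LEVELS)!r})"
        quan = f"C(carb_quantity, levels={list(CARB_QUANTITY_LEVELS)!r})"
        rhs = [qual, quan, f"{qual}:{quan}", *adj]
        result, _, _ = _raw_fit(data, rhs, spec)
        names = [n for n in result.params.index if ":" in n]
        wald = result.wald_test(names, scalar=True)
        return float(wald.pvalue), len(names)
    raise ValueError(f"unknown interaction test {interaction!r}")


# --------------------------------------------------------------------------
# Sensitivity scenarios
# --------------------------------------------------------------------------

SENSITIVITY_SCENARIOS = (
    "nulliparous",
    "parous",
    "age-at-entry",
    "age-at-each-pregnancy",
    "both-ages",
    "first-pregnancy-only",
)


def sensitivity_runner(
    data: pd.DataFrame,
    scenarios,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Re-fit the main CQI-category model under named scenarios.

    Restriction scenarios subset the rows (nulliparous / parous women at
    baseline, first cohort pregnancy only); age scenarios swap or extend the
    age adjustment (age at cohort entry and/or age at each pregnancy instead
    of age at the first cohort pregnancy).  Results are returned as one tidy
    table, side by side, including a ``main`` row set.
    """
    spec = spec or ModelSpec()
    tables = [_scenario_tidy(fit_gee(data, spec), "main")]
    for name in scenarios:
        if name not in SENSITIVITY_SCENARIOS:
            raise ValueError(f"unknown sensitivity scenario {name!r}")
        sub_data, sub_spec = _apply_scenario(data, spec, name)
        tables.append(_scenario_tidy(fit_gee(sub_data, sub_spec), name))
    return pd.concat(tables, ignore_index=True)


def _scenario_tidy(fit: GEEFit, name: str) -> pd.DataFrame:
    tidy = fit.to_tidy()
    tidy.insert(0, "scenario", name)
    return tidy


def _apply_scenario(
    data: pd.DataFrame, spec: ModelSpec, name: str
) -> tuple[pd.DataFrame, ModelSpec]:
    extra = spec.extra_terms
    if name == "nulliparous":
        data = data[data["parity"] == 0]
    elif name == "parous":
        data = data[data["parity"] != 0]
    elif name == "first-pregnancy-only":
        data = data[data["pregnancy_index"] == 1]
    elif name == "age-at-entry":
        extra = extra + ("age_at_entry",)
    elif name == "age-at-each-pregnancy":
        extra = extra + ("age_at_pregnancy",)
    elif name == "both-ages":
        extra = extra + ("age_at_entry", "age_at_pregnancy")
    return data, ModelSpec(
        exposure=spec.exposure,
        adjustment=spec.adjustment,
        correlation_structure=spec.correlation_structure,
        variance=spec.variance,
        cluster=spec.cluster,
        extra_terms=extra,
    )


# --------------------------------------------------------------------------
# Output formatting
# --------------------------------------------------------------------------


def tidy_results(fits) -> pd.DataFrame:
    """Concatenate GEEFit odds-ratio tables into one tidy DataFrame."""
    return pd.concat([f.to_tidy() for f in fits], ignore_index=True)


def format_or_table(fit: GEEFit) -> str:
    """Plain-text rendering of one fit's OR (95 % CI) column."""
    lines = [f"{fit.exposure} ({fit.adjustment}); n_obs={fit.n_obs}, "
             f"n_women={fit.n_clusters}"]
    if fit.reference_level:
        lines.append(f"  {fit.reference_level:>12}  1.00 (ref.)")
    for level, row in fit.params.iterrows():
        lines.append(
            f"  {level:>12}  {row['or']:.2f} ({row['ci_low']:.2f}, {row['ci_high']:.2f})"
        )
    return "\n".join(lines)
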