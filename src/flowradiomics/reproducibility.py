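"""Feature curves, intraclass correlation, and reproducibility selection.

Each radiomics feature traces a curve over the cardiac cycle per plane and
subject. Curves acquired at different temporal resolutions are harmonized
by linear interpolation on the normalized cycle fraction. Agreement between
scanners or observers is quantified with the intraclass correlation
coefficient from a two-way ANOVA decomposition; the default model is
two-way random effects, absolute agreement, single measurement (scanners
and observers are exchangeable "raters"), with the consistency variant
selectable. ICC values are categorized as poor (< 0.5), moderate
(0.5-0.75), good (0.75-0.9) or excellent (> 0.9), and a feature is selected
when it reaches at least the moderate category in both the inter-scanner
and the inter-observer table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureCurve",
    "ICCResult",
    "SelectionResult",
    "ICC_MODELS",
    "CATEGORY_ORDER",
    "upsample_curve",
    "icc",
    "categorize_icc",
    "reproducibility_table",
    "select_features",
    "category_counts",
    "assign_age_group",
    "summarize_group_curves",
]

ICC_MODELS = ("two_way_random_absolute_single", "two_way_mixed_consistency_single")

CATEGORY_ORDER = ("poor", "moderate", "good", "excellent")

#: Closed age intervals (years) used for age-stratified curve summaries.
AGE_GROUPS = {1: (20, 39), 2: (40, 59), 3: (60, 80)}

ID_COLUMNS = ("subject", "rater", "plane", "timeframe")


@dataclass
class FeatureCurve:
    """One feature's values over the cardiac cycle for one plane/subject."""

    feature: str
    values: np.ndarray
    times: np.ndarray              # normalized cycle fraction, increasing
    plane_label: str = ""
    subject_id: str = ""
    rater_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise ValueError("values and times must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


@dataclass
class ICCResult:
    feature: str
    icc: float
    model: str
    n_units: int
    n_raters: int
    category: str
    degenerate: bool = False


@dataclass
class SelectionResult:
    selected: list[str]
    min_category: str
    n_candidates: int


def upsample_curve(curve: FeatureCurve, target_n: int) -> FeatureCurve:
    """Linearly resample a curve onto a uniform grid over the cycle.

    The target grid spans the same normalized interval as the input
    (endpoints preserved); a curve already on the uniform ``target_n`` grid
    is returned unchanged up to floating-point identity.
    """
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    if len(curve.values) < 2:
        raise ValueError("curve needs at least 2 frames")
    t0, t1 = curve.times[0], curve.times[-1]
    t_new = np.linspace(t0, t1, target_n)
    v_new = np.interp(t_new, curve.times, curve.values)
    return FeatureCurve(curve.feature, v_new, t_new, curve.plane_label,
                        curve.subject_id, curve.rater_id)


def icc(ratings: np.ndarray, model: str = ICC_MODELS[0]) -> float:
    """Intraclass correlation from a units x raters matrix.

    Two-way ANOVA mean squares (rows = units, columns = raters):

    * absolute agreement, single rating:
      ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``
    * consistency, single rating: ``(MSR - MSE) / (MSR + (k-1) MSE)``

    A matrix with zero total variance is perfect agreement by definition
    and returns 1.0.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if np.isnan(x).any():
        raise ValueError("ratings must have no missing cells")
    if model not in ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand, atol=1e-14 * max(1.0, abs(grand))):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def categorize_icc(value: float) -> str:
    """Reproducibility category of an ICC value.

    poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent; boundary
    values belong to the higher category except 0.9, which is good.
    """
    if not np.isfinite(value):
        raise ValueError("ICC value must be finite")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def _curve_table(df: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Upsample every (subject, rater, plane) curve to the finest frame grid."""
    n_target = int(df.groupby(["subject", "rater", "plane"])["timeframe"]
                   .nunique().max())
    pieces = []
    for (subj, rater, plane), g in df.groupby(["subject", "rater", "plane"]):
        g = g.sort_values("timeframe")
        n = len(g)
        if n == n_target:
            out = g[["timeframe"] + feature_cols].copy()
            out["timeframe"] = np.arange(n)
        else:
            t = np.arange(n) / n
            t_new = np.linspace(t[0], t[-1], n_target)
            out = pd.DataFrame({
                col: np.interp(t_new, t, g[col].to_numpy())
                for col in feature_cols
            })
            out.insert(0, "timeframe", np.arange(n_target))
        out.insert(0, "plane", plane)
        out.insert(0, "rater", rater)
        out.insert(0, "subject", subj)
        pieces.append(out)
    return pd.concat(pieces, ignore_index=True)


def reproducibility_table(features: pd.DataFrame,
                          model: str = ICC_MODELS[0]) -> list[ICCResult]:
    """Per-feature ICC over a subjects x raters design.

    ``features`` is a wide table with id columns ``subject``, ``rater``,
    ``plane``, ``timeframe`` and one column per feature. Rating units pool
    planes and timeframes (one unit per subject x plane x timeframe);
    raters are the scanner or observer replicates. Curves with fewer frames
    than the finest rater are first upsampled linearly.
    """
    missing = [c for c in ID_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks id columns: {missing}")
    feature_cols = [c for c in features.columns if c not in ID_COLUMNS]
    df = _curve_table(features, feature_cols)

    raters = sorted(df["rater"].unique())
    pivoted = df.pivot_table(index=["subject", "plane", "timeframe"],
                             columns="rater", values=feature_cols,
                             aggfunc="first")
    results = []
    for feat in feature_cols:
        mat = pivoted[feat][raters]
        if mat.isna().any().any():
            bad = mat[mat.isna().any(axis=1)].index.tolist()[:5]
            raise ValueError(
                f"incomplete rater coverage for {feat!r}; missing cells at "
                f"units {bad}"
            )
        x = mat.to_numpy()
        val = icc(x, model=model)
        degenerate = bool(np.allclose(x, x.mean()))
        results.append(ICCResult(
            feature=feat, icc=val, model=model, n_units=x.shape[0],
            n_raters=x.shape[1], category=categorize_icc(val),
            degenerate=degenerate,
        ))
    return results


def select_features(interscanner: list[ICCResult],
                    interobserver: list[ICCResult],
                    min_category: str = "moderate") -> SelectionResult:
    """Features at or above ``min_category`` in BOTH reproducibility tables."""
    if min_category not in CATEGORY_ORDER:
        raise ValueError(f"unknown category {min_category!r}")
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    need = rank[min_category]

    def passing(results):
        return {r.feature for r in results if rank[r.category] >= need}

    both = sorted(passing(interscanner) & passing(interobserver))
    n_cand = len({r.feature for r in interscanner} |
                 {r.feature for r in interobserver})
    if not both:
        warnings.warn("no feature satisfies the reproducibility criterion")
    return SelectionResult(selected=both, min_category=min_category,
                           n_candidates=n_cand)


def category_counts(results: list[ICCResult]) -> pd.DataFrame:
    """Count features per reproducibility category and parameter map.

    Feature names follow the ``<map>__<family>__<name>`` / ``shape__<name>``
    convention; the output has one row per category and one column per map
    (plus ``shape``).
    """
    rows = []
    for r in results:
        group = r.feature.split("__")[0]
        rows.append({"group": group, "category": r.category})
    df = pd.DataFrame(rows)
    table = (df.value_counts(["category", "group"]).unstack(fill_value=0)
             .reindex(list(CATEGORY_ORDER), fill_value=0))
    return table


def assign_age_group(age: float) -> int | None:
    """Age-decade group: 1 for [20, 39], 2 for [40, 59], 3 for [60, 80]."""
    for grp, (lo, hi) in AGE_GROUPS.items():
        if lo <= age <= hi:
            return grp
    return None


def summarize_group_curves(curves: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-group mean/min/max envelopes of feature curves.

    ``curves`` is long-format with columns ``subject``, ``feature``,
    ``timeframe``, ``value`` and the grouping column (``sex``,
    ``age_group`` or ``cohort``). Empty groups are simply absent; a
    warning names them if the grouping column contains NA.
    """
    if grouping not in curves.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    df = curves.copy()
    if df[grouping].isna().any():
        warnings.warn(f"dropping rows with undefined {grouping}")
        df = df.dropna(subset=[grouping])
    out = (df.groupby([grouping, "feature", "timeframe"])["value"]
           .agg(["mean", "min", "max"]).reset_index())
    return out
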