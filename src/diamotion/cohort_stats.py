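"""Cohort statistics: group comparisons, change scores, subgroups, reports.

Conventions of the study design this module serves:

* continuous variables are summarized as median (min - max) and compared
  with the two-sided Mann-Whitney test; sex with Pearson's chi-square
  (no continuity correction);
* change scores are follow-up minus initial; a positive change in the
  diaphragm height ratio (increased curvature over time) is classified as
  deterioration, a negative change as improvement;
* patient subgroups: ERT duration at the initial visit (untreated / <= 3
  years / > 3 years, boundary closed at 3.0, negative durations counted as
  <= 3 years) and diaphragmatic weakness at the initial visit
  (cranial-caudal ratio < 1.4, the lowest value recorded in healthy
  controls); subgroup tests against controls are not corrected for
  multiplicity, matching the indicative character of those analyses;
* significance level 0.05, marked with an asterisk in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import OUTCOME_NAMES

#: Cranial-caudal ratio below which the initial visit counts as moderate to
#: severe diaphragmatic weakness.
CC_WEAKNESS_CUTOFF = 1.4

#: Two-sided significance level for asterisks in reports.
ALPHA = 0.05

#: Largest per-group size for which the exact Mann-Whitney null is used.
EXACT_MAX_N = 25

ERT_GROUPS = ("untreated", "<=3y", ">3y")


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison: summaries, test, and two-sided p-value."""

    variable: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float = float("nan")
    median_b: float = float("nan")
    range_a: tuple[float, float] = (float("nan"), float("nan"))
    range_b: tuple[float, float] = (float("nan"), float("nan"))
    method: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """Sample median (midpoint convention for even n), minimum and maximum.

    Missing values are ignored; all-missing input is an error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise StatsError("median of an all-missing sample is undefined")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def _clean(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise StatsError(f"group {name} has no non-missing values")
    return arr


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], variable: str = ""
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most
    25 observations and there are no ties; otherwise the normal
    approximation with tie and continuity correction.  The method actually
    used is recorded on the result.
    """
    a = _clean(group_a, "a")
    b = _clean(group_b, "b")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    med_a, lo_a, hi_a = median_range(a)
    med_b, lo_b, hi_b = median_range(b)
    return ComparisonResult(
        variable=variable,
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        median_a=med_a,
        median_b=med_b,
        range_a=(lo_a, hi_a),
        range_b=(lo_b, hi_b),
        method="exact" if exact else "asymptotic",
    )


def chi_square_2x2(counts: Sequence[Sequence[int]], variable: str = "") -> ComparisonResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise StatsError(f"need a 2x2 table, got shape {table.shape}")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise StatsError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined with a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(
        variable=variable,
        test="chi-square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(table[:, 0].sum()),
        n_b=int(table[:, 1].sum()),
        method="pearson",
    )


# ---------------------------------------------------------------------------
# Change scores, subgroups, classification
# ---------------------------------------------------------------------------


def change_scores(outcomes: pd.DataFrame, columns: Sequence[str] = OUTCOME_NAMES) -> pd.DataFrame:
    """Follow-up minus initial per subject for each outcome column.

    ``outcomes`` follows the per-subject outcomes schema (one row per
    subject per visit).  Subjects missing a visit get NaN changes; a
    ``missing_reason`` column records why.
    """
    required = {"subject_id", "group", "visit"}
    if not required <= set(outcomes.columns):
        raise StatsError(f"outcomes table must have columns {sorted(required)}")
    rows = []
    for sid, sub in outcomes.groupby("subject_id", sort=True):
        row: dict[str, object] = {"subject_id": sid, "group": sub["group"].iloc[0]}
        initial = sub[sub["visit"] == "initial"]
        followup = sub[sub["visit"] == "follow-up"]
        if len(initial) != 1 or len(followup) != 1:
            row["missing_reason"] = "missing_visit"
            for col in columns:
                row[col] = np.nan
        else:
            row["missing_reason"] = ""
            for col in columns:
                v0 = initial[col].iloc[0]
                v1 = followup[col].iloc[0]
                row[col] = v1 - v0
        rows.append(row)
    return pd.DataFrame(rows)


def ert_group(duration: float | None) -> str:
    """ERT subgroup from treatment duration at the initial visit.

    None/NaN = untreated; durations <= 3.0 years (including negative ones,
    i.e. treatment started between the visits) = "<=3y"; else ">3y".
    """
    if duration is None or (isinstance(duration, float) and np.isnan(duration)):
        return "untreated"
    return "<=3y" if duration <= 3.0 else ">3y"


def classify_change(height_ratio_change: float) -> str:
    """Deterioration/improvement label from the diaphragm height-ratio change.

    Positive change (curvature increased over time) = deterioration;
    negative = improvement; exact zero = stable; missing = unclassified.
    """
    if height_ratio_change is None or np.isnan(height_ratio_change):
        return "unclassified"
    if height_ratio_change > 0:
        return "deterioration"
    if height_ratio_change < 0:
        return "improvement"
    return "stable"


@dataclass(frozen=True)
class SubgroupSpec:
    """A named patient subgroup defined by a predicate over subject rows."""

    name: str
    predicate: Callable[[pd.Series], bool]


def ert_subgroup_specs() -> list[SubgroupSpec]:
    """The three ERT-duration subgroups (partition of the patient set)."""
    return [
        SubgroupSpec(name, lambda row, g=name: ert_group(row.get("ert_duration_years")) == g)
        for name in ERT_GROUPS
    ]


def weakness_subgroup_specs() -> list[SubgroupSpec]:
    """Initial-weakness subgroups by the cranial-caudal cut-off of 1.4."""
    return [
        SubgroupSpec(
            "cc_lt_1.4", lambda row: row["cranial_caudal_ratio_initial"] < CC_WEAKNESS_CUTOFF
        ),
        SubgroupSpec(
            "cc_ge_1.4", lambda row: row["cranial_caudal_ratio_initial"] >= CC_WEAKNESS_CUTOFF
        ),
    ]


def subgroup_analysis(
    subjects: pd.DataFrame,
    spec: SubgroupSpec,
    outcome: str,
) -> ComparisonResult:
    """Compare a patient subgroup's change scores against all controls.

    ``subjects`` has one row per subject with a change-score column named
    ``outcome``, a ``group`` column and whatever fields the subgroup
    predicate needs.  Mann-Whitney, no multiplicity adjustment.
    """
    patients = subjects[subjects["group"] == "patient"]
    controls = subjects[subjects["group"] == "control"]
    member = patients[patients.apply(spec.predicate, axis=1)]
    if member.empty:
        raise StatsError(f"subgroup {spec.name!r} is empty")
    return mann_whitney(
        member[outcome], controls[outcome], variable=f"{outcome}[{spec.name} vs controls]"
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def _fmt(median: float, lo: float, hi: float) -> str:
    return f"{median:.2f} ({lo:.2f} to {hi:.2f})"


def _comparison_row(name: str, a: pd.Series, b: pd.Series) -> dict[str, object]:
    res = mann_whitney(a, b, variable=name)
    return {
        "variable": name,
        "patients": _fmt(res.median_a, *res.range_a),
        "controls": _fmt(res.median_b, *res.range_b),
        "p_value": res.p_value,
        "significant": "*" if res.significant else "",
        "test": f"{res.test}/{res.method}",
        "n_patients": res.n_a,
        "n_controls": res.n_b,
    }


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics report: demographics by group plus tests.

    Sex is compared with the chi-square test, continuous variables with the
    Mann-Whitney test; ERT subgroup counts are listed for patients.
    """
    pat = cohort[cohort["group"] == "patient"]
    con = cohort[cohort["group"] == "control"]
    rows: list[dict[str, object]] = []
    if "sex" in cohort.columns:
        counts = np.array(
            [
                [(pat["sex"].str.lower() == "m").sum(), (con["sex"].str.lower() == "m").sum()],
                [(pat["sex"].str.lower() == "f").sum(), (con["sex"].str.lower() == "f").sum()],
            ],
            dtype=int,
        )
        res = chi_square_2x2(counts, variable="sex")
        rows.append(
            {
                "variable": "sex_male_n",
                "patients": f"{counts[0, 0]} ({100 * counts[0, 0] / max(len(pat), 1):.0f}%)",
                "controls": f"{counts[0, 1]} ({100 * counts[0, 1] / max(len(con), 1):.0f}%)",
                "p_value": res.p_value,
                "significant": "*" if res.significant else "",
                "test": "chi-square",
                "n_patients": len(pat),
                "n_controls": len(con),
            }
        )
    for col in ("age_years", "height_cm", "weight_kg", "followup_interval_years"):
        if col in cohort.columns and pat[col].notna().any() and con[col].notna().any():
            rows.append(_comparison_row(col, pat[col], con[col]))
    if "ert_duration_years" in cohort.columns:
        groups = pat["ert_duration_years"].map(ert_group)
        for name in ERT_GROUPS:
            n = int((groups == name).sum())
            rows.append(
                {
                    "variable": f"ert_{name}_n",
                    "patients": f"{n} ({100 * n / max(len(pat), 1):.0f}%)",
                    "controls": "",
                    "p_value": np.nan,
                    "significant": "",
                    "test": "",
                    "n_patients": n,
                    "n_controls": 0,
                }
            )
    return pd.DataFrame(rows)


def outcome_comparison_table(
    outcomes: pd.DataFrame, columns: Sequence[str] = OUTCOME_NAMES
) -> pd.DataFrame:
    """Outcome report: initial medians and change scores by group with tests.

    One row per outcome: patient and control median (min - max) at the
    initial visit with the Mann-Whitney p, then the same for follow-up minus
    initial change scores.  Asterisks mark p <= 0.05.
    """
    missing = [c for c in columns if c not in outcomes.columns]
    report_columns = [c for c in columns if c in outcomes.columns]
    changes = change_scores(outcomes, report_columns)
    initial = outcomes[outcomes["visit"] == "initial"]
    rows = []
    for col in report_columns:
        pat0 = initial.loc[initial["group"] == "patient", col]
        con0 = initial.loc[initial["group"] == "control", col]
        pat1 = changes.loc[changes["group"] == "patient", col]
        con1 = changes.loc[changes["group"] == "control", col]
        r0 = mann_whitney(pat0, con0, variable=col)
        r1 = mann_whitney(pat1, con1, variable=f"{col}_change")
        rows.append(
            {
                "variable": col,
                "initial_patients": _fmt(r0.median_a, *r0.range_a),
                "initial_controls": _fmt(r0.median_b, *r0.range_b),
                "initial_p": r0.p_value,
                "initial_sig": "*" if r0.significant else "",
                "change_patients": _fmt(r1.median_a, *r1.range_a),
                "change_controls": _fmt(r1.median_b, *r1.range_b),
                "change_p": r1.p_value,
                "change_sig": "*" if r1.significant else "",
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["missing_variables"] = missing
    return df


def classification_table(cohort: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient classification: weakness class at the initial visit, ERT
    subgroup, and deterioration/improvement from the height-ratio change."""
    changes = change_scores(outcomes, ["diaphragm_height_ratio"])
    initial = outcomes[outcomes["visit"] == "initial"].set_index("subject_id")
    rows = []
    for _, row in changes[changes["group"] == "patient"].iterrows():
        sid = row["subject_id"]
        cc0 = initial["cranial_caudal_ratio"].get(sid, np.nan)
        dur = np.nan
        if "ert_duration_years" in cohort.columns:
            match = cohort.loc[cohort["subject_id"] == sid, "ert_duration_years"]
            if len(match):
                dur = match.iloc[0]
        rows.append(
            {
                "subject_id": sid,
                "cranial_caudal_ratio_initial": cc0,
                "weakness_class": (
                    "moderate_severe" if cc0 < CC_WEAKNESS_CUTOFF else "mild_none"
                )
                if not np.isnan(cc0)
                else "unknown",
                "ert_group": ert_group(dur if not np.isnan(dur) else None),
                "diaphragm_height_ratio_change": row["diaphragm_height_ratio"],
                "change_class": classify_change(row["diaphragm_height_ratio"]),
            }
        )
    return pd.DataFrame(rows)


def subgroup_table(cohort: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Subgroup report: each ERT and weakness subgroup's change in the two
    curvature outcomes versus controls."""
    changes = change_scores(outcomes, list(OUTCOME_NAMES))
    initial = outcomes[outcomes["visit"] == "initial"][
        ["subject_id", "cranial_caudal_ratio"]
    ].rename(columns={"cranial_caudal_ratio": "cranial_caudal_ratio_initial"})
    merged = changes.merge(initial, on="subject_id", how="left")
    if "ert_duration_years" in cohort.columns:
        merged = merged.merge(
            cohort[["subject_id", "ert_duration_years"]], on="subject_id", how="left"
        )
    rows = []
    specs = ert_subgroup_specs() + weakness_subgroup_specs()
    for spec in specs:
        for outcome in ("diaphragm_height_ratio", "diaphragm_area_ratio"):
            try:
                res = subgroup_analysis(merged, spec, outcome)
            except StatsError:
                continue
            rows.append(
                {
                    "subgroup": spec.name,
                    "outcome": outcome,
                    "n_subgroup": res.n_a,
                    "change_subgroup": _fmt(res.median_a, *res.range_a),
                    "change_controls": _fmt(res.median_b, *res.range_b),
                    "p_value": res.p_value,
                    "significant": "*" if res.significant else "",
                }
            )
    return pd.DataFrame(rows)


def reproduce_tables(
    cohort: pd.DataFrame, outcomes: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """All report tables from a cohort table and per-subject outcomes.

    Returns demographics, pulmonary-function (when PFT columns are present
    in the outcomes table), MRI-outcome, subgroup and classification
    reports.  Missing variables are listed on each report's
    ``attrs["missing_variables"]`` and the partial table is still produced.
    """
    reports = {
        "demographics": demographics_table(cohort),
        "mri_outcomes": outcome_comparison_table(outcomes),
        "subgroups": subgroup_table(cohort, outcomes),
        "classification": classification_table(cohort, outcomes),
    }
    pft_cols = [
        c
        for c in ("fvc_upright_pct", "fvc_supine_pct", "mip_pct", "mep_pct")
        if c in outcomes.columns
    ]
    if pft_cols:
        reports["pulmonary_function"] = outcome_comparison_table(outcomes, pft_cols)
    return reports
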