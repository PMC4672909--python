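"""Descriptive analyses of localization behavior.

Covers the cohort-level pipeline applied to trial tables: robust
exclusion of sloppy responders, per-condition localization bias
(signed error, positive = rightward) and precision (response SD),
classification of congruent bisensory trials by the inferred causal
structure, and the group statistical tests (Bonferroni-corrected
one-sample t-tests on peripheral biases, repeated-measures ANOVA on
response SDs across locations, paired t-tests between adjacent
locations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CausalClass",
    "classify_bisensory_trial",
    "classify_bisensory_trials",
    "exclude_outlier_subjects",
    "bias_table",
    "unisensory_bias_table",
    "group_tests",
]

logger = logging.getLogger(__name__)

#: IQR of a standard normal; IQR / 1.349 is a robust SD estimate
_IQR_TO_SD = 1.349

#: response-discrepancy cuts for causal classification of bisensory trials
COMMON_CAUSE_CUT = 2.0
INDEPENDENT_CAUSE_CUT = 5.0


@dataclass(frozen=True)
class CausalClass:
    """Causal label of a congruent bisensory trial, from |r_V - r_A| alone."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ("common", "independent", "excluded"):
            raise ValueError(f"unknown causal label {self.label!r}")


def classify_bisensory_trial(r_A: float, r_V: float) -> CausalClass:
    """Label one bisensory trial: responses within 2 degrees of each other
    indicate a perceived common cause, more than 5 degrees apart indicate
    independent causes, and the ambiguous band in between is excluded."""
    if r_A is None or r_V is None or np.isnan(r_A) or np.isnan(r_V):
        raise ValueError("both responses must be present to classify a trial")
    d = abs(r_V - r_A)
    if d <= COMMON_CAUSE_CUT:
        return CausalClass("common")
    if d > INDEPENDENT_CAUSE_CUT:
        return CausalClass("independent")
    return CausalClass("excluded")


def classify_bisensory_trials(trials: pd.DataFrame) -> pd.Series:
    """Vectorized causal labels for the bisensory rows of a trial table."""
    d = (trials["r_V"] - trials["r_A"]).abs()
    out = pd.Series("excluded", index=trials.index, dtype=object)
    out[d <= COMMON_CAUSE_CUT] = "common"
    out[d > INDEPENDENT_CAUSE_CUT] = "independent"
    out[d.isna()] = np.nan
    return out


# --------------------------------------------------------------------------
# exclusion
# --------------------------------------------------------------------------


def exclude_outlier_subjects(trials: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    """Flag subjects whose unisensory mean responses are extreme outliers.

    For each of the 10 unisensory conditions (modality x location) the
    cohort's per-subject mean responses yield a robust SD (IQR / 1.349);
    a subject is excluded if their mean deviates from the cohort median
    by more than three times that robust SD in any condition.  Returns
    the retained subject list and a per-(subject, condition) report.
    Conditions with zero IQR are skipped with a warning.
    """
    subjects = sorted(trials["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for the exclusion rule")
    uni_A = trials[trials["s_A"].notna() & trials["s_V"].isna()]
    uni_V = trials[trials["s_V"].notna() & trials["s_A"].isna()]
    rows = []
    for modality, df, s_col, r_col in (("A", uni_A, "s_A", "r_A"), ("V", uni_V, "s_V", "r_V")):
        for loc, grp in df.groupby(s_col):
            means = grp.groupby("subject")[r_col].mean()
            q75, q25 = np.percentile(means, [75, 25])
            iqr = q75 - q25
            if iqr == 0:
                logger.warning(
                    "zero IQR for %s at %+.1f deg; condition skipped in exclusion rule",
                    modality,
                    loc,
                )
                continue
            robust_sd = iqr / _IQR_TO_SD
            med = float(means.median())
            for subj, m in means.items():
                rows.append(
                    {
                        "subject": subj,
                        "modality": modality,
                        "location": loc,
                        "mean_response": m,
                        "cohort_median": med,
                        "robust_sd": robust_sd,
                        "outlier": abs(m - med) > 3.0 * robust_sd,
                    }
                )
    report = pd.DataFrame(rows)
    flagged = set(report.loc[report["outlier"], "subject"]) if len(report) else set()
    retained = [s for s in subjects if s not in flagged]
    return retained, report


# --------------------------------------------------------------------------
# bias and precision summaries
# --------------------------------------------------------------------------


def bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x modality x condition localization error summary.

    ``mean_error`` is mean(response - true location) over the condition's
    trials (positive = rightward) and ``sd`` the response SD over the same
    trials.  Bisensory conditions are identified by both stimulus columns;
    ``condition_type`` distinguishes unisensory from bisensory rows.
    """
    frames = []
    for modality, r_col, s_col in (("A", "r_A", "s_A"), ("V", "r_V", "s_V")):
        present = trials[trials[s_col].notna()].copy()
        if present.empty:
            continue
        other = "s_V" if s_col == "s_A" else "s_A"
        present["condition_type"] = np.where(
            present[other].notna(), "bisensory", "unisensory"
        )
        present["error"] = present[r_col] - present[s_col]
        g = present.groupby(
            ["subject", "condition_type", "s_A", "s_V"], dropna=False
        )
        summ = g.agg(
            mean_error=("error", "mean"),
            sd=(r_col, "std"),
            n_trials=("error", "size"),
        ).reset_index()
        summ.insert(1, "modality", modality)
        summ["stimulus"] = summ[s_col]
        frames.append(summ)
    out = pd.concat(frames, ignore_index=True)
    return out


def unisensory_bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Unisensory rows of :func:`bias_table` (one row per subject x modality x location)."""
    tab = bias_table(trials)
    return tab[tab["condition_type"] == "unisensory"].reset_index(drop=True)


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------


def _rm_anova(values: pd.DataFrame, dv: str, within: str) -> dict:
    """One-way repeated-measures ANOVA (no sphericity correction)."""
    import pingouin as pg

    aov = pg.rm_anova(data=values, dv=dv, within=within, subject="subject", detailed=True)
    effect, error = aov.iloc[0], aov.iloc[1]
    return {
        "F": float(effect["F"]),
        "df1": float(effect["DF"]),
        "df2": float(error["DF"]),
        "p": float(effect["p_unc"]),
    }


def group_tests(
    trials: pd.DataFrame,
    condition_type: str = "unisensory",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Group statistics on biases and response SDs.

    Returns a dict of tidy frames:

    ``bias_ttests``
        One-sample t-tests of mean error against zero per modality x
        location; the eight peripheral cells are Bonferroni-corrected
        (``p_corrected``), the central cells are reported uncorrected.
    ``sd_anova``
        One-way repeated-measures ANOVA on response SDs across the five
        locations, per modality.
    ``adjacent_sd_ttests``
        Paired t-tests of response SDs between spatially adjacent
        locations, per modality.
    """
    tab = bias_table(trials)
    if condition_type == "bisensory_congruent":
        tab = tab[(tab["condition_type"] == "bisensory") & (tab["s_A"] == tab["s_V"])]
    else:
        tab = tab[tab["condition_type"] == condition_type]
    if tab["subject"].nunique() < 2:
        raise ValueError("group tests need at least 2 subjects")

    rows = []
    peripheral_cells = []
    for (modality, loc), grp in tab.groupby(["modality", "stimulus"]):
        t, p = stats.ttest_1samp(grp["mean_error"], 0.0)
        rows.append(
            {
                "modality": modality,
                "location": loc,
                "mean_bias": float(grp["mean_error"].mean()),
                "t": float(t),
                "df": int(len(grp) - 1),
                "p": float(p),
                "peripheral": loc != 0.0,
            }
        )
        if loc != 0.0:
            peripheral_cells.append(len(rows) - 1)
    bias_t = pd.DataFrame(rows)
    m = len(peripheral_cells)
    bias_t["p_corrected"] = np.nan
    if m:
        bias_t.loc[peripheral_cells, "p_corrected"] = np.minimum(
            1.0, bias_t.loc[peripheral_cells, "p"] * m
        )
    bias_t["significant"] = bias_t["p_corrected"].fillna(bias_t["p"]) < alpha

    anova_rows = []
    paired_rows = []
    for modality, grp in tab.groupby("modality"):
        wide = grp.pivot_table(index="subject", columns="stimulus", values="sd")
        wide = wide.dropna()
        long = wide.reset_index().melt(id_vars="subject", var_name="location", value_name="sd")
        df1 = wide.shape[1] - 1.0
        df2 = float((wide.shape[0] - 1) * (wide.shape[1] - 1))
        if np.isclose(wide.mean(axis=0).var(), 0.0):
            # no location effect at all (possibly with pure subject effects):
            # the F ratio is exactly zero rather than 0/0
            res = {"F": 0.0, "df1": df1, "df2": df2, "p": 1.0}
        else:
            res = _rm_anova(long, dv="sd", within="location")
        res["modality"] = modality
        anova_rows.append(res)
        locs = sorted(wide.columns)
        for a, b in zip(locs[:-1], locs[1:]):
            t, p = stats.ttest_rel(wide[a], wide[b])
            paired_rows.append(
                {
                    "modality": modality,
                    "location_a": a,
                    "location_b": b,
                    "mean_sd_a": float(wide[a].mean()),
                    "mean_sd_b": float(wide[b].mean()),
                    "t": float(t),
                    "df": int(len(wide) - 1),
                    "p": float(p),
                }
            )
    return {
        "bias_ttests": bias_t,
        "sd_anova": pd.DataFrame(anova_rows)[["modality", "F", "df1", "df2", "p"]],
        "adjacent_sd_ttests": pd.DataFrame(paired_rows),
    }
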