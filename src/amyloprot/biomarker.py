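"""CSF biomarker evaluation: group comparison, ROC/AUC, biomarker association.

The AUC is the linear-trapezoid integral of the empirical ROC curve with the
midrank tie convention, which makes it exactly equal to the Mann-Whitney U
statistic divided by ``n_cases * n_controls`` — an identity exercised in the
tests. No covariates enter the ROC. Group comparison is an unpaired two-tailed
t-test (classic by default, Welch optional); biomarker association is Spearman
correlation with a two-tailed t-test p and no multiplicity adjustment by
default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve

from .correlation import spearman_with_p
from .diffexpr import benjamini_hochberg


def roc_auc(scores_cases, scores_controls) -> tuple[float, pd.DataFrame]:
    """Trapezoid-rule AUC and the ROC points for cases-vs-controls scores.

    Ties between a case and a control contribute 1/2. Invariant under strictly
    monotone transforms of all scores, and ``roc_auc(x, y) = 1 - roc_auc(y, x)``.
    """
    cases = np.asarray(list(scores_cases), float)
    controls = np.asarray(list(scores_controls), float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups need >= 1 value")
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    s = np.concatenate([cases, controls])
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, points


def group_compare(values_a, values_b, welch: bool = False) -> dict:
    """Mean +/- SD per group and unpaired two-tailed t-test."""
    a = np.asarray(list(values_a), float)
    b = np.asarray(list(values_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "t": float(t), "p": float(p), "welch": welch,
        "degenerate_variance": bool(degenerate),
    }


def biomarker_spearman(
    table: pd.DataFrame, analyte: str = "analyte", biomarker_cols=None, adjust: bool = False
) -> pd.DataFrame:
    """Spearman association of the analyte with each biomarker column.

    Uses pairwise-complete observations; requires >= 3 per pair. No
    multiplicity adjustment unless ``adjust=True``.
    """
    if biomarker_cols is None:
        biomarker_cols = [
            c for c in table.columns
            if c not in ("subject_id", "group", analyte)
        ]
    rows = []
    for col in biomarker_cols:
        sub = table[[analyte, col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"biomarker {col!r}: < 3 pairwise-complete observations")
        rho, p = spearman_with_p(sub[analyte].to_numpy(), sub[col].to_numpy())
        rows.append({"biomarker": col, "rho": rho, "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


class CSFBiomarkerEvaluator(BaseEstimator):
    """End-to-end evaluation of one CSF analyte.

    Parameters name the case and control groups; ``fit`` computes the group
    comparison, ROC/AUC and biomarker associations from a CSF table.
    """

    def __init__(self, analyte: str = "analyte", case_group: str = "AD",
                 control_group: str = "control", welch: bool = False):
        self.analyte = analyte
        self.case_group = case_group
        self.control_group = control_group
        self.welch = welch

    def fit(self, X: pd.DataFrame, y=None):
        cases = X.loc[X["group"] == self.case_group, self.analyte]
        controls = X.loc[X["group"] == self.control_group, self.analyte]
        if len(cases) == 0 or len(controls) == 0:
            raise ValueError("case or control group absent from the table")
        self.auc_, self.roc_points_ = roc_auc(cases, controls)
        self.comparison_ = group_compare(cases, controls, welch=self.welch)
        both = X[X["group"].isin([self.case_group, self.control_group])]
        self.associations_ = biomarker_spearman(both, analyte=self.analyte)
        return self

    def summary(self) -> dict:
        return {
            "analyte": self.analyte,
            "auc": self.auc_,
            "comparison": self.comparison_,
            "associations": self.associations_.to_dict(orient="records"),
        }
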