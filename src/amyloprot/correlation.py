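"""Aggregate-trajectory correlation classification and the small correlation
toolkit.

Differential proteins are classified as aggregate-*correlated* or
*anticorrelated* by Pearson-correlating their 3-point log-fold-change
trajectory over age against each of four per-tissue aggregate readout
trajectories (membrane-filter assay, plaque load, 6E10 plaque counts, ThioS
plaque counts). Significance uses the two-tailed t-test
``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom; with
three time points the critical |r| at alpha = 0.05 is ~0.9969. ``r = +/-1``
gets ``p = 0`` and is classified (perfect correlation passes any alpha).

Also provides Spearman correlation with the same t-approximation, the
cross-condition Spearman matrix of differential tables, and the plaque-load
helper (percent of region volume occupied by plaques >= 50 um^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .diffexpr import benjamini_hochberg


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed t-test p at df = n - 2.

    Zero variance in either vector is an error (the correlation is undefined,
    not zero); ``|r| = 1`` yields ``p = 0``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return pearson_with_p(rx, ry)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """|r| above which the two-tailed p drops below alpha at df = n - 2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t * t + (n - 2)))


def plaque_load(plaque_volumes, region_volume: float, min_volume: float = 50.0) -> float:
    """Percent of region volume occupied by plaques at or above ``min_volume`` (um^3)."""
    v = np.asarray(list(plaque_volumes), float)
    if region_volume <= 0:
        raise ValueError("region volume must be positive")
    if (v < 0).any():
        raise ValueError("negative plaque volume")
    return float(100.0 * v[v >= min_volume].sum() / region_volume)


# ---------------------------------------------------------------------------
# DEP trajectory classification
# ---------------------------------------------------------------------------

@dataclass
class CorrClassification:
    protein_id: str
    tissue: str
    best_readout: str
    r: float
    p: float
    label: str  # "corr" | "acorr"


class TrajectoryCorrelationClassifier(BaseEstimator):
    """Classify per-protein LFC trajectories against aggregate trajectories.

    Parameters
    ----------
    alpha :
        Two-tailed significance level for the trajectory correlation.
    readouts :
        Optional subset of readout names to use; default all available.

    ``fit`` takes the per-tissue readout trajectories (dict tissue ->
    {readout: age-ordered values}); ``predict`` classifies a table of
    per-protein trajectories.
    """

    def __init__(self, alpha: float = 0.05, readouts=None):
        self.alpha = alpha
        self.readouts = readouts

    def fit(self, X: dict, y=None):
        traj = {}
        for tissue, per in X.items():
            traj[tissue] = {}
            for readout, values in per.items():
                if self.readouts is not None and readout not in self.readouts:
                    continue
                v = np.asarray(values, float)
                if np.ptp(v) == 0:
                    raise ValueError(
                        f"readout {readout!r} in {tissue!r} has zero variance; "
                        "correlation undefined"
                    )
                traj[tissue][readout] = v
        self.trajectories_ = traj
        self.conflicts_ = []
        return self

    def classify_one(self, protein_id: str, tissue: str, lfcs) -> CorrClassification | None:
        """Classify one protein's trajectory in one tissue; None if neither class."""
        lfcs = np.asarray(lfcs, float)
        if np.isnan(lfcs).any():
            raise ValueError(f"{protein_id}: missing age point")
        if np.ptp(lfcs) == 0:
            return None  # flat trajectory: correlation undefined, not classified
        hits = []
        for readout, traj in self.trajectories_[tissue].items():
            r, p = pearson_with_p(lfcs, traj)
            if p < self.alpha and r != 0.0:
                hits.append((p, abs(1.0 - abs(r)), readout, r))
        if not hits:
            return None
        hits.sort()
        p, _, readout, r = hits[0]
        signs = {np.sign(h[3]) for h in hits}
        if len(signs) > 1:
            self.conflicts_.append(protein_id)  # resolved by smallest p above
        return CorrClassification(
            protein_id, tissue, readout, r, p, "corr" if r > 0 else "acorr"
        )

    def predict(self, trajectories: pd.DataFrame) -> pd.DataFrame:
        """Classify a tidy table with columns protein_id, tissue, and one
        column per age (ascending age order)."""
        age_cols = [c for c in trajectories.columns if c not in ("protein_id", "tissue")]
        rows, skipped = [], []
        for rec in trajectories.itertuples(index=False):
            lfcs = [getattr(rec, str(c)) for c in age_cols]
            if any(pd.isna(v) for v in lfcs):
                skipped.append(rec.protein_id)
                continue
            res = self.classify_one(rec.protein_id, rec.tissue, lfcs)
            if res is not None:
                rows.append(res.__dict__)
        self.skipped_ = skipped
        out = pd.DataFrame(rows, columns=["protein_id", "tissue", "best_readout", "r", "p", "label"])
        return out


def dep_lfc_trajectories(pairwise_results: pd.DataFrame, ages=(2, 5, 8)) -> pd.DataFrame:
    """Pivot pairwise ``DE.<tissue>.Age<k>`` results into per-protein trajectories.

    The DEP universe is the union of proteins significant in at least one age
    of a tissue; a protein needs a log-fold-change at every age of that tissue
    to be classifiable (others are reported with NaN and skipped downstream).
    """
    t = pairwise_results.copy()
    parts = t["contrast_id"].str.split(".", expand=True)
    t["tissue"] = parts[1].map({"cortex": "cortex", "hippo": "hippocampus"})
    t["age"] = parts[2].str.removeprefix("Age").astype(int)
    sig = t[t["significant"]].groupby(["protein_id", "tissue"]).size().index
    wide = t.pivot_table(index=["protein_id", "tissue"], columns="age", values="logfc")
    wide = wide.reindex(columns=list(ages))
    wide = wide.loc[wide.index.isin(sig)]
    out = wide.reset_index()
    out.columns = ["protein_id", "tissue"] + [f"lfc_{a}" for a in ages]
    return out


def classify_dep_trajectories(
    pairwise_results: pd.DataFrame,
    trajectories_by_tissue: dict,
    alpha: float = 0.05,
    ages=(2, 5, 8),
) -> tuple[dict, pd.DataFrame]:
    """Classify pairwise-model DEPs into the four families.

    Returns ``({"c_corr": set, "c_acorr": set, "h_corr": set, "h_acorr": set},
    classification table)``.
    """
    clf = TrajectoryCorrelationClassifier(alpha=alpha).fit(trajectories_by_tissue)
    table = clf.predict(dep_lfc_trajectories(pairwise_results, ages))
    prefix = {"cortex": "c", "hippocampus": "h"}
    families = {"c_corr": set(), "c_acorr": set(), "h_corr": set(), "h_acorr": set()}
    for rec in table.itertuples(index=False):
        families[f"{prefix[rec.tissue]}_{rec.label}"].add(rec.protein_id)
    return families, table


# ---------------------------------------------------------------------------
# Spearman cross-comparison matrices
# ---------------------------------------------------------------------------

def lfc_spearman_matrix(diff_tables: dict, pairs=None, value_col: str = "logfc") -> pd.DataFrame:
    """Pairwise Spearman of effect sizes over shared proteins.

    ``diff_tables`` maps dataset name -> table with ``protein_id`` (or
    ``gene_symbol``) and an effect column. Pairs with < 3 shared proteins are
    marked not computable (NaN). P-values are BH-adjusted over all computed
    pairs; anticorrelations keep their negative sign.
    """
    names = list(diff_tables)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    keyed = {}
    for name, t in diff_tables.items():
        key = "protein_id" if "protein_id" in t.columns else "gene_symbol"
        keyed[name] = t.set_index(key)[value_col]
    rows = []
    for a, b in pairs:
        shared = keyed[a].index.intersection(keyed[b].index)
        if len(shared) < 3:
            rows.append({"a": a, "b": b, "rho": np.nan, "p": np.nan, "n": len(shared)})
            continue
        rho, p = spearman_with_p(keyed[a].loc[shared], keyed[b].loc[shared])
        rows.append({"a": a, "b": b, "rho": rho, "p": p, "n": len(shared)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out.loc[ok, "fdr"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out
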