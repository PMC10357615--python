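"""Empirical-Bayes moderated differential abundance with interaction contrasts.

Per protein, condition means are estimated by generalized least squares with a
compound-symmetric within-block correlation (blocks are animal-tissue
homogenates, capturing technical-replicate dependence; the consensus
correlation is estimated once across proteins, the analogue of limma's
``duplicateCorrelation``). Residual variances are shrunk toward a pooled prior
by closed-form empirical Bayes — the prior degrees of freedom ``d0`` and prior
variance ``s0^2`` are moment-matched on the log residual variances — giving
moderated t-statistics with ``d0 + d_g`` degrees of freedom. Benjamini-
Hochberg FDR is computed separately within each contrast; a protein is
significant when its FDR is below 0.05.

Transgene effects are estimated separately per tissue and age (``A8TH`` is
the TG-WT difference at 8 months in hippocampus); interaction contrasts
compare transgene effects between ages (``A82TC``) or tissues (``A5THC``).
The pairwise model applies the same machinery restricted to one (tissue, age),
producing the ``DE.<tissue>.Age<k>`` families.

Effects are estimated and reported on the log10 scale (multiply by
``1/log10(2)`` for log2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator

from .filtering import pairwise_analysis_set
from .io_tables import IntensityMatrix

LOG2_PER_LOG10 = 1.0 / np.log10(2.0)

_TISSUE_LETTER = {"cortex": "C", "hippocampus": "H"}
_TISSUE_SHORT = {"cortex": "cortex", "hippocampus": "hippo"}


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Standard BH step-up adjustment; monotone in p rank, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


# ---------------------------------------------------------------------------
# consensus within-block correlation
# ---------------------------------------------------------------------------

def estimate_consensus_correlation(
    matrix: IntensityMatrix, block_cols: tuple = ("animal_id", "tissue"), trim: float = 0.1
) -> float:
    """Consensus correlation of technical replicates within a homogenate.

    Per protein, residuals from the condition-mean fit are scored with a
    one-way intraclass correlation over blocks with >= 2 observed replicates;
    the per-protein values are Fisher-z transformed, robust-averaged with a
    trimmed mean, and back-transformed.
    """
    meta = matrix.sample_meta
    cond = meta[["tissue", "age", "genotype"]].astype(str).agg("|".join, axis=1).to_numpy()
    block = meta[list(block_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    Y = matrix.values.to_numpy(float)

    # (condition, block) grouping: the ANOVA is one-way within each condition
    # (condition means are nuisance fixed effects) with pooled sums of squares
    groups_by_cond: dict = {}
    for j in range(len(meta)):
        groups_by_cond.setdefault(cond[j], {}).setdefault(block[j], []).append(j)

    any_reps = any(
        len(ix) >= 2 for per in groups_by_cond.values() for ix in per.values()
    )
    if not any_reps:
        warnings.warn("no block with >= 2 technical replicates; consensus correlation set to 0")
        return 0.0

    iccs = []
    for g in range(Y.shape[0]):
        ssb = ssw = 0.0
        df_b = df_w = 0
        k0_num = 0.0
        for per_block in groups_by_cond.values():
            obs = [Y[g, ix][~np.isnan(Y[g, ix])] for ix in per_block.values()]
            obs = [x for x in obs if len(x) >= 1]
            if len(obs) < 2:
                continue
            k = np.array([len(x) for x in obs], float)
            means = np.array([x.mean() for x in obs])
            N_c = k.sum()
            cmean = np.concatenate(obs).mean()
            ssb += float(np.sum(k * (means - cmean) ** 2))
            df_b += len(obs) - 1
            ssw += float(sum(((x - x.mean()) ** 2).sum() for x in obs))
            df_w += int(N_c) - len(obs)
            k0_num += (N_c - np.sum(k ** 2) / N_c)
        if df_b < 1 or df_w < 1:
            continue
        msb, msw = ssb / df_b, ssw / df_w
        k0 = k0_num / df_b
        denom = msb + (k0 - 1.0) * msw
        if denom <= 0 or k0 <= 1.0:
            continue
        iccs.append(np.clip((msb - msw) / denom, -0.999, 0.999))
    if not iccs:
        warnings.warn("consensus correlation not estimable; set to 0")
        return 0.0
    z = np.arctanh(np.asarray(iccs))
    return float(np.tanh(stats.trim_mean(z, trim)))


# ---------------------------------------------------------------------------
# EB variance moderation (moment matching on log variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = polygamma(1, x) - y
        step = f / polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * abs(x):
            return float(x_new)
        x = x_new
    return float(x)


def squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` for EB shrinkage."""
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    s2, df = s2[ok], df[ok].astype(float)
    if s2.size < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_variance(s2, df, prior_df: float, prior_var: float):
    """Convex combination ``(d0*s0^2 + d*s^2) / (d0 + d)``."""
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    if prior_df == 0:
        return s2
    return (prior_df * prior_var + df * s2) / (prior_df + df)


@dataclass
class ModerationState:
    prior_df: float
    prior_var: float
    sigma2: pd.Series  # per-protein residual variances
    df_resid: pd.Series
    rho: float


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def transgene_contrast(tissue: str, age) -> tuple[str, dict]:
    cid = f"A{age}T{_TISSUE_LETTER[tissue]}"
    return cid, {(tissue, age, "TG"): 1.0, (tissue, age, "WT"): -1.0}


def age_difference_contrast(tissue: str, age_hi, age_lo) -> tuple[str, dict]:
    cid = f"A{age_hi}{age_lo}T{_TISSUE_LETTER[tissue]}"
    return cid, {
        (tissue, age_hi, "TG"): 1.0, (tissue, age_hi, "WT"): -1.0,
        (tissue, age_lo, "TG"): -1.0, (tissue, age_lo, "WT"): 1.0,
    }


def tissue_difference_contrast(age, tissue_hi: str = "hippocampus",
                               tissue_lo: str = "cortex") -> tuple[str, dict]:
    cid = f"A{age}T{_TISSUE_LETTER[tissue_hi]}{_TISSUE_LETTER[tissue_lo]}"
    return cid, {
        (tissue_hi, age, "TG"): 1.0, (tissue_hi, age, "WT"): -1.0,
        (tissue_lo, age, "TG"): -1.0, (tissue_lo, age, "WT"): 1.0,
    }


def full_model_contrasts(tissues=("cortex", "hippocampus"), ages=(2, 5, 8)) -> dict:
    """The standard 15-contrast set: 6 transgene, 6 age-difference, 3 tissue-difference."""
    contrasts = {}
    for t in tissues:
        for a in ages:
            cid, c = transgene_contrast(t, a)
            contrasts[cid] = c
        for hi, lo in [(ages[1], ages[0]), (ages[2], ages[1]), (ages[2], ages[0])]:
            cid, c = age_difference_contrast(t, hi, lo)
            contrasts[cid] = c
    for a in ages:
        cid, c = tissue_difference_contrast(a)
        contrasts[cid] = c
    return contrasts


def validate_contrast(coeffs: dict) -> None:
    vals = np.array(list(coeffs.values()), float)
    if len(vals) > 2 and abs(vals.sum()) > 1e-9:
        raise ValueError("difference-contrast coefficients must sum to 0")


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class ModeratedLinearModel(BaseEstimator):
    """Cell-means GLS per protein with EB-moderated t-statistics.

    Parameters
    ----------
    rho :
        Within-block (animal-tissue homogenate) correlation of technical
        replicates; ``"auto"`` estimates the consensus correlation from the
        data, 0 reduces GLS to OLS exactly.
    prior_df :
        ``"auto"`` estimates ``d0`` by moment matching; 0 disables shrinkage
        (ordinary t); ``numpy.inf`` pools all proteins to the prior variance.
    fdr :
        Significance threshold on the BH-adjusted p-value.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : DataFrame, proteins x conditions (NaN where unestimable)
    sigma2_, df_resid_ : per-protein residual variance and df
    prior_df_, prior_var_, rho_ : moderation hyperparameters
    """

    def __init__(self, rho=0.0, prior_df="auto", fdr: float = 0.05):
        self.rho = rho
        self.prior_df = prior_df
        self.fdr = fdr

    # -- fitting ----------------------------------------------------------
    def fit(self, X: IntensityMatrix, y=None):
        matrix = X
        meta = matrix.sample_meta
        conditions = sorted(set(zip(meta["tissue"], meta["age"], meta["genotype"])))
        cond_index = {c: i for i, c in enumerate(conditions)}
        cond_of = np.array([cond_index[c] for c in zip(meta["tissue"], meta["age"], meta["genotype"])])
        block = meta[["animal_id", "tissue"]].astype(str).agg("|".join, axis=1)
        block_code = pd.factorize(block)[0]

        rho = self.rho
        if rho == "auto":
            rho = estimate_consensus_correlation(matrix)
        rho = float(np.clip(rho, -0.99, 0.99))

        Y = matrix.values.to_numpy(float)
        obs = ~np.isnan(Y)
        n_genes = Y.shape[0]
        n_cond = len(conditions)

        coef = np.full((n_genes, n_cond), np.nan)
        sigma2 = np.full(n_genes, np.nan)
        df_resid = np.zeros(n_genes)
        pattern_of = np.full(n_genes, -1)
        pattern_info: list[dict] = []

        patterns: dict[bytes, list] = {}
        for g in range(n_genes):
            patterns.setdefault(obs[g].tobytes(), []).append(g)

        for pat, genes in patterns.items():
            m = np.frombuffer(pat, dtype=bool)
            o = np.where(m)[0]
            if o.size == 0:
                continue
            cond_o = cond_of[o]
            present = np.unique(cond_o)
            Xo = np.zeros((o.size, present.size))
            for k, c in enumerate(present):
                Xo[cond_o == c, k] = 1.0
            # block compound-symmetric correlation among observed samples
            R = np.eye(o.size)
            if rho != 0.0:
                same = block_code[o][:, None] == block_code[o][None, :]
                R = np.where(same, rho, 0.0)
                np.fill_diagonal(R, 1.0)
            L = np.linalg.cholesky(R)
            Xw = np.linalg.solve(L, Xo)
            XtX = Xw.T @ Xw
            Cinv = np.linalg.inv(XtX)
            A = Cinv @ Xw.T  # coefficient operator on whitened data
            df = o.size - present.size

            Yw = np.linalg.solve(L, Y[np.ix_(genes, o)].T)  # n_o x n_genes_in_pattern
            B = A @ Yw  # present-conditions x genes
            res = Yw - Xw @ B
            rss = np.sum(res ** 2, axis=0)
            gi = np.asarray(genes)
            coef[np.ix_(gi, present)] = B.T
            df_resid[gi] = df
            if df > 0:
                sigma2[gi] = rss / df
            pid = len(pattern_info)
            pattern_info.append({"present": present, "Cinv": Cinv, "genes": gi})
            pattern_of[gi] = pid

        prior_df, prior_var = self.prior_df, None
        if prior_df == "auto":
            prior_df, prior_var = squeeze_variances(sigma2, df_resid)
        else:
            prior_df = float(prior_df)
            _, prior_var = squeeze_variances(sigma2, df_resid)

        self.conditions_ = conditions
        self.coef_ = pd.DataFrame(coef, index=matrix.protein_ids, columns=conditions)
        self.sigma2_ = pd.Series(sigma2, index=matrix.protein_ids)
        self.df_resid_ = pd.Series(df_resid, index=matrix.protein_ids)
        self.prior_df_ = prior_df
        self.prior_var_ = prior_var
        self.rho_ = rho
        self._patterns = pattern_info
        self._pattern_of = pattern_of
        self._protein_ids = matrix.protein_ids
        self.moderation_ = ModerationState(prior_df, prior_var, self.sigma2_, self.df_resid_, rho)
        return self

    # -- inference --------------------------------------------------------
    def contrast(self, contrasts: dict) -> pd.DataFrame:
        """Evaluate contrasts; returns the tidy differential-result table.

        ``contrasts`` maps contrast id -> {condition tuple: weight}. Proteins
        whose data cannot estimate a contrast (a weighted condition entirely
        missing, or zero residual df) get no row. BH adjustment is applied
        within each contrast independently.
        """
        cond_index = {c: i for i, c in enumerate(self.conditions_)}
        frames = []
        s2_post = moderated_variance(
            self.sigma2_.to_numpy(), self.df_resid_.to_numpy(), self.prior_df_, self.prior_var_
        )
        df_total = self.df_resid_.to_numpy() + (
            0.0 if np.isinf(self.prior_df_) else self.prior_df_
        )
        coef = self.coef_.to_numpy()

        for cid, coeffs in contrasts.items():
            validate_contrast(coeffs)
            c_full = np.zeros(len(self.conditions_))
            for cond, w in coeffs.items():
                if cond not in cond_index:
                    raise ValueError(f"contrast {cid}: condition {cond} not in the design")
                c_full[cond_index[cond]] = w
            needed = np.where(c_full != 0.0)[0]

            est = np.full(len(self._protein_ids), np.nan)
            vu = np.full(len(self._protein_ids), np.nan)
            for info in self._patterns:
                present = info["present"]
                if not set(needed).issubset(set(present)):
                    continue
                sel = np.searchsorted(present, needed)
                c_red = c_full[needed]
                var_unit = float(c_red @ info["Cinv"][np.ix_(sel, sel)] @ c_red)
                gi = info["genes"]
                est[gi] = coef[np.ix_(gi, needed)] @ c_red
                vu[gi] = var_unit

            ok = (
                np.isfinite(est)
                & (self.df_resid_.to_numpy() > 0)
                & np.isfinite(s2_post)
                & (s2_post > 0)
            )
            if np.isinf(self.prior_df_):
                dft = np.full(ok.sum(), np.inf)
            else:
                dft = df_total[ok]
            se = np.sqrt(s2_post[ok] * vu[ok])
            t = est[ok] / se
            p = 2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(dft), 1e9, dft))
            fdr = benjamini_hochberg(p)
            frames.append(pd.DataFrame({
                "protein_id": np.asarray(self._protein_ids)[ok],
                "contrast_id": cid,
                "logfc": est[ok],
                "moderated_stat": t,
                "p_value": p,
                "fdr": fdr,
                "significant": fdr < self.fdr,
            }))
        if not frames:
            return pd.DataFrame(columns=["protein_id", "contrast_id", "logfc",
                                         "moderated_stat", "p_value", "fdr", "significant"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_contrasts(
    matrix: IntensityMatrix,
    contrasts: dict | None = None,
    rho=0.0,
    prior_df="auto",
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, ModerationState]:
    """Full-model fit over all conditions present in the matrix."""
    model = ModeratedLinearModel(rho=rho, prior_df=prior_df, fdr=fdr).fit(matrix)
    if contrasts is None:
        meta = matrix.sample_meta
        tissues = list(dict.fromkeys(meta["tissue"]))
        ages = sorted(set(meta["age"]))
        if len(tissues) == 2 and len(ages) == 3:
            contrasts = full_model_contrasts(tuple(tissues), tuple(ages))
        else:
            contrasts = {}
            for t in tissues:
                for a in ages:
                    cid, c = transgene_contrast(t, a)
                    contrasts[cid] = c
    return model.contrast(contrasts), model.moderation_


def pairwise_fit(
    matrix: IntensityMatrix, tissue: str, age, rho=0.0, prior_df="auto", fdr: float = 0.05
) -> pd.DataFrame:
    """Per-(tissue, age) transgene comparison on the pairwise reliability set.

    Produces the ``DE.<tissue>.Age<k>`` result family.
    """
    proteins = sorted(pairwise_analysis_set(matrix, tissue, age))
    sub = matrix.subset_tissue(tissue)
    keep = sub.sample_meta["age"] == age
    meta = sub.sample_meta.loc[keep].reset_index(drop=True)
    sub = IntensityMatrix(sub.values[meta["sample"]], meta, sub.gene_symbols)
    sub = sub.subset_proteins(proteins)
    model = ModeratedLinearModel(rho=rho, prior_df=prior_df, fdr=fdr).fit(sub)
    _, coeffs = transgene_contrast(tissue, age)
    result = model.contrast({f"DE.{_TISSUE_SHORT[tissue]}.Age{age}": coeffs})
    return result
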