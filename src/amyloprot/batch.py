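"""Parametric empirical-Bayes batch adjustment (ComBat) on log10 intensities.

Missing-value-aware re-implementation of the standard location/scale ComBat
model: per protein, intensities are standardized by a covariate-protected
least-squares fit; per-batch additive (location) and multiplicative (scale)
effects are estimated and shrunk toward batch-level priors — normal for
locations, inverse-gamma for scales, both moment-matched — with the usual
iterative conditional-modes solution; adjusted values restore the covariate
fit. Missing entries stay missing and are excluded from every estimate, which
is why an off-the-shelf dense implementation cannot be used here.

A single batch is the identity. A design in which a batch is perfectly
confounded with a protected covariate level is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_tables import IntensityMatrix


@dataclass
class BatchModel:
    """Fitted per-batch location/scale effects and their EB hyperpriors."""

    batches: list
    gamma_hat: pd.DataFrame  # raw per-protein batch locations (standardized scale)
    delta2_hat: pd.DataFrame  # raw per-protein batch scale factors (variances)
    gamma_star: pd.DataFrame  # shrunken locations
    delta2_star: pd.DataFrame  # shrunken variances
    gamma_bar: dict  # batch -> prior mean of locations
    tau2: dict  # batch -> prior variance of locations
    a_prior: dict  # batch -> inverse-gamma shape
    b_prior: dict  # batch -> inverse-gamma rate
    n_fallback: int  # (protein, batch) cells with <2 observations, set to prior


def _design_matrices(meta: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray, list]:
    batches = list(dict.fromkeys(meta["batch"]))
    B = pd.get_dummies(meta["batch"], dtype=float)[batches].to_numpy()
    if covariates:
        key = meta[list(covariates)].astype(str).agg("|".join, axis=1)
        C = pd.get_dummies(key, dtype=float, drop_first=True).to_numpy()
    else:
        C = np.empty((len(meta), 0))
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is confounded with a covariate level; cannot adjust without "
            "absorbing a biological effect"
        )
    return B, C, batches


def combat_adjust(
    matrix: IntensityMatrix,
    covariates: tuple = ("tissue", "age", "genotype"),
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[IntensityMatrix, BatchModel | None]:
    """Adjust an intensity matrix for its ``batch`` metadata column.

    Parameters
    ----------
    covariates :
        Metadata columns whose joint levels are protected (fit and restored);
        default protects the full condition. Pass ``()`` for no protection.

    Returns the adjusted matrix (same shape, same missingness) and the fitted
    :class:`BatchModel`, or ``(matrix, None)`` when only one batch is present.
    """
    meta = matrix.sample_meta
    if meta["batch"].nunique() < 2:
        return matrix, None
    Y = matrix.values.to_numpy(float)
    obs = ~np.isnan(Y)
    B, C, batches = _design_matrices(meta, covariates)
    X = np.hstack([B, C])
    n_genes, n_samples = Y.shape
    n_batch = len(batches)
    batch_of = meta["batch"].to_numpy()
    batch_cols = {b: np.where(batch_of == b)[0] for b in batches}
    size_frac = np.array([obs[:, batch_cols[b]].sum(1) for b in batches], float).T  # genes x batches

    # --- per-protein covariate-protected fit, grouped by missingness pattern
    beta = np.full((n_genes, X.shape[1]), np.nan)
    patterns: dict[bytes, list] = {}
    for g in range(n_genes):
        patterns.setdefault(obs[g].tobytes(), []).append(g)
    for pat, genes in patterns.items():
        m = np.frombuffer(pat, dtype=bool)
        if m.sum() <= X.shape[1]:
            continue
        Xo = X[m]
        if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
            continue
        coef, *_ = np.linalg.lstsq(Xo, Y[np.ix_(genes, np.where(m)[0])].T, rcond=None)
        beta[genes] = coef.T
    estimable = ~np.isnan(beta).any(axis=1)

    # grand mean: batch-size-weighted mean of batch locations, per protein
    w = size_frac / np.clip(size_frac.sum(1, keepdims=True), 1, None)
    grand = (beta[:, :n_batch] * w).sum(1)
    fit_cov = beta[:, n_batch:] @ C.T if C.shape[1] else np.zeros_like(Y)
    stand_mean = grand[:, None] + fit_cov

    resid = Y - (beta[:, :n_batch] @ B.T + fit_cov)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma2 = np.nanmean(resid ** 2, axis=1)
    sigma = np.sqrt(np.clip(sigma2, 1e-12, None))
    Z = (Y - stand_mean) / sigma[:, None]

    # --- per-batch raw effects
    gamma_hat = np.full((n_genes, n_batch), np.nan)
    delta2_hat = np.full((n_genes, n_batch), np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, b in enumerate(batches):
            zb = Z[:, batch_cols[b]]
            n_obs = np.sum(~np.isnan(zb), axis=1)
            gamma_hat[:, j] = np.where(n_obs >= 1, np.nanmean(zb, axis=1), np.nan)
            v = np.nanvar(zb, axis=1, ddof=1)
            delta2_hat[:, j] = np.where(n_obs >= 2, v, np.nan)

    # --- EB hyperpriors and iterative shrinkage, per batch
    gamma_star = np.array(gamma_hat)
    delta2_star = np.array(delta2_hat)
    gamma_bar, tau2, a_prior, b_prior = {}, {}, {}, {}
    n_fallback = 0
    for j, b in enumerate(batches):
        ok = estimable & ~np.isnan(gamma_hat[:, j]) & ~np.isnan(delta2_hat[:, j])
        g_bar = float(np.mean(gamma_hat[ok, j]))
        t2 = float(np.var(gamma_hat[ok, j], ddof=1))
        d2 = delta2_hat[ok, j]
        m, s2 = float(np.mean(d2)), float(np.var(d2, ddof=1))
        a = (2.0 * s2 + m ** 2) / s2 if s2 > 0 else 2.0
        bp = (m * s2 + m ** 3) / s2 if s2 > 0 else m
        gamma_bar[b], tau2[b], a_prior[b], b_prior[b] = g_bar, t2, a, bp

        idx = np.where(ok)[0]
        n_b = size_frac[idx, j]
        zb = Z[np.ix_(idx, batch_cols[b])]
        g_new = gamma_hat[idx, j].copy()
        d_new = delta2_hat[idx, j].copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (n_b * t2 * gamma_hat[idx, j] + d_new * g_bar) / (n_b * t2 + d_new)
            with np.errstate(invalid="ignore"):
                sse = np.nansum((zb - g_new[:, None]) ** 2, axis=1)
            d_new = (bp + 0.5 * sse) / (n_b / 2.0 + a - 1.0)
            if (np.max(np.abs(g_new - g_old)) < tol) and (np.max(np.abs(d_new - d_old)) < tol):
                break
        gamma_star[idx, j] = g_new
        delta2_star[idx, j] = d_new

        # fallback: too few observations in this batch -> prior expectations
        bad = estimable & ~ok
        n_fallback += int(bad.sum())
        gamma_star[bad, j] = g_bar
        delta2_star[bad, j] = bp / (a - 1.0) if a > 1.0 else m

    # --- adjust
    adj = np.array(Z)
    for j, b in enumerate(batches):
        cols = batch_cols[b]
        adj[:, cols] = (Z[:, cols] - gamma_star[:, j][:, None]) / np.sqrt(
            np.clip(delta2_star[:, j], 1e-12, None)
        )[:, None]
    Y_adj = adj * sigma[:, None] + stand_mean
    Y_adj[~estimable] = Y[~estimable]  # unestimable proteins pass through untouched
    Y_adj[~obs] = np.nan

    out = IntensityMatrix(
        pd.DataFrame(Y_adj, index=matrix.values.index, columns=matrix.values.columns),
        meta.copy(),
        matrix.gene_symbols,
    )
    idx = matrix.values.index
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=idx, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=idx, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=idx, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=idx, columns=batches),
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_fallback=n_fallback,
    )
    return out, model


class ComBatAdjuster(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`combat_adjust`.

    ComBat is transductive: the adjustment is estimated on, and applies to,
    the fitted samples. ``transform`` therefore requires the same sample set
    it was fitted on.
    """

    def __init__(self, covariates: tuple = ("tissue", "age", "genotype")):
        self.covariates = covariates

    def fit(self, X: IntensityMatrix, y=None):
        self.adjusted_, self.model_ = combat_adjust(X, covariates=self.covariates)
        self.samples_ = list(X.values.columns)
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        if list(X.values.columns) != self.samples_:
            raise ValueError("ComBat adjustment only applies to the samples it was fitted on")
        return self.adjusted_
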