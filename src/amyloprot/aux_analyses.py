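"""Small side analyses: transcript-protein intersection, cell-type marker
enrichment, and wild-type expression-level enrichment."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg


def intersect_deg_dep(deg_table: pd.DataFrame, corr_symbols: set) -> tuple[set, float]:
    """Genes significant at both the transcript and the (aggregate-correlated)
    protein level, plus their fraction of the protein universe.

    Both arguments are same-species gene symbols (no ortholog step).
    """
    deg_sig = set(deg_table.loc[deg_table["significant"], "gene_symbol"])
    universe = set(corr_symbols)
    if not universe:
        warnings.warn("empty correlated-protein universe; fraction undefined")
        return set(), float("nan")
    shared = deg_sig & universe
    return shared, len(shared) / len(universe)


def derive_markers(expression: pd.DataFrame, fold: float = 10.0) -> pd.DataFrame:
    """Cell-type markers: expression >= fold x mean of the other cell types.

    ``expression`` is genes x cell types (non-negative means). A gene matching
    the criterion for more than one cell type (possible only with zeros) is
    assigned no marker and logged in the ``ambiguous`` attribute of the result.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    if (expression.to_numpy(float) < 0).any():
        raise ValueError("expressions must be non-negative")
    cell_types = list(expression.columns)
    rows, ambiguous = [], []
    E = expression.to_numpy(float)
    for i, gene in enumerate(expression.index):
        hits = []
        for j, ct in enumerate(cell_types):
            others = np.delete(E[i], j)
            if E[i, j] >= fold * others.mean():
                hits.append(ct)
        if len(hits) == 1:
            rows.append({"gene_symbol": gene, "cell_type": hits[0]})
        elif len(hits) > 1:
            ambiguous.append(gene)
    out = pd.DataFrame(rows, columns=["gene_symbol", "cell_type"])
    out.attrs["ambiguous"] = ambiguous
    return out


def marker_enrichment(dep_set: set, markers: pd.DataFrame, universe: set) -> pd.DataFrame:
    """Per-cell-type overlap count and one-sided hypergeometric enrichment p.

    P-values are BH-adjusted across cell types. The DEP set must be contained
    in the universe.
    """
    dep_set, universe = set(dep_set), set(universe)
    if not dep_set <= universe:
        raise ValueError("dep_set must be a subset of the universe")
    N, n = len(universe), len(dep_set)
    rows = []
    for ct, grp in markers.groupby("cell_type"):
        K = len(set(grp["gene_symbol"]) & universe)
        k = len(set(grp["gene_symbol"]) & dep_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"cell_type": ct, "markers_in_universe": K, "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def wt_median_split(
    wt_expression: pd.Series,
    dep_flags: pd.Series,
    omit_fraction: float = 1.0 / 3.0,
) -> dict:
    """Are highly expressed proteins more often differential than lowly expressed?

    Proteins are ordered by wild-type mean expression; a central band of
    ``omit_fraction`` around the median is omitted (low / medium / high groups,
    medium dropped), and the remaining low/high split is crossed with the
    differential status into a 2x2 table. Returns the table, the odds ratio
    (Haldane-corrected when a cell is empty) and the two-sided Fisher p.
    """
    if len(wt_expression) < 4:
        raise ValueError("need >= 4 proteins")
    if not 0.0 <= omit_fraction < 1.0:
        raise ValueError("omit_fraction must be in [0, 1)")
    dep_flags = dep_flags.reindex(wt_expression.index).fillna(False).astype(bool)
    order = wt_expression.sort_values(kind="mergesort")
    n = len(order)
    n_omit = int(round(omit_fraction * n))
    n_low = (n - n_omit) // 2
    n_high = n - n_omit - n_low
    low = set(order.index[:n_low])
    high = set(order.index[n - n_high:])

    a = int(sum(dep_flags[p] for p in high))      # high & DEP
    b = len(high) - a                             # high & not DEP
    c = int(sum(dep_flags[p] for p in low))       # low & DEP
    d = len(low) - c                              # low & not DEP
    table = np.array([[a, b], [c, d]])
    degenerate = dep_flags.all() or not dep_flags.any()
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        haldane = True
    else:
        odds = (a * d) / (b * c)
        haldane = False
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(odds),
        "p": float(p),
        "haldane": haldane,
        "degenerate": bool(degenerate),
        "n_low": len(low),
        "n_high": len(high),
        "n_omitted": n - len(low) - len(high),
    }
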