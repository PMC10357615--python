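"""Mouse-human ortholog mapping, overlap, concordance and signatures.

Mouse differential results (the hippocampus 5- and 8-month and cortex 8-month
pairwise families, H5/H8/C8) are matched to human differential-abundance
tables (D22/J20/J22) through an ortholog map built from both translation
directions. Connected components of the mouse-human symbol graph that are
one-to-one are resolved; many-to-many components are dropped, one-to-many
components are dropped by default. A protein is *concordant* when it is
significant with the same effect sign in at least one mouse and at least one
human dataset; the top-15 concordantly up- and downregulated proteins (ranked
by the largest absolute mouse log fold-change over significant mouse
datasets) form the Sig+ / Sig- signatures. Human effect sizes stay on their
native scales: only signs and ranks cross the species boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import lfc_spearman_matrix, spearman_with_p
from .diffexpr import benjamini_hochberg


@dataclass
class OrthologResolution:
    """One-to-one resolved mouse-human symbol pairs plus dropped clusters."""

    pairs: pd.DataFrame  # columns mouse_symbol, human_symbol
    dropped_many_to_many: list = field(default_factory=list)
    dropped_one_to_many: list = field(default_factory=list)

    def mouse_to_human(self) -> dict:
        return dict(zip(self.pairs["mouse_symbol"], self.pairs["human_symbol"]))

    def human_to_mouse(self) -> dict:
        return dict(zip(self.pairs["human_symbol"], self.pairs["mouse_symbol"]))


def resolve_orthologs(ortholog_map: pd.DataFrame, keep_one_to_many: bool = False) -> OrthologResolution:
    """Combine both translation directions and resolve to a 1-1 partial matching.

    The union of the m->h and h->m tables defines a bipartite graph; 1-1
    connected components are resolved pairs, many-to-many components are
    dropped, and one-to-many components are dropped by default (set
    ``keep_one_to_many`` to keep the lexicographically first match).
    The result is invariant to the order of the input rows and idempotent.
    """
    edges = ortholog_map[["mouse_symbol", "human_symbol"]].drop_duplicates()
    graph = nx.Graph()
    graph.add_edges_from((("m", m), ("h", h)) for m, h in edges.itertuples(index=False))
    pairs, m2m, o2m = [], [], []
    for comp in nx.connected_components(graph):
        mice = sorted(n for side, n in comp if side == "m")
        humans = sorted(n for side, n in comp if side == "h")
        if len(mice) == 1 and len(humans) == 1:
            pairs.append((mice[0], humans[0]))
        elif len(mice) > 1 and len(humans) > 1:
            m2m.append((tuple(mice), tuple(humans)))
        elif keep_one_to_many:
            pairs.append((mice[0], humans[0]))
        else:
            o2m.append((tuple(mice), tuple(humans)))
    pairs.sort()
    return OrthologResolution(
        pd.DataFrame(pairs, columns=["mouse_symbol", "human_symbol"]),
        sorted(m2m),
        sorted(o2m),
    )


# ---------------------------------------------------------------------------
# overlap accounting
# ---------------------------------------------------------------------------

def overlap_report(mouse_sets: dict, human_sets: dict, resolution: OrthologResolution) -> dict:
    """Venn-region counts between mouse and human significant sets.

    Mouse symbols are translated to human space through the resolution before
    comparison. Returns per-pair ``|A & B|, |A - B|, |B - A|`` and the
    union-wide count of symbols significant in >= 1 mouse and >= 1 human set.
    """
    m2h = resolution.mouse_to_human()
    translated = {name: {m2h[s] for s in ss if s in m2h} for name, ss in mouse_sets.items()}
    human_sets = {name: set(ss) for name, ss in human_sets.items()}
    report = {"pairs": {}, "mouse_translated_sizes": {k: len(v) for k, v in translated.items()}}
    for mname, mset in translated.items():
        for hname, hset in human_sets.items():
            report["pairs"][f"{mname}|{hname}"] = {
                "intersection": len(mset & hset),
                "mouse_only": len(mset - hset),
                "human_only": len(hset - mset),
            }
    mouse_union = set().union(*translated.values()) if translated else set()
    human_union = set().union(*human_sets.values()) if human_sets else set()
    report["union_overlap"] = len(mouse_union & human_union)
    report["union_total"] = len(mouse_union | human_union)
    return report


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance(
    mouse_diff: dict,
    human_tables: dict,
    resolution: OrthologResolution,
    rule: str = "any",
) -> pd.DataFrame:
    """Concordantly dysregulated proteins across species.

    Parameters
    ----------
    mouse_diff :
        Dataset name (e.g. H5, H8, C8) -> differential table with columns
        ``gene_symbol, logfc, significant``.
    human_tables :
        Dataset name -> table with ``gene_symbol, effect, significant``.
    rule :
        ``"any"`` (default): concordant when significant with the same sign in
        >= 1 mouse and >= 1 human dataset. ``"all"``: every dataset in which
        the protein is significant must agree in sign.

    An entry whose significant mouse/human results also contain the opposite
    sign is kept (under ``"any"``) with ``conflict=True``; its direction
    follows the mouse dataset with the largest absolute effect.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    m2h = resolution.mouse_to_human()

    mouse_effects: dict = {}
    for dname, table in mouse_diff.items():
        sig = table[table["significant"]]
        for rec in sig.itertuples(index=False):
            sym = rec.gene_symbol
            if sym in m2h:
                mouse_effects.setdefault(sym, {})[dname] = float(rec.logfc)
    human_effects: dict = {}
    for dname, table in human_tables.items():
        sig = table[table["significant"]]
        for rec in sig.itertuples(index=False):
            human_effects.setdefault(rec.gene_symbol, {})[dname] = float(rec.effect)

    rows = []
    for msym in sorted(mouse_effects):
        hsym = m2h[msym]
        if hsym not in human_effects:
            continue
        m_eff, h_eff = mouse_effects[msym], human_effects[hsym]
        signs_m = {np.sign(v) for v in m_eff.values()}
        signs_h = {np.sign(v) for v in h_eff.values()}
        agree = signs_m & signs_h
        if not agree:
            continue
        all_signs = signs_m | signs_h
        if rule == "all" and len(all_signs) > 1:
            continue
        conflict = len(all_signs) > 1
        lead = max(m_eff.items(), key=lambda kv: abs(kv[1]))
        direction_sign = np.sign(lead[1])
        if direction_sign not in agree:  # lead mouse sign has no human partner
            direction_sign = sorted(agree)[-1]
        rows.append({
            "mouse_symbol": msym,
            "human_symbol": hsym,
            "direction": "up" if direction_sign > 0 else "down",
            "ranking_lfc": max(abs(v) for k, v in m_eff.items()
                               if np.sign(v) == direction_sign),
            "conflict": conflict,
            "mouse_datasets": ";".join(sorted(m_eff)),
            "human_datasets": ";".join(sorted(h_eff)),
        })
    return pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol", "direction",
                                       "ranking_lfc", "conflict", "mouse_datasets",
                                       "human_datasets"])


@dataclass
class Signature:
    sig_plus: pd.DataFrame
    sig_minus: pd.DataFrame
    shortfall: dict = field(default_factory=dict)


def make_signatures(concordant: pd.DataFrame, k: int = 15) -> Signature:
    """Top-k up (Sig+) and down (Sig-) concordant proteins by |mouse logfc|.

    Deterministic: ties at the k-th rank break by lexicographic mouse symbol,
    and the output is independent of input row order.
    """
    if concordant.empty:
        raise ValueError("concordance set is empty")
    sig = {}
    shortfall = {}
    for direction, name in (("up", "sig_plus"), ("down", "sig_minus")):
        sub = concordant[concordant["direction"] == direction].copy()
        sub = sub.sort_values(
            ["ranking_lfc", "mouse_symbol"], ascending=[False, True], kind="mergesort"
        )
        if len(sub) < k:
            shortfall[name] = k - len(sub)
        sig[name] = sub.head(k).reset_index(drop=True)
    return Signature(sig["sig_plus"], sig["sig_minus"], shortfall)


# ---------------------------------------------------------------------------
# cross-species Spearman
# ---------------------------------------------------------------------------

def cross_correlation(
    mouse_diff: dict,
    human_tables: dict,
    resolution: OrthologResolution,
    mode: str = "all",
) -> pd.DataFrame:
    """Spearman of effect sizes for every mouse-human dataset pair.

    ``mode="sig"`` restricts each pair to proteins significant in both
    datasets; ``"all"`` uses every shared protein. P-values are BH-adjusted
    over the matrix.
    """
    if mode not in ("all", "sig"):
        raise ValueError("mode must be 'all' or 'sig'")
    m2h = resolution.mouse_to_human()
    rows = []
    for mname, mtable in mouse_diff.items():
        mt = mtable.copy()
        mt["human_symbol"] = mt["gene_symbol"].map(m2h)
        mt = mt.dropna(subset=["human_symbol"])
        # several protein groups can share a symbol: keep the largest effect
        mt = mt.loc[mt["logfc"].abs().sort_values(ascending=False).index]
        mt = mt.drop_duplicates(subset=["human_symbol"]).set_index("human_symbol")
        for hname, htable in human_tables.items():
            ht = htable.drop_duplicates(subset=["gene_symbol"]).set_index("gene_symbol")
            shared = mt.index.intersection(ht.index)
            if mode == "sig":
                shared = [s for s in shared
                          if mt.loc[s, "significant"] and ht.loc[s, "significant"]]
                shared = pd.Index(shared)
            if len(shared) < 3:
                rows.append({"mouse": mname, "human": hname, "rho": np.nan,
                             "p": np.nan, "n": len(shared)})
                continue
            rho, p = spearman_with_p(
                mt.loc[shared, "logfc"].to_numpy(float), ht.loc[shared, "effect"].to_numpy(float)
            )
            rows.append({"mouse": mname, "human": hname, "rho": rho, "p": p, "n": len(shared)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out.loc[ok, "fdr"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out


__all__ = [
    "OrthologResolution", "resolve_orthologs", "overlap_report", "concordance",
    "Signature", "make_signatures", "cross_correlation", "lfc_spearman_matrix",
]
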