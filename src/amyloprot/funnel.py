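"""Biomarker candidate-selection funnel.

A parameterized, auditable stage sequence over the hippocampal results:

S1  present        reliability-filtered tissue universe
S2  significant    pairwise-model DEPs (FDR < 0.05 at any age of the tissue)
S3  human overlap  ortholog-resolved and significant in >= 1 human dataset
S4  concordant     same direction in mouse and human
S5  correlated+top aggregate-trajectory-correlated AND in the per-age top-k
                   effect-size ranking at all three ages
S6  annotation     carries a configured annotation term (default lysosomal)

Each stage is a conjunctive filter, so the final intersection does not depend
on stage order; counts are non-increasing along the funnel and every stage's
surviving set is recorded. An empty stage propagates empty sets downstream
rather than raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class FunnelStage:
    name: str
    predicate: str
    output: set

    @property
    def count(self) -> int:
        return len(self.output)


@dataclass
class FunnelReport:
    tissue: str
    stages: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def counts(self) -> dict:
        return {s.name: s.count for s in self.stages}

    @property
    def final(self) -> set:
        return self.stages[-1].output if self.stages else set()

    def to_json(self, path=None):
        payload = {
            "tissue": self.tissue,
            "config": self.config,
            "stages": [
                {"name": s.name, "predicate": s.predicate, "count": s.count,
                 "output": sorted(s.output)}
                for s in self.stages
            ],
        }
        if path is None:
            return json.dumps(payload, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FunnelReport":
        with open(path) as fh:
            payload = json.load(fh)
        report = cls(tissue=payload["tissue"], config=payload["config"])
        for s in payload["stages"]:
            report.stages.append(FunnelStage(s["name"], s["predicate"], set(s["output"])))
        return report


def top_k_effect_rank(
    dep_table: pd.DataFrame, tissue: str, k: int = 25, by: str = "moderated_stat"
) -> tuple[dict, set]:
    """Per-age top-k proteins by effect size, and their all-ages intersection.

    ``by`` selects the effect-size reading: ``"moderated_stat"`` (default,
    |moderated t|) or ``"logfc"`` (|log fold-change|). Ties at rank k break by
    the other quantity's magnitude, then lexicographic protein id. Ages with
    fewer than k proteins return all of them.
    """
    if by not in ("moderated_stat", "logfc"):
        raise ValueError("by must be 'moderated_stat' or 'logfc'")
    other = "logfc" if by == "moderated_stat" else "moderated_stat"
    short = {"cortex": "cortex", "hippocampus": "hippo"}[tissue]
    sub = dep_table[dep_table["contrast_id"].str.startswith(f"DE.{short}.Age")].copy()
    if sub.empty:
        return {}, set()
    sub["age"] = sub["contrast_id"].str.rsplit("Age", n=1).str[-1].astype(int)
    per_age = {}
    for age, grp in sub.groupby("age"):
        g = grp.assign(_a=grp[by].abs(), _b=grp[other].abs())
        g = g.sort_values(["_a", "_b", "protein_id"], ascending=[False, False, True],
                          kind="mergesort")
        per_age[int(age)] = set(g["protein_id"].head(k))
    intersection = set.intersection(*per_age.values()) if per_age else set()
    return per_age, intersection


def run_funnel(
    present_set: set,
    dep_table: pd.DataFrame,
    human_significant: dict,
    concordant: pd.DataFrame,
    corr_families: dict,
    annotations: pd.DataFrame,
    symbol_of: dict,
    human_symbol_of: dict,
    tissue: str = "hippocampus",
    top_k: int = 25,
    rank_by: str = "moderated_stat",
    annotation_terms: tuple = ("lysosome", "endo-lysosomal"),
) -> FunnelReport:
    """Run the six-stage selection funnel over one tissue's results.

    Parameters
    ----------
    present_set :
        Reliability-filtered protein universe of the tissue (protein ids).
    dep_table :
        Pairwise-model differential table (``DE.<tissue>.Age<k>`` rows).
    human_significant :
        Human dataset -> set of significant human gene symbols.
    concordant :
        Output of :func:`amyloprot.cross_species.concordance`.
    corr_families :
        Output families of the trajectory classifier (``h_corr`` etc.).
    annotations :
        ``gene_symbol, terms`` table (terms ';'-separated).
    symbol_of / human_symbol_of :
        protein id -> mouse symbol, and mouse symbol -> resolved human symbol.
    """
    prefix = {"cortex": "c", "hippocampus": "h"}[tissue]
    short = {"cortex": "cortex", "hippocampus": "hippo"}[tissue]
    report = FunnelReport(
        tissue=tissue,
        config={"top_k": top_k, "rank_by": rank_by,
                "annotation_terms": list(annotation_terms)},
    )

    s1 = set(present_set)
    report.stages.append(FunnelStage("S1_present", "reliably measured in the tissue", s1))

    sub = dep_table[dep_table["contrast_id"].str.startswith(f"DE.{short}.Age")]
    s2 = s1 & set(sub.loc[sub["significant"], "protein_id"])
    report.stages.append(FunnelStage("S2_significant", "pairwise FDR < 0.05 at any age", s2))

    human_union = set().union(*human_significant.values()) if human_significant else set()
    s3 = {
        p for p in s2
        if human_symbol_of.get(symbol_of.get(p, ""), None) in human_union
    }
    report.stages.append(
        FunnelStage("S3_human_overlap", "significant in >= 1 human dataset", s3)
    )

    concordant_mouse = set(concordant["mouse_symbol"]) if len(concordant) else set()
    s4 = {p for p in s3 if symbol_of.get(p, "") in concordant_mouse}
    report.stages.append(
        FunnelStage("S4_concordant", "same direction in mouse and human", s4)
    )

    corr_set = corr_families.get(f"{prefix}_corr", set()) | corr_families.get(
        f"{prefix}_acorr", set()
    )
    _, top_all_ages = top_k_effect_rank(dep_table, tissue, k=top_k, by=rank_by)
    s5 = s4 & corr_set & top_all_ages
    report.stages.append(
        FunnelStage(
            "S5_correlated_top",
            f"aggregate-correlated and top-{top_k} effect at all ages",
            s5,
        )
    )

    term_of = {}
    for rec in annotations.itertuples(index=False):
        term_of[rec.gene_symbol] = set(str(rec.terms).split(";"))
    wanted = set(annotation_terms)
    s6 = {p for p in s5 if term_of.get(symbol_of.get(p, ""), set()) & wanted}
    report.stages.append(
        FunnelStage("S6_annotation", f"annotated with {sorted(wanted)}", s6)
    )
    return report
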