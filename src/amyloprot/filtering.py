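"""No-imputation reliability filtering.

A protein is *reliably measured* in a condition (tissue, age, genotype cell)
when strictly fewer than half of that condition's samples are missing;
"half of the samples or more missing" marks it unreliable. Technical
replicates count as samples in the denominator. The comparison is done in
exact integer arithmetic (``2 * n_missing < n_samples``) so odd sample counts
behave deterministically: with 15 samples, 7 missing is reliable and 8 is not.

Three analysis sets build on the per-condition flags:

* per-tissue universe — a protein stays unless it is unreliable in *every*
  condition of the tissue (default reading; the stricter any-condition
  reading is available via ``reading="any-condition"``);
* pairwise set — reliable in both genotypes at one (tissue, age), the
  universe of the per-age transgenic-vs-wild-type comparisons;
* full-model set — reliable in every condition of both tissues, intersected
  across tissues after reconciling protein-group identifiers, with
  many-to-many identifier relations discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_tables import IntensityMatrix


@dataclass
class FilterReport:
    """Audit record of one filtering stage."""

    stage: str
    proteins_in: int
    proteins_out: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proteins_out > self.proteins_in:
            raise ValueError("proteins_out cannot exceed proteins_in")

    def to_json(self, path=None):
        payload = {
            "stage": self.stage,
            "proteins_in": self.proteins_in,
            "proteins_out": self.proteins_out,
            "details": self.details,
        }
        if path is None:
            return json.dumps(payload, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def condition_reliability(matrix: IntensityMatrix) -> pd.DataFrame:
    """Boolean proteins x conditions table: strictly < half missing.

    Columns are (tissue, age, genotype) tuples. Raises if any condition has
    fewer than 2 samples.
    """
    cond = matrix.condition_of()
    flags = {}
    for key, samples in cond.groupby(cond).groups.items():
        n = len(samples)
        if n < 2:
            raise ValueError(f"condition {key} has {n} sample(s); need >= 2")
        n_missing = matrix.values[list(samples)].isna().sum(axis=1)
        flags[key] = 2 * n_missing < n
    out = pd.DataFrame(flags)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tissue", "age", "genotype"])
    return out


def filter_tissue(
    matrix: IntensityMatrix, tissue: str, reading: str = "all-conditions"
) -> tuple[IntensityMatrix, FilterReport]:
    """Per-tissue reliability universe.

    ``reading="all-conditions"`` (default): excluded only when unreliable in
    every condition of the tissue. ``reading="any-condition"``: excluded when
    unreliable in any condition.
    """
    sub = matrix.subset_tissue(tissue)
    rel = condition_reliability(sub)
    if reading == "all-conditions":
        keep = rel.any(axis=1)
    elif reading == "any-condition":
        keep = rel.all(axis=1)
    else:
        raise ValueError("reading must be 'all-conditions' or 'any-condition'")
    filtered = sub.subset_proteins(sub.protein_ids[keep])
    report = FilterReport(
        stage=f"filter_tissue[{tissue}]",
        proteins_in=sub.n_proteins,
        proteins_out=filtered.n_proteins,
        details={
            "reading": reading,
            "reliable_per_condition": {
                str(c): int(rel[c].sum()) for c in rel.columns
            },
        },
    )
    return filtered, report


def pairwise_analysis_set(matrix: IntensityMatrix, tissue: str, age) -> set:
    """Proteins reliable in both genotypes at one (tissue, age)."""
    sub = matrix.subset_tissue(tissue)
    rel = condition_reliability(sub)
    cols = [c for c in rel.columns if c[0] == tissue and c[1] == age]
    genotypes = {c[2] for c in cols}
    if len(genotypes) < 2:
        raise ValueError(f"missing genotype condition at ({tissue}, {age})")
    keep = rel[cols].all(axis=1)
    return set(rel.index[keep])


def _all_condition_set(matrix: IntensityMatrix, tissue: str) -> set:
    rel = condition_reliability(matrix.subset_tissue(tissue))
    return set(rel.index[rel.all(axis=1)])


def full_model_set(
    matrix_cortex: IntensityMatrix,
    matrix_hippo: IntensityMatrix,
    name_map: pd.DataFrame | None = None,
    keep_one_to_many: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Cross-tissue full-model universe.

    Per tissue, keeps proteins reliable in all conditions at all ages in both
    genotypes, then intersects the two tissues after reconciling protein-group
    identifiers through ``name_map`` (columns ``cortex_id, hippo_id``; default:
    identity on shared identifiers). Any identifier relation that is
    many-to-many between the tissue datasets is discarded before intersection;
    one-to-many relations are discarded by default as well.

    Returns the resolved (cortex_id, hippo_id) pairs and a report.
    """
    tissue_c = matrix_cortex.sample_meta["tissue"].iloc[0]
    tissue_h = matrix_hippo.sample_meta["tissue"].iloc[0]
    set_c = _all_condition_set(matrix_cortex, tissue_c)
    set_h = _all_condition_set(matrix_hippo, tissue_h)

    if name_map is None:
        shared = sorted(set_c & set_h)
        name_map = pd.DataFrame({"cortex_id": shared, "hippo_id": shared})
    links = name_map[
        name_map["cortex_id"].isin(set_c) & name_map["hippo_id"].isin(set_h)
    ].drop_duplicates()

    graph = nx.Graph()
    graph.add_edges_from(
        (("c", c), ("h", h)) for c, h in zip(links["cortex_id"], links["hippo_id"])
    )
    pairs, dropped_m2m, dropped_o2m = [], 0, 0
    for comp in nx.connected_components(graph):
        c_ids = sorted(n for side, n in comp if side == "c")
        h_ids = sorted(n for side, n in comp if side == "h")
        if len(c_ids) == 1 and len(h_ids) == 1:
            pairs.append((c_ids[0], h_ids[0]))
        elif len(c_ids) > 1 and len(h_ids) > 1:
            dropped_m2m += len(c_ids) + len(h_ids)
        elif keep_one_to_many:
            # keep the lexicographically first match on the many side
            pairs.append((c_ids[0], h_ids[0]))
            dropped_o2m += len(c_ids) + len(h_ids) - 2
        else:
            dropped_o2m += len(c_ids) + len(h_ids)
    pairs.sort()
    out = pd.DataFrame(pairs, columns=["cortex_id", "hippo_id"])
    report = FilterReport(
        stage="full_model_set",
        proteins_in=len(set_c) + len(set_h),
        proteins_out=2 * len(out),
        details={
            "cortex_all_conditions": len(set_c),
            "hippo_all_conditions": len(set_h),
            "resolved_pairs": len(out),
            "dropped_many_to_many": dropped_m2m,
            "dropped_one_to_many": dropped_o2m,
            "keep_one_to_many": keep_one_to_many,
        },
    )
    return out, report


class ReliabilityFilter(BaseEstimator, TransformerMixin):
    """Transformer view of the per-tissue reliability filter.

    Parameters
    ----------
    tissue :
        Tissue whose conditions define the filter. If None, the (single)
        tissue present in the fitted matrix is used.
    reading :
        ``"all-conditions"`` (default; drop only if unreliable everywhere) or
        ``"any-condition"``.
    """

    def __init__(self, tissue: str | None = None, reading: str = "all-conditions"):
        self.tissue = tissue
        self.reading = reading

    def fit(self, X: IntensityMatrix, y=None):
        tissue = self.tissue or X.sample_meta["tissue"].iloc[0]
        _, self.report_ = filter_tissue(X, tissue, reading=self.reading)
        sub = X.subset_tissue(tissue)
        self.reliability_ = condition_reliability(sub)
        if self.reading == "all-conditions":
            keep = self.reliability_.any(axis=1)
        else:
            keep = self.reliability_.all(axis=1)
        self.keep_ = set(self.reliability_.index[keep])
        self.tissue_ = tissue
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        sub = X.subset_tissue(self.tissue_)
        keep = [p for p in sub.protein_ids if p in self.keep_]
        return sub.subset_proteins(keep)
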