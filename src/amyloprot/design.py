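"""Study design: tissues x ages x genotypes with biological and technical replicates.

The default design mirrors a two-region, three-age transgenic-vs-wild-type
LFQ proteomics study: cortex and hippocampus collected at 2, 5 and 8 months
from 5 transgenic and 5 wild-type animals per age, each homogenate measured
in 2 technical MS replicates (3 for the 5-month hippocampus runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TISSUES = ("cortex", "hippocampus")
AGES = (2, 5, 8)
GENOTYPES = ("WT", "TG")

#: metadata columns every sample table must carry
META_COLUMNS = ("sample", "tissue", "age", "genotype", "animal_id", "tech_rep", "batch")


def _default_tech_reps() -> dict:
    reps = {(t, a): 2 for t in TISSUES for a in AGES}
    reps[("hippocampus", 5)] = 3
    return reps


@dataclass
class StudyDesign:
    """Factorial sampling design of the study.

    Parameters
    ----------
    tissues, ages, genotypes :
        Factor levels. Ages are ordered and given in months.
    n_animals_per_condition :
        Biological replicates per (tissue, age, genotype) cell.
    n_tech_reps :
        Technical (MS re-injection) replicates per (tissue, age); defaults to 2
        everywhere except 3 for the 5-month hippocampus.
    n_batches_per_tissue :
        Acquisition batches; animals of a tissue are split round-robin over
        batches, so no batch is confounded with age or genotype.
    """

    tissues: tuple = TISSUES
    ages: tuple = AGES
    genotypes: tuple = GENOTYPES
    n_animals_per_condition: int = 5
    n_tech_reps: dict = field(default_factory=_default_tech_reps)
    n_batches_per_tissue: int = 2

    def __post_init__(self) -> None:
        if self.n_animals_per_condition < 2:
            raise ValueError("every condition needs >= 2 biological replicates")
        if len(self.ages) < 1:
            raise ValueError("need >= 1 age")
        if self.n_batches_per_tissue < 1:
            raise ValueError("need >= 1 batch per tissue")
        self.ages = tuple(sorted(self.ages))

    def tech_reps(self, tissue: str, age: int) -> int:
        return int(self.n_tech_reps.get((tissue, age), 2))

    def conditions(self, tissue: str | None = None) -> list:
        """(tissue, age, genotype) cells, optionally restricted to one tissue."""
        tissues = self.tissues if tissue is None else (tissue,)
        return [(t, a, g) for t in tissues for a in self.ages for g in self.genotypes]

    def sample_table(self) -> pd.DataFrame:
        """One row per MS run with condition labels, animal, replicate and batch.

        Animals are shared between tissues (both regions are dissected from the
        same mouse); technical replicates are per tissue homogenate. Batch
        assignment alternates animals within a tissue so genotype and age are
        balanced across batches.
        """
        rows = []
        for tissue in self.tissues:
            for age in self.ages:
                for genotype in self.genotypes:
                    for i in range(self.n_animals_per_condition):
                        animal = f"{genotype}_{age}m_{i + 1}"
                        batch = f"{tissue[:3]}_b{i % self.n_batches_per_tissue + 1}"
                        for rep in range(1, self.tech_reps(tissue, age) + 1):
                            rows.append(
                                {
                                    "sample": f"{tissue}_{age}m_{genotype}_{i + 1}_r{rep}",
                                    "tissue": tissue,
                                    "age": age,
                                    "genotype": genotype,
                                    "animal_id": animal,
                                    "tech_rep": rep,
                                    "batch": batch,
                                }
                            )
        table = pd.DataFrame(rows)
        if table["sample"].duplicated().any():
            raise ValueError("duplicate sample names in design")
        return table


def validate_sample_meta(meta: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Check a metadata table against the closed design vocabulary."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks required column(s): {missing}")
    if meta["sample"].duplicated().any():
        dupes = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    design = design or StudyDesign()
    for column, allowed in (
        ("tissue", design.tissues),
        ("age", design.ages),
        ("genotype", design.genotypes),
    ):
        bad = set(meta[column]) - set(allowed)
        if bad:
            raise ValueError(
                f"unknown {column} label(s) {sorted(map(str, bad))}; allowed: {list(allowed)}"
            )
    return meta
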