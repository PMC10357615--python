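"""Reliability-filter rules against brute-force enumeration and boundaries."""

import numpy as np
import pandas as pd
import pytest

from amyloprot.design import StudyDesign
from amyloprot.filtering import (
    ReliabilityFilter,
    condition_reliability,
    filter_tissue,
    full_model_set,
    pairwise_analysis_set,
)


def brute_force_reliable(values: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Independent oracle: literal per-condition enumeration of the rule."""
    out = {}
    for (t, a, g), grp in meta.groupby(["tissue", "age", "genotype"]):
        cols = grp["sample"]
        for p in values.index:
            n_missing = sum(pd.isna(values.loc[p, c]) for c in cols)
            out[(p, (t, a, g))] = n_missing < len(cols) / 2
    return out


def random_toy(seed: int, design: StudyDesign, n_proteins: int = 12):
    rng = np.random.default_rng(seed)
    meta = design.sample_table()
    vals = rng.normal(7, 1, (n_proteins, len(meta)))
    vals[rng.random(vals.shape) < rng.uniform(0.1, 0.7)] = np.nan
    ids = [f"P{i}" for i in range(n_proteins)]
    from amyloprot.io_tables import IntensityMatrix

    return IntensityMatrix(pd.DataFrame(vals, index=ids, columns=meta["sample"]), meta)


class TestConditionReliability:
    def test_half_or_more_boundary(self, toy_matrix_factory):
        """10 samples: 4 missing -> reliable, 5 missing -> unreliable."""
        design = StudyDesign(tissues=("cortex",), ages=(2,), genotypes=("WT",))
        meta = design.sample_table()  # 5 animals x 2 reps = 10 samples
        vals = np.full((2, 10), 7.0)
        vals[0, :4] = np.nan
        vals[1, :5] = np.nan
        m = toy_matrix_factory(vals, meta)
        rel = condition_reliability(m)
        assert bool(rel.iloc[0, 0]) is True
        assert bool(rel.iloc[1, 0]) is False

    def test_odd_count_boundary(self, toy_matrix_factory):
        """15 samples (5-month hippocampus): 7 missing reliable, 8 missing not."""
        design = StudyDesign(tissues=("hippocampus",), ages=(5,), genotypes=("TG",))
        meta = design.sample_table()  # 5 animals x 3 reps = 15
        vals = np.full((2, 15), 7.0)
        vals[0, :7] = np.nan
        vals[1, :8] = np.nan
        rel = condition_reliability(toy_matrix_factory(vals, meta))
        assert bool(rel.iloc[0, 0]) is True and bool(rel.iloc[1, 0]) is False

    def test_no_missing_reliable_everywhere(self, toy_matrix_factory):
        meta = StudyDesign().sample_table()
        rel = condition_reliability(toy_matrix_factory(np.full((3, len(meta)), 7.0), meta))
        assert rel.all().all()

    def test_matches_bruteforce(self):
        design = StudyDesign(n_animals_per_condition=2)
        for seed in range(25):
            m = random_toy(seed, design)
            rel = condition_reliability(m)
            oracle = brute_force_reliable(m.values, m.sample_meta)
            for p in m.protein_ids:
                for c in rel.columns:
                    assert bool(rel.loc[p, c]) == oracle[(p, tuple(c))]


class TestTissueAndPairwiseSets:
    def test_reliable_in_exactly_one_condition_kept(self, toy_matrix_factory):
        design = StudyDesign(tissues=("cortex",), n_animals_per_condition=2)
        meta = design.sample_table()
        vals = np.full((1, len(meta)), np.nan)
        first_cond = (meta["age"] == 2) & (meta["genotype"] == "WT")
        vals[0, np.where(first_cond)[0]] = 7.0
        m = toy_matrix_factory(vals, meta)
        filtered, report = filter_tissue(m, "cortex")
        assert filtered.n_proteins == 1 and report.proteins_out == 1
        # stricter reading excludes it
        filtered_any, _ = filter_tissue(m, "cortex", reading="any-condition")
        assert filtered_any.n_proteins == 0

    def test_unreliable_everywhere_excluded(self, toy_matrix_factory):
        design = StudyDesign(tissues=("cortex",), n_animals_per_condition=2)
        meta = design.sample_table()
        m = toy_matrix_factory(np.full((2, len(meta)), np.nan), meta)
        filtered, _ = filter_tissue(m, "cortex")
        assert filtered.n_proteins == 0

    def test_pairwise_requires_both_genotypes(self, toy_matrix_factory):
        design = StudyDesign(tissues=("cortex",), n_animals_per_condition=2)
        meta = design.sample_table()
        vals = np.full((3, len(meta)), 7.0)
        tg2 = (meta["age"] == 2) & (meta["genotype"] == "TG")
        vals[0, np.where(tg2)[0]] = np.nan  # unreliable in TG only -> excluded
        m = toy_matrix_factory(vals, meta)
        assert pairwise_analysis_set(m, "cortex", 2) == {"P0002", "P0003"}

    def test_pairwise_matches_bruteforce_intersection(self):
        design = StudyDesign(n_animals_per_condition=2)
        for seed in range(10):
            m = random_toy(seed + 100, design)
            oracle = brute_force_reliable(m.values, m.sample_meta)
            for tissue in design.tissues:
                for age in design.ages:
                    expected = {
                        p for p in m.protein_ids
                        if oracle[(p, (tissue, age, "WT"))] and oracle[(p, (tissue, age, "TG"))]
                    }
                    assert pairwise_analysis_set(m, tissue, age) == expected

    def test_monotonicity_adding_observation_never_removes(self):
        """Filling in one missing value can only grow every output set."""
        design = StudyDesign(n_animals_per_condition=2)
        rng = np.random.default_rng(0)
        for seed in range(10):
            m = random_toy(seed + 200, design)
            missing = np.argwhere(m.values.isna().to_numpy())
            if len(missing) == 0:
                continue
            i, j = missing[rng.integers(len(missing))]
            m2 = m.values.copy()
            m2.iloc[i, j] = 7.0
            from amyloprot.io_tables import IntensityMatrix

            m2 = IntensityMatrix(m2, m.sample_meta)
            rel1 = condition_reliability(m)
            rel2 = condition_reliability(m2)
            assert (rel2 | ~rel1).all().all()  # rel1 => rel2


class TestFullModel:
    def test_full_subset_of_pairwise(self, smoke_results):
        filtered = smoke_results["filtered"]
        pairs, _ = full_model_set(filtered["cortex"], filtered["hippocampus"])
        full_c = set(pairs["cortex_id"])
        for tissue, key in (("cortex", "cortex_id"), ("hippocampus", "hippo_id")):
            full = set(pairs[key])
            for age in (2, 5, 8):
                assert full <= pairwise_analysis_set(filtered[tissue], tissue, age)

    def test_protein_missing_one_condition_excluded(self, toy_matrix_factory):
        design = StudyDesign(n_animals_per_condition=2)
        meta = design.sample_table()
        vals = np.full((2, len(meta)), 7.0)
        bad = (meta["tissue"] == "cortex") & (meta["age"] == 5) & (meta["genotype"] == "WT")
        vals[0, np.where(bad)[0]] = np.nan  # unreliable in exactly one condition
        m = toy_matrix_factory(vals, meta)
        pairs, _ = full_model_set(m.subset_tissue("cortex"), m.subset_tissue("hippocampus"))
        assert set(pairs["cortex_id"]) == {"P0002"}

    def test_many_to_many_cluster_dropped(self, toy_matrix_factory):
        design = StudyDesign(n_animals_per_condition=2)
        meta = design.sample_table()
        vals = np.full((6, len(meta)), 7.0)
        m = toy_matrix_factory(vals, meta)
        cm, hm = m.subset_tissue("cortex"), m.subset_tissue("hippocampus")
        name_map = pd.DataFrame({
            # 3x3 fully ambiguous cluster + one clean pair
            "cortex_id": ["P0001", "P0001", "P0002", "P0002", "P0003", "P0003", "P0004"],
            "hippo_id": ["P0001", "P0002", "P0001", "P0003", "P0002", "P0003", "P0004"],
        })
        pairs, report = full_model_set(cm, hm, name_map=name_map)
        assert set(pairs["cortex_id"]) == {"P0004"}
        assert report.details["dropped_many_to_many"] == 6

    def test_one_to_many_policy(self, toy_matrix_factory):
        design = StudyDesign(n_animals_per_condition=2)
        meta = design.sample_table()
        m = toy_matrix_factory(np.full((3, len(meta)), 7.0), meta)
        name_map = pd.DataFrame({
            "cortex_id": ["P0001", "P0001"], "hippo_id": ["P0001", "P0002"],
        })
        pairs, _ = full_model_set(
            m.subset_tissue("cortex"), m.subset_tissue("hippocampus"), name_map=name_map
        )
        assert pairs.empty  # dropped by default
        pairs, _ = full_model_set(
            m.subset_tissue("cortex"), m.subset_tissue("hippocampus"),
            name_map=name_map, keep_one_to_many=True,
        )
        assert len(pairs) == 1


class TestTransformer:
    def test_transformer_equivalence_and_params(self):
        design = StudyDesign(n_animals_per_condition=2)
        m = random_toy(7, design)
        est = ReliabilityFilter(tissue="cortex")
        out = est.fit(m).transform(m)
        direct, _ = filter_tissue(m, "cortex")
        assert list(out.protein_ids) == list(direct.protein_ids)
        assert est.get_params() == {"tissue": "cortex", "reading": "all-conditions"}
        est.set_params(reading="any-condition")
        assert est.reading == "any-condition"
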