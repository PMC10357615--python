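"""Moderated statistics: BH, shrinkage limits, GLS, consensus correlation,
and the limma oracle."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from amyloprot.design import StudyDesign
from amyloprot.diffexpr import (
    ModeratedLinearModel,
    benjamini_hochberg,
    estimate_consensus_correlation,
    full_model_contrasts,
    moderated_variance,
    pairwise_fit,
    squeeze_variances,
    transgene_contrast,
)
from amyloprot.io_tables import IntensityMatrix
from amyloprot.simulate import GeneratorParams, simulate_lfq

NO_MISS = dict(missing_midpoint=-1e9, missing_slope=1.0)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_inputs(self):
        assert benjamini_hochberg([]).size == 0
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        fdr = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(benjamini_hochberg(p), expected, rtol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def simple_matrix(seed=0, n=120, n_animals=4, effect_first=0.0):
    """One tissue, one age, two genotypes, independent noise."""
    rng = np.random.default_rng(seed)
    design = StudyDesign(tissues=("cortex",), ages=(2, 8),
                         n_animals_per_condition=n_animals)
    meta = design.sample_table()
    meta = meta[meta["age"] == 8].reset_index(drop=True)
    Y = rng.normal(7, 0.6, n)[:, None] + rng.normal(0, 0.15, (n, len(meta)))
    if effect_first:
        Y[: n // 5, (meta["genotype"] == "TG").to_numpy()] += effect_first
    ids = [f"P{i:04d}" for i in range(n)]
    return IntensityMatrix(pd.DataFrame(Y, index=ids, columns=meta["sample"]), meta)


class TestModerationLimits:
    def test_prior_df_zero_equals_ordinary_t(self):
        m = simple_matrix(seed=2, effect_first=0.3)
        model = ModeratedLinearModel(rho=0.0, prior_df=0).fit(m)
        res = model.contrast(dict([transgene_contrast("cortex", 8)]))
        meta = m.sample_meta
        tg = meta.loc[meta["genotype"] == "TG", "sample"]
        wt = meta.loc[meta["genotype"] == "WT", "sample"]
        t_ref = stats.ttest_ind(m.values[tg], m.values[wt], axis=1).statistic
        np.testing.assert_allclose(res["moderated_stat"].to_numpy(), t_ref, atol=1e-12)

    def test_prior_df_inf_pools_variance(self):
        m = simple_matrix(seed=3)
        model = ModeratedLinearModel(rho=0.0, prior_df=np.inf).fit(m)
        s2 = moderated_variance(model.sigma2_.to_numpy(), model.df_resid_.to_numpy(),
                                model.prior_df_, model.prior_var_)
        assert np.allclose(s2, model.prior_var_)

    def test_moderated_variance_is_bounded_convex_combination(self):
        rng = np.random.default_rng(4)
        s2 = rng.chisquare(5, 200) / 5
        df = np.full(200, 8.0)
        d0, s02 = squeeze_variances(s2, df)
        post = moderated_variance(s2, df, d0, s02)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_gls_rho_zero_equals_ols(self):
        m = simple_matrix(seed=5)
        a = ModeratedLinearModel(rho=0.0).fit(m)
        b = ModeratedLinearModel(rho=1e-15).fit(m)
        pd.testing.assert_frame_equal(a.coef_, b.coef_, atol=1e-10, rtol=0)

    def test_single_protein_logfc_is_mean_difference(self):
        meta = StudyDesign(tissues=("cortex",), ages=(2, 8),
                           n_animals_per_condition=3).sample_table()
        meta = meta[meta["age"] == 8].reset_index(drop=True)
        vals = np.arange(len(meta), dtype=float)[None, :]
        m = IntensityMatrix(pd.DataFrame(vals, index=["P1"], columns=meta["sample"]), meta)
        model = ModeratedLinearModel(rho=0.0, prior_df=0).fit(m)
        res = model.contrast(dict([transgene_contrast("cortex", 8)]))
        tg = vals[0, (meta["genotype"] == "TG").to_numpy()].mean()
        wt = vals[0, (meta["genotype"] == "WT").to_numpy()].mean()
        assert res["logfc"].iloc[0] == pytest.approx(tg - wt, abs=1e-12)

    def test_difference_contrast_must_balance(self):
        m = simple_matrix(seed=6, n=10)
        model = ModeratedLinearModel(rho=0.0).fit(m)
        with pytest.raises(ValueError):
            model.contrast({"bad": {("cortex", 8, "TG"): 1.0,
                                    ("cortex", 8, "WT"): -0.5,
                                    ("cortex", 2, "WT"): -0.2}})


class TestLimmaOracle:
    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_moderated_t_matches_limma(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes on a complete two-group
        matrix reproduces d0, s0^2 and every moderated t and p."""
        m = simple_matrix(seed=7, n=90, effect_first=0.4)
        model = ModeratedLinearModel(rho=0.0, prior_df="auto").fit(m)
        res = model.contrast(dict([transgene_contrast("cortex", 8)]))
        m.values.to_csv(tmp_path / "y.csv")
        m.sample_meta.to_csv(tmp_path / "meta.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1, check.names=FALSE))\n'
            f'meta <- read.csv("{tmp_path}/meta.csv")\n'
            'design <- model.matrix(~factor(meta$genotype, levels=c("WT","TG")))\n'
            'fit <- eBayes(lmFit(y, design))\n'
            'out <- data.frame(protein=rownames(y), t=fit$t[,2], p=fit$p.value[,2],\n'
            '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.csv(out, "{tmp_path}/limma.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        limma = pd.read_csv(tmp_path / "limma.csv")
        merged = res.merge(limma, left_on="protein_id", right_on="protein")
        assert model.prior_df_ == pytest.approx(limma["d0"].iloc[0], rel=1e-9)
        assert model.prior_var_ == pytest.approx(limma["s02"].iloc[0], rel=1e-9)
        np.testing.assert_allclose(merged["moderated_stat"], merged["t"], atol=1e-10)
        np.testing.assert_allclose(merged["p_value"], merged["p"], atol=1e-10)


class TestConsensusCorrelation:
    def _generated(self, animal_sd, tech_sd, seed, n=800):
        params = GeneratorParams(
            n_proteins=n, animal_sd=animal_sd, tech_sd=tech_sd,
            planted_dep_fraction=0.0, candidate=None, batch_shift_sd=0.0,
            batch_scale_sd=0.0, rng_seed=seed, **NO_MISS,
        )
        matrix, _ = simulate_lfq(StudyDesign(tissues=("cortex",)), params)
        return matrix

    def test_identical_technical_replicates(self):
        rho = estimate_consensus_correlation(self._generated(0.1, 1e-6, seed=1, n=300))
        assert rho > 0.98

    def test_independent_replicates_near_zero(self):
        rho = estimate_consensus_correlation(self._generated(0.0, 0.1, seed=2, n=2000))
        assert abs(rho) < 0.05

    def test_planted_intraclass_correlation_recovered(self):
        # animal_sd = tech_sd -> true ICC = 0.5
        rho = estimate_consensus_correlation(self._generated(0.1, 0.1, seed=3, n=2000))
        assert 0.4 <= rho <= 0.6

    def test_no_replicates_warns_and_returns_zero(self):
        m = self._generated(0.1, 0.1, seed=4, n=20)
        meta = m.sample_meta[m.sample_meta["tech_rep"] == 1].reset_index(drop=True)
        m1 = IntensityMatrix(m.values[meta["sample"]], meta)
        with pytest.warns(UserWarning):
            assert estimate_consensus_correlation(m1) == 0.0


class TestFullVsPairwise:
    def test_t_statistics_agree_between_models(self, smoke_results):
        """Aggregating all conditions into the full model must not distort the
        per-condition transgene effects (the models' t statistics correlate)."""
        full = smoke_results["full_results"]
        pairwise = smoke_results["pairwise"]
        mapping = {"A8TH": "DE.hippo.Age8", "A8TC": "DE.cortex.Age8",
                   "A5TH": "DE.hippo.Age5"}
        for fid, pid in mapping.items():
            f = full[full["contrast_id"] == fid].set_index("protein_id")["moderated_stat"]
            p = pairwise[pairwise["contrast_id"] == pid].set_index("protein_id")["moderated_stat"]
            shared = f.index.intersection(p.index)
            assert len(shared) > 50
            r = np.corrcoef(f.loc[shared], p.loc[shared])[0, 1]
            assert r >= 0.9

    def test_full_model_contrast_set_shape(self):
        contrasts = full_model_contrasts()
        assert len(contrasts) == 15
        for cid, c in contrasts.items():
            if len(c) > 2:
                assert sum(c.values()) == pytest.approx(0.0)

    def test_pairwise_significant_counts(self, smoke_results):
        pw = smoke_results["pairwise"]
        for cid, grp in pw.groupby("contrast_id"):
            assert (grp["significant"] == (grp["fdr"] < 0.05)).all()
            # BH is monotone within the contrast
            order = np.argsort(grp["p_value"].to_numpy())
            assert np.all(np.diff(grp["fdr"].to_numpy()[order]) >= -1e-15)
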