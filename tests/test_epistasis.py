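"""Interaction decomposition, gene-set utilities, expression GLM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mitoepi.epistasis import (
    expression_interaction_glm,
    gene_set_overrepresentation,
    interaction_scan,
    restrict_to_gene_set,
    test_interaction,
)
from mitoepi.io import PhenotypeTable, VariantInfo
from mitoepi.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def inter_cohort():
    cfg = SimulationConfig(
        n_samples=600, n_nuclear_snps=30, n_mito_snps=4, seed=71,
        causal_mito="mt000", causal_nuc="nuc00000", beta_inter=2.0,
        mito_mafs=0.2, nuclear_mafs=0.3,
    )
    return simulate_cohort(cfg)


def two_model_oracle(y, C, m, g):
    """Independent two-model least-squares oracle via statsmodels."""
    X_S = sm.add_constant(np.column_stack([C, m, g]))
    X_I = sm.add_constant(np.column_stack([C, m, g, m * g]))
    f_S, f_I = sm.OLS(y, X_S).fit(), sm.OLS(y, X_I).fit()
    z = lambda f, i: 2 * stats.norm.sf(abs(f.params[i] / f.bse[i]))
    return {
        "nuc_eff_single": f_S.params[-1], "nuc_pval_single": z(f_S, -1),
        "mito_eff_joint": f_I.params[-3], "mito_pval_joint": z(f_I, -3),
        "nuc_eff_joint": f_I.params[-2], "nuc_pval_joint": z(f_I, -2),
        "inter_eff": f_I.params[-1], "inter_se": f_I.bse[-1],
        "inter_pval": z(f_I, -1),
        "f_I": f_I, "f_S": f_S,
    }


class TestInteractionOracle:
    def test_matches_two_model_oracle_to_1e8(self, inter_cohort):
        p, g = inter_cohort.phenotypes, inter_cohort.genotypes
        C = p.covariates(["age", "sex"])
        m, gn = g.dosage_of("mt000"), g.dosage_of("nuc00000")
        r = test_interaction(p, ["age", "sex"], m, gn)
        o = two_model_oracle(p.bmi, C, m, gn)
        for fieldname in (
            "nuc_eff_single", "nuc_pval_single", "nuc_eff_joint",
            "nuc_pval_joint", "mito_eff_joint", "mito_pval_joint",
            "inter_eff", "inter_se", "inter_pval",
        ):
            assert getattr(r, fieldname) == pytest.approx(
                o[fieldname], abs=1e-8
            ), fieldname

    def test_joint_pval_equals_nested_f_oracle(self, inter_cohort):
        p, g = inter_cohort.phenotypes, inter_cohort.genotypes
        C = p.covariates(["age", "sex"])
        m, gn = g.dosage_of("mt000"), g.dosage_of("nuc00001")
        r = test_interaction(p, ["age", "sex"], m, gn)
        # sum-of-squares F comparison: model I vs covariates + mito only
        X_0 = sm.add_constant(np.column_stack([C, m]))
        X_I = sm.add_constant(np.column_stack([C, m, gn, m * gn]))
        f0, fI = sm.OLS(p.bmi, X_0).fit(), sm.OLS(p.bmi, X_I).fit()
        F = ((f0.ssr - fI.ssr) / 2) / (fI.ssr / fI.df_resid)
        p_oracle = stats.f.sf(F, 2, fI.df_resid)
        assert r.joint_pval == pytest.approx(p_oracle, abs=1e-6)

    def test_rescaling_dosage_rescales_interaction_exactly(self, inter_cohort):
        p, g = inter_cohort.phenotypes, inter_cohort.genotypes
        m, gn = g.dosage_of("mt000"), g.dosage_of("nuc00000")
        r1 = test_interaction(p, ["age", "sex"], m, gn)
        r2 = test_interaction(p, ["age", "sex"], m, 2.0 * gn)
        assert r2.inter_eff == pytest.approx(r1.inter_eff / 2.0, rel=1e-10)
        assert r2.inter_pval == pytest.approx(r1.inter_pval, rel=1e-9)

    def test_decomposition_converges_without_interaction(self):
        # with beta_inter = 0 the nuclear effect is stable across models
        cfg = SimulationConfig(
            n_samples=4000, n_nuclear_snps=2, n_mito_snps=1, seed=72,
            causal_mito="mt000", causal_nuc="nuc00000",
            beta_nuc=0.4, mito_mafs=0.3, nuclear_mafs=0.3,
        )
        c = simulate_cohort(cfg)
        r = test_interaction(
            c.phenotypes, ["age", "sex"],
            c.genotypes.dosage_of("mt000"), c.genotypes.dosage_of("nuc00000"),
        )
        assert r.nuc_eff_single == pytest.approx(r.nuc_eff_joint, abs=0.1)
        assert r.nuc_eff_single == pytest.approx(0.4, abs=0.1)

    def test_constant_product_untestable(self, inter_cohort):
        p, g = inter_cohort.phenotypes, inter_cohort.genotypes
        n = len(p.data)
        # carriers of the mito allele never carry the nuclear alt
        m = np.zeros(n)
        m[: n // 2] = 1.0
        gn = np.zeros(n)
        gn[n // 2:][:50] = 1.0
        r = test_interaction(p, ["age", "sex"], m, gn)
        assert "untestable" in r.note

    def test_constant_nuc_untestable(self, inter_cohort):
        p = inter_cohort.phenotypes
        m = inter_cohort.genotypes.dosage_of("mt000")
        r = test_interaction(p, ["age", "sex"], m, np.ones(len(p.data)))
        assert "untestable" in r.note

    def test_grm_identity_matches_plain(self, inter_cohort):
        p, g = inter_cohort.phenotypes, inter_cohort.genotypes
        m, gn = g.dosage_of("mt000"), g.dosage_of("nuc00000")
        r0 = test_interaction(p, ["age", "sex"], m, gn)
        r1 = test_interaction(
            p, ["age", "sex"], m, gn, grm=np.eye(len(p.data))
        )
        assert r1.inter_eff == pytest.approx(r0.inter_eff, abs=1e-8)
        assert r1.inter_pval == pytest.approx(r0.inter_pval, abs=1e-8)


class TestInteractionScan:
    def test_true_interactor_ranked_first(self, inter_cohort):
        g = inter_cohort.genotypes
        nuclear = g.subset_variants(~g.haploid)
        results = interaction_scan(
            inter_cohort.phenotypes, ["age", "sex"], g.dosage_of("mt000"),
            nuclear, nuclear.variant_ids,
        )
        assert results[0].nuc_variant_id == "nuc00000"
        pv = [r.inter_pval for r in results if np.isfinite(r.inter_pval)]
        assert pv == sorted(pv)

    def test_duplicates_deduplicated(self, inter_cohort, caplog):
        import logging

        g = inter_cohort.genotypes
        nuclear = g.subset_variants(~g.haploid)
        with caplog.at_level(logging.WARNING, logger="mitoepi.epistasis"):
            results = interaction_scan(
                inter_cohort.phenotypes, ["age", "sex"], g.dosage_of("mt000"),
                nuclear, ["nuc00001", "nuc00001", "nuc00002"],
            )
        assert len(results) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_candidates_empty_result(self, inter_cohort):
        g = inter_cohort.genotypes
        assert interaction_scan(
            inter_cohort.phenotypes, ["age", "sex"], g.dosage_of("mt000"),
            g.subset_variants(~g.haploid), [],
        ) == []


class TestGeneSetUtilities:
    def _intervals(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [100, 500, 40],
                "end": [200, 700, 90],
                "gene": ["GA", "GB", "GC"],
            }
        )

    def test_variant_inside_interval_annotated(self):
        v = [VariantInfo("x", "1", 150)]
        out = restrict_to_gene_set(v, self._intervals(), ["GA", "GB"])
        assert len(out) == 1 and out[0].gene == "GA"

    def test_half_open_boundary_excluded(self):
        v = [VariantInfo("edge", "1", 200), VariantInfo("start", "1", 100)]
        out = restrict_to_gene_set(v, self._intervals(), ["GA"])
        assert [o.id for o in out] == ["start"]

    def test_hand_enumerated_subset(self):
        variants = [
            VariantInfo(f"v{i}", c, pos)
            for i, (c, pos) in enumerate(
                [("1", 99), ("1", 100), ("1", 199), ("1", 200), ("1", 550),
                 ("1", 650), ("2", 39), ("2", 40), ("2", 89), ("3", 150)]
            )
        ]
        out = restrict_to_gene_set(variants, self._intervals(), ["GA", "GB", "GC"])
        assert [o.id for o in out] == ["v1", "v2", "v4", "v5", "v7", "v8"]

    def test_unknown_gene_names_warned_and_ignored(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mitoepi.epistasis"):
            out = restrict_to_gene_set(
                [VariantInfo("x", "1", 150)], self._intervals(), ["NOPE", "GA"]
            )
        assert len(out) == 1
        assert any("NOPE" in r.message for r in caplog.records)

    def test_fisher_matches_hypergeometric_tail(self):
        # 8 of 10 hit genes in an 18-gene set, universe of 100
        universe = [f"g{i}" for i in range(100)]
        gset = universe[:18]
        hits = universe[:8] + universe[90:92]
        res = gene_set_overrepresentation(hits, gset, universe)
        oracle = stats.hypergeom.sf(7, 100, 18, 10)
        assert res.pval == pytest.approx(oracle, abs=1e-12)
        assert (res.n_hits_in_set, res.n_hits, res.n_set) == (8, 10, 18)

    def test_degenerate_tables(self):
        universe = ["a", "b", "c"]
        full = gene_set_overrepresentation(universe, universe, universe)
        assert full.pval == pytest.approx(1.0)
        none = gene_set_overrepresentation(["a"], ["b"], universe)
        assert none.odds_ratio == 0.0 and none.pval == pytest.approx(1.0)
        with pytest.raises(ValueError, match="empty"):
            gene_set_overrepresentation([], [], [])


class TestExpressionGlm:
    def _pheno(self, rng, n=150):
        age = rng.normal(35, 8, n)
        sex = (rng.random(n) < 0.5).astype(float)
        return age, sex

    def test_sign_recovery_at_count_scales(self):
        # transcript-abundance scales: effects per expression unit are tiny
        eff_nuc, eff_mito, eff_int = 0.25, 2e-4, -1e-5
        hits = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            age, sex = self._pheno(rng)
            en = rng.normal(50, 10, 150)
            em = rng.normal(5e4, 1e4, 150)
            bmi = (
                24 + 0.05 * age + 0.5 * sex
                + eff_nuc * en + eff_mito * em + eff_int * en * em
                + rng.normal(0, 1.0, 150)
            )
            p = PhenotypeTable(pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(150)],
                "bmi": bmi, "age": age, "sex": sex,
            }))
            r = expression_interaction_glm(p, en, em)
            if (
                r.nuc_eff_joint > 0 and r.mito_eff_joint > 0 and r.inter_eff < 0
                and max(r.nuc_pval_joint, r.mito_pval_joint, r.inter_pval) < 0.05
            ):
                hits += 1
        assert hits / reps > 0.9

    def test_collinear_expressions_rejected(self, inter_cohort):
        p = inter_cohort.phenotypes
        rng = np.random.default_rng(2)
        en = rng.normal(50, 10, len(p.data))
        with pytest.raises(ValueError, match="collinear"):
            expression_interaction_glm(p, en, 2.0 * en + 1e-9)

    def test_constant_expression_rejected(self, inter_cohort):
        p = inter_cohort.phenotypes
        en = np.random.default_rng(3).normal(50, 10, len(p.data))
        with pytest.raises(ValueError, match="constant"):
            expression_interaction_glm(p, en, np.full(len(p.data), 7.0))
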