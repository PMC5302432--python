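"""Mixed-model variance components, BLUP shrinkage and harmonic statistics."""

import numpy as np
import pandas as pd
import pytest

from nutmet import (
    AnalysisConfig,
    GenotypicValueTable,
    METDataset,
    PlotRecord,
    SimulationConfig,
    VarianceComponents,
    fit_random_genotype_model,
    generate_met,
    hmgv_rpgv_hmrpgv,
    predict_genotypic_values,
)

CFG = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})


def _dataset(values):
    """values[(g, e, r)] = yield; single mineral held constant."""
    records = [
        PlotRecord(g, "Cultivar", e, r, y, {"Fe": 40.0})
        for (g, e, r), y in values.items()
    ]
    genos = list(dict.fromkeys(g for g, _, _ in values))
    envs = list(dict.fromkeys(e for _, e, _ in values))
    return METDataset(records, ["Fe"], genos, envs)


def _additive(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = {}
    for i, g in enumerate("ABCDE"):
        for j, e in enumerate(("E1", "E2", "E3")):
            for r in (1, 2):
                vals[(g, e, r)] = 3000.0 + 200 * i + 80 * j + (
                    rng.normal(0, noise) if noise else 0.0
                )
    return _dataset(vals)


class TestVarianceComponents:
    def test_noise_free_additive_data(self):
        vc = fit_random_genotype_model(_additive(), "yield", CFG)
        assert vc.sigma2_ge == 0.0
        assert vc.sigma2_eps == 0.0
        assert vc.sigma2_g > 0

    def test_identical_genotypes_have_zero_genotypic_variance(self):
        vals = {(g, e, r): 3000.0 + 80 * j
                for g in "ABC" for j, e in enumerate(("E1", "E2")) for r in (1, 2)}
        vc = fit_random_genotype_model(_dataset(vals), "yield", CFG)
        assert vc.sigma2_g == 0.0

    def test_single_environment_rejected(self):
        vals = {(g, "E1", r): 3000.0 for g in "ABC" for r in (1, 2)}
        with pytest.raises(ValueError, match="single environment"):
            fit_random_genotype_model(_dataset(vals), "yield", CFG)

    def test_em_reml_equals_anova_closed_forms_on_balanced_data(self, rank1_sim):
        data, _ = rank1_sim
        anova = fit_random_genotype_model(data, "yield", CFG, method="anova_closed_form")
        em = fit_random_genotype_model(data, "yield", CFG, method="em_reml")
        for attr in ("sigma2_g", "sigma2_ge", "sigma2_eps"):
            a, b = getattr(anova, attr), getattr(em, attr)
            assert b == pytest.approx(a, rel=1e-6, abs=1e-6 * max(a, 1.0))
        assert em.method == "em_reml" and em.converged

    def test_em_reml_handles_unbalanced_data(self, rank1_sim):
        data, _ = rank1_sim
        # drop one replicate to unbalance the layout
        records = [r for r in data.records
                   if not (r.genotype_id == "G01" and r.environment_id == "E1"
                           and r.replicate == 2)]
        unb = METDataset(records, data.minerals, data.genotypes, data.environments)
        vc = fit_random_genotype_model(unb, "yield", CFG)
        assert vc.method == "em_reml" and vc.converged
        ref = fit_random_genotype_model(data, "yield", CFG)
        assert vc.sigma2_g == pytest.approx(ref.sigma2_g, rel=0.2)

    def test_monte_carlo_recovery_of_sigma2_g(self):
        """Mean σ̂²_g across 200 seeds within 10% of the simulated 160 000."""
        ests = []
        for seed in range(200):
            sim = SimulationConfig(
                n_genotypes=30, n_environments=5, n_replicates=2,
                interaction_lambdas=[400.0], sigma_g=400.0, sigma_eps=200.0,
                hulled_fraction=0.0, seed=seed,
            )
            data, _ = generate_met(sim)
            ests.append(fit_random_genotype_model(data, "yield", CFG).sigma2_g)
        assert np.mean(ests) == pytest.approx(160_000.0, rel=0.10)


class TestGenotypicValues:
    def test_zero_genotypic_variance_gives_environment_means(self, rank1_sim):
        data, _ = rank1_sim
        vc = VarianceComponents(0.0, 0.0, 1000.0, method="anova_closed_form")
        table = predict_genotypic_values(vc, data, "yield", CFG)
        env_means = table.env_means
        for e in table.gv.columns:
            np.testing.assert_allclose(table.gv[e], env_means[e], rtol=1e-9)

    def test_no_shrinkage_limit_recovers_cell_means(self, rank1_sim):
        data, _ = rank1_sim
        from nutmet.nutrition import trait_cell_means

        vc = VarianceComponents(1e12, 1e12, 1e-6, method="anova_closed_form")
        table = predict_genotypic_values(vc, data, "yield", CFG)
        cells = trait_cell_means(data, "yield", CFG).values
        np.testing.assert_allclose(table.gv.to_numpy(), cells.to_numpy(), rtol=1e-4)

    def test_blup_recovers_true_genotype_effects(self):
        sim = SimulationConfig(
            n_genotypes=30, n_environments=5, n_replicates=2,
            interaction_lambdas=[], sigma_g=400.0, sigma_eps=200.0,
            hulled_fraction=0.0, seed=21,
        )
        data, truth = generate_met(sim)
        vc = fit_random_genotype_model(data, "yield", CFG)
        table = predict_genotypic_values(vc, data, "yield", CFG)
        blup_g = table.gv.mean(axis=1) - table.gv.to_numpy().mean()
        r = np.corrcoef(blup_g, truth.genotype_effects.reindex(blup_g.index))[0, 1]
        assert r > 0.9


def _gv_table(gv: pd.DataFrame, env_means: pd.Series) -> GenotypicValueTable:
    vc = VarianceComponents(1.0, 0.0, 1.0, method="anova_closed_form")
    return GenotypicValueTable(trait_name="yield", gv=gv, env_means=env_means,
                               components=vc)


class TestHarmonicStatistics:
    def test_hand_computed_two_environment_case(self):
        gv = pd.DataFrame({"E1": [4.0], "E2": [4.0]}, index=["A"])
        table = hmgv_rpgv_hmrpgv(_gv_table(gv, pd.Series({"E1": 2.0, "E2": 8.0})))
        assert table.stats.loc["A", "HMGV"] == pytest.approx(4.0)
        assert table.stats.loc["A", "RPGV"] == pytest.approx(1.25)
        assert table.stats.loc["A", "HMRPGV"] == pytest.approx(0.8)

    def test_constant_genotype_at_environment_means(self):
        gv = pd.DataFrame({"E1": [2.0], "E2": [8.0]}, index=["A"])
        table = hmgv_rpgv_hmrpgv(_gv_table(gv, pd.Series({"E1": 2.0, "E2": 8.0})))
        assert table.stats.loc["A", "RPGV"] == pytest.approx(1.0)
        assert table.stats.loc["A", "HMRPGV"] == pytest.approx(1.0)

    def test_proportional_genotype_scales_exactly(self):
        mu = pd.Series({"E1": 2.0, "E2": 8.0})
        gv = pd.DataFrame({"E1": [2.0 * 1.3], "E2": [8.0 * 1.3]}, index=["A"])
        table = hmgv_rpgv_hmrpgv(_gv_table(gv, mu))
        assert table.stats.loc["A", "RPGV"] == pytest.approx(1.3)
        assert table.stats.loc["A", "HMRPGV"] == pytest.approx(1.3)

    def test_nonpositive_gv_raises_naming_genotype(self):
        gv = pd.DataFrame({"E1": [4.0, -1.0], "E2": [4.0, 5.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="B"):
            hmgv_rpgv_hmrpgv(_gv_table(gv, pd.Series({"E1": 2.0, "E2": 8.0})))

    def test_am_hm_inequalities_on_fitted_tables(self, worked, config):
        from nutmet.pipeline import analysis_traits, blup_tables

        for trait, table in blup_tables(worked, config).items():
            am = table.gv.mean(axis=1)
            assert (table.stats["HMGV"] <= am + 1e-9).all(), trait
            assert (table.stats["HMRPGV"] <= table.stats["RPGV"] + 1e-9).all(), trait

    def test_scale_equivariance(self, rank1_sim):
        data, _ = rank1_sim
        c = 2.5
        scaled_records = [
            PlotRecord(r.genotype_id, r.genotype_group, r.environment_id,
                       r.replicate, r.yield_raw * c, r.concentrations)
            for r in data.records
        ]
        scaled = METDataset(scaled_records, data.minerals, data.genotypes,
                            data.environments)
        t1 = hmgv_rpgv_hmrpgv(predict_genotypic_values(
            fit_random_genotype_model(data, "yield", CFG), data, "yield", CFG))
        t2 = hmgv_rpgv_hmrpgv(predict_genotypic_values(
            fit_random_genotype_model(scaled, "yield", CFG), scaled, "yield", CFG))
        np.testing.assert_allclose(t2.stats["HMGV"], c * t1.stats["HMGV"], rtol=1e-8)
        np.testing.assert_allclose(t2.stats["RPGV"], t1.stats["RPGV"], rtol=1e-8)
        np.testing.assert_allclose(t2.stats["HMRPGV"], t1.stats["HMRPGV"], rtol=1e-8)

    def test_zero_gxe_ranking_equals_mean_ranking(self):
        sim = SimulationConfig(n_genotypes=12, n_environments=4, n_replicates=2,
                               interaction_lambdas=[], sigma_g=500.0,
                               sigma_eps=100.0, hulled_fraction=0.0, seed=13)
        data, _ = generate_met(sim)
        vc = fit_random_genotype_model(data, "yield", CFG)
        table = hmgv_rpgv_hmrpgv(predict_genotypic_values(vc, data, "yield", CFG))
        mean_rank = data.to_frame().groupby("genotype")["yield_kg_ha"].mean().rank(
            ascending=False
        )
        assert (table.stats["rank"] == mean_rank.reindex(table.stats.index)).all()
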