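"""Nutritional yield, nutrient density, summaries, correlations, ANOVA shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nutmet import (
    AnalysisConfig,
    METDataset,
    PlotRecord,
    SimulationConfig,
    amount_for_dri,
    correlation_matrix,
    dehull_adjust,
    generate_met,
    genotype_summary,
    nutritional_yield,
    plot_nutritional_yields,
    population_summary,
    variance_partition,
)
from nutmet.data import round_half_away


class TestDehull:
    @pytest.mark.parametrize(
        "raw,hulled,expected", [(4000.0, True, 3000.0), (4000.0, False, 4000.0)]
    )
    def test_factor_applied_only_when_hulled(self, raw, hulled, expected):
        assert dehull_adjust(raw, hulled, 0.75) == expected

    def test_published_einkorn_mean_recovered(self):
        # raw hulled 2702.7 kg/ha → dehulled 2027 (printed mean)
        assert round_half_away(dehull_adjust(2702.7, True, 0.75)) == 2027

    def test_factor_out_of_range(self):
        with pytest.raises(ValueError):
            dehull_adjust(100.0, True, 1.5)


class TestNutritionalYield:
    @pytest.mark.parametrize(
        "yld,conc,dri,expected_rounded",
        [
            (6920.0, 38.0, 12.0, 60),  # conventional Swedish cultivar, Fe
            (8190.0, 4.6, 0.9, 115),  # high-yield conventional, Cu
            (0.0, 50.0, 12.0, 0),
        ],
    )
    def test_published_values(self, yld, conc, dri, expected_rounded):
        assert round_half_away(nutritional_yield(yld, conc, dri, 365.0)) == expected_rounded

    def test_exact_value(self):
        assert nutritional_yield(6920.0, 38.0, 12.0, 365.0) == pytest.approx(60.0365, abs=1e-4)

    @given(
        yld=st.floats(0, 2e4), conc=st.floats(0, 2e3),
        dri=st.floats(0.1, 500), scale=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_linearity_and_dri_inverse(self, yld, conc, dri, scale):
        base = nutritional_yield(yld, conc, dri)
        assert nutritional_yield(yld * scale, conc, dri) == pytest.approx(base * scale, rel=1e-9)
        assert nutritional_yield(yld, conc, dri / 2) == pytest.approx(base * 2, rel=1e-9)

    def test_dri_must_be_positive(self):
        with pytest.raises(ValueError):
            nutritional_yield(100.0, 40.0, 0.0)


class TestAmountForDri:
    @pytest.mark.parametrize(
        "conc,dri,expected_rounded",
        [(49.0, 12.0, 245), (1399.0, 315.0, 225), (1000.0, 1.0, 1)],
    )
    def test_published_values(self, conc, dri, expected_rounded):
        assert round_half_away(amount_for_dri(conc, dri)) == expected_rounded

    @given(conc=st.floats(1.0, 2000.0), dri=st.floats(0.1, 500.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_roundtrip_identity(self, conc, dri):
        assert amount_for_dri(conc, dri) * conc / 1000.0 == pytest.approx(dri, rel=1e-12)

    def test_zero_concentration_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            amount_for_dri(0.0, 12.0)


class TestSummaries:
    def test_population_means_of_worked_example(self, worked, config):
        summary = genotype_summary(plot_nutritional_yields(worked, config))
        pop = population_summary(summary)
        assert round_half_away(pop["ny_Fe"]) == 39
        assert round_half_away(pop["ny_Cu"]) == 63

    def test_identical_genotypes_have_zero_sd(self, config):
        records = [
            PlotRecord("A", "Cultivar", e, r, 4000.0, {"Fe": 40.0})
            for e in ("E1", "E2") for r in (1, 2)
        ]
        data = METDataset(records, ["Fe"], ["A"], ["E1", "E2"])
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        summary = genotype_summary(plot_nutritional_yields(data, cfg))
        assert summary.loc["A", "ny_Fe_sd"] == 0.0

    def test_per_plot_averaging_differs_from_formula_on_means(self, config):
        """Mean of per-plot NY ≠ NY(mean yield, mean conc) when coupled."""
        records = [
            PlotRecord("A", "Cultivar", "E1", 1, 3000.0, {"Fe": 50.0}),
            PlotRecord("A", "Cultivar", "E1", 2, 5000.0, {"Fe": 30.0}),
        ]
        data = METDataset(records, ["Fe"], ["A"], ["E1"])
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        summary = genotype_summary(plot_nutritional_yields(data, cfg))
        per_plot = summary.loc["A", "ny_Fe"]
        formula = nutritional_yield(4000.0, 40.0, 12.0)
        assert per_plot == pytest.approx(nutritional_yield(3000, 50, 12) / 2
                                         + nutritional_yield(5000, 30, 12) / 2)
        assert per_plot != pytest.approx(formula)


class TestCorrelations:
    def test_unit_diagonal_and_symmetry(self, worked, config):
        r, p = correlation_matrix(worked, config)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_constant_concentration_makes_ny_proportional_to_yield(self, config):
        cfg_sim = SimulationConfig(n_genotypes=8, n_environments=3, seed=4,
                                   hulled_fraction=0.0)
        from nutmet.simulate import MineralSpec

        cfg_sim.minerals = {"Fe": MineralSpec(43.0, 0.0, 0.0)}
        data, _ = generate_met(cfg_sim)
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        r, _ = correlation_matrix(data, cfg)
        assert r.loc["yield", "ny_Fe"] == pytest.approx(1.0, abs=1e-12)

    def test_antiordered_pair_is_minus_one(self, worked, config):
        from nutmet.nutrition import trait_cell_means

        x = trait_cell_means(worked, "yield", config).values.stack()
        r = np.corrcoef(x, -x)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_zero_variance_trait_flagged_as_missing(self, config):
        records = [
            PlotRecord(g, "Cultivar", e, r, 4000.0 + i * 10 + j, {"Fe": 40.0})
            for i, g in enumerate("ABC") for j, e in enumerate(("E1", "E2"))
            for r in (1, 2)
        ]
        data = METDataset(records, ["Fe"], list("ABC"), ["E1", "E2"])
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = correlation_matrix(data, cfg, traits=["yield", "Fe"])
        assert np.isnan(r.loc["yield", "Fe"])


class TestVariancePartition:
    def _additive(self):
        records = []
        for i, g in enumerate("ABCD"):
            for j, e in enumerate(("E1", "E2", "E3")):
                for r in (1, 2):
                    records.append(
                        PlotRecord(g, "Cultivar", e, r, 3000.0 + 100 * i + 40 * j,
                                   {"Fe": 40.0})
                    )
        return METDataset(records, ["Fe"], list("ABCD"), ["E1", "E2", "E3"])

    def test_additive_noise_free_data(self, config):
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        props = variance_partition(self._additive(), "yield", cfg)
        assert props["genotype"] + props["environment"] == pytest.approx(1.0)
        assert props["gxe"] == pytest.approx(0.0, abs=1e-12)
        assert props["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_flagged(self):
        records = [
            PlotRecord(g, "Cultivar", e, r, 4000.0, {"Fe": 40.0})
            for g in "AB" for e in ("E1", "E2") for r in (1, 2)
        ]
        data = METDataset(records, ["Fe"], ["A", "B"], ["E1", "E2"])
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        with pytest.warns(UserWarning, match="constant"):
            props = variance_partition(data, "yield", cfg)
        assert props.isna().all()

    def test_genotype_dominates_when_sigma_g_large(self):
        sim = SimulationConfig(n_genotypes=15, n_environments=3, sigma_g=800.0,
                               sigma_env=50.0, sigma_eps=100.0,
                               interaction_lambdas=[], hulled_fraction=0.0, seed=9)
        data, _ = generate_met(sim)
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        props = variance_partition(data, "yield", cfg)
        assert props["genotype"] > props["environment"]
        assert props.sum() == pytest.approx(1.0)
        assert ((props >= 0) & (props <= 1)).all()

    def test_single_replicate_confounds_interaction_and_residual(self):
        records = [
            PlotRecord(g, "Cultivar", e, 1, 3000.0 + i * 100 + j * 37 + i * j * 11,
                       {"Fe": 40.0})
            for i, g in enumerate("ABC") for j, e in enumerate(("E1", "E2"))
        ]
        data = METDataset(records, ["Fe"], list("ABC"), ["E1", "E2"])
        cfg = AnalysisConfig(dri={"Fe": 12.0}, lal={}, desired_gains={})
        with pytest.warns(UserWarning, match="confounded"):
            props = variance_partition(data, "yield", cfg)
        assert "gxe_plus_residual" in props.index
        assert props.sum() == pytest.approx(1.0)
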