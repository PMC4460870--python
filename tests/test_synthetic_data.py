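"""Generator contracts: toy models, proteomes, and planted correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aaflux.supply_fba import max_growth, supply_table
from aaflux.synthetic_data import (
    PlantedParams,
    ToyModelSpec,
    build_toy_model,
    gen_expression,
    gen_proteome,
    gen_starvation,
    toy1_spec,
    toy_aa_map,
)


class TestToyModels:
    def test_toy1_growth_rate_closed_form(self):
        model = build_toy_model(toy1_spec())
        assert max_growth(model) == pytest.approx(20.0 / 3.0, abs=1e-6)

    def test_model_validates(self):
        build_toy_model(toy1_spec()).validate()

    def test_doubled_yields_double_supplies(self):
        base = toy1_spec()
        doubled = ToyModelSpec(
            yields={a: 2 * y for a, y in base.yields.items()},
            biomass_composition=base.biomass_composition,
            substrate_uptake=base.substrate_uptake,
        )
        prots = gen_proteome(10, 0.3, seed=2)
        s1 = [r.supply for r in supply_table(build_toy_model(base), toy_aa_map(base), prots)]
        s2 = [r.supply for r in supply_table(build_toy_model(doubled), toy_aa_map(doubled), prots)]
        np.testing.assert_allclose(s2, 2.0 * np.array(s1), rtol=1e-6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="2 amino acids"):
            ToyModelSpec(yields={"A": 1.0}, biomass_composition={"A": 1.0})
        with pytest.raises(ValueError, match="positive"):
            ToyModelSpec(yields={"A": -1.0, "B": 1.0}, biomass_composition={})
        with pytest.raises(ValueError, match="synthesis"):
            ToyModelSpec(yields={"A": 1.0, "B": 1.0}, biomass_composition={"C": 1.0})


class TestProteome:
    def test_deterministic_in_seed(self):
        a = gen_proteome(5, 0.2, seed=3)
        b = gen_proteome(5, 0.2, seed=3)
        assert [(p.id, p.sequence) for p in a] == [(q.id, q.sequence) for q in b]
        c = gen_proteome(5, 0.2, seed=4)
        assert [p.sequence for p in a] != [q.sequence for q in c]

    def test_full_bias_gives_pure_cheapest_residue(self):
        spec = toy1_spec()
        prots = gen_proteome(5, 1.0, seed=1, spec=spec)
        assert all(set(p.sequence) == {spec.cheapest} for p in prots)

    def test_zero_bias_mean_composition_uniform(self):
        """Dirichlet(1) compositions have mean 1/2 per residue; check within 3 SE."""
        n = 500
        prots = gen_proteome(n, 0.0, seed=6)
        mean_a = np.mean([p.aa_freq.get("A", 0.0) for p in prots])
        se = np.sqrt(1.0 / 12.0 / n)  # per-protein sd of a Dirichlet(1,1) share is 1/sqrt(12)
        assert abs(mean_a - 0.5) < 3 * se

    def test_frequencies_match_sequence(self):
        for p in gen_proteome(3, 0.4, seed=8):
            assert sum(p.aa_freq.values()) == pytest.approx(1.0, abs=1e-12)
            for a, f in p.aa_freq.items():
                assert f == pytest.approx(p.sequence.count(a) / len(p.sequence))


class TestExpression:
    def supplies(self, rng, n):
        return rng.lognormal(size=n)

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(0)
        s = self.supplies(rng, 50)
        p = PlantedParams(0.3, 0.1, 0.2, n_genes=50, seed=12)
        pd.testing.assert_frame_equal(gen_expression(s, p), gen_expression(s, p))

    def test_planted_spearman_recovered(self):
        rng = np.random.default_rng(1)
        s = self.supplies(rng, 2000)
        p = PlantedParams(0.3, 0.1, 0.2, n_genes=2000, seed=5)
        table = gen_expression(s, p)
        rho = stats.spearmanr(table["supply"], table["te_true"]).statistic
        assert rho == pytest.approx(0.3, abs=0.05)
        rho_rd = stats.spearmanr(table["supply"], table["rd_true"]).statistic
        assert rho_rd == pytest.approx(0.3, abs=0.05)
        rho_m = stats.spearmanr(table["supply"], table["mrna_level"]).statistic
        assert rho_m == pytest.approx(0.2, abs=0.05)

    def test_zero_target_gives_independence(self):
        rng = np.random.default_rng(2)
        s = self.supplies(rng, 2000)
        p = PlantedParams(0.0, 0.1, 0.2, n_genes=2000, seed=5,
                          target_spearman_supply_rd=0.0, target_spearman_supply_mrna=0.0)
        table = gen_expression(s, p)
        assert abs(stats.spearmanr(table["supply"], table["te_true"]).statistic) < 0.05

    def test_zero_cv_gives_identical_replicates_passing_filters(self):
        rng = np.random.default_rng(3)
        s = self.supplies(rng, 100)
        p = PlantedParams(0.3, 0.0, 0.2, n_genes=100, seed=7)
        table = gen_expression(s, p)
        np.testing.assert_array_equal(
            table["footprint_rpkm_rep1"], table["footprint_rpkm_rep2"]
        )
        # equal replicates have fold ratio 1 < 1.5, so the series rule reduces to the mean
        from aaflux.expression_metrics import filter_rpkm
        from aaflux.synthetic_data import expression_records

        kept = filter_rpkm(expression_records(table))
        means_ok = (table["footprint_rpkm_rep1"] > 1) & (table["mrna_rpkm_rep1"] > 1)
        assert len(kept) == int(means_ok.sum())

    def test_length_mismatch_rejected(self):
        p = PlantedParams(0.3, 0.1, 0.2, n_genes=10, seed=1)
        with pytest.raises(ValueError, match="n_genes"):
            gen_expression(np.ones(5), p)

    def test_extreme_target_rejected(self):
        with pytest.raises(ValueError, match="0.99"):
            PlantedParams(0.99, 0.1, 0.2, n_genes=10, seed=1)


class TestStarvation:
    def table(self, n, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "supply": rng.lognormal(size=n),
                "rd_normal": np.ones(n),
            }
        )

    def test_deterministic_in_params_seed(self):
        t = self.table(50, 0)
        p = PlantedParams(0.3, 0.1, 0.2, n_genes=50, seed=21)
        pd.testing.assert_frame_equal(gen_starvation(t, p), gen_starvation(t, p))

    def test_buffering_orders_group_medians(self):
        t = self.table(2000, 1)
        p = PlantedParams(0.3, 0.1, 0.2, n_genes=2000, seed=22)
        out = gen_starvation(t, p)
        low = out[out["supply"] <= np.median(out["supply"])]["fold_change"].median()
        high = out[out["supply"] > np.median(out["supply"])]["fold_change"].median()
        # delta = 0.2: medians near 1.15 (poorly supplied) vs 1.05 (well supplied)
        assert low > high
        assert low == pytest.approx(1.15, abs=0.05)
        assert high == pytest.approx(1.05, abs=0.05)

    def test_zero_delta_removes_supply_dependence(self):
        t = self.table(2000, 2)
        p = PlantedParams(0.3, 0.1, 0.0, n_genes=2000, seed=23)
        out = gen_starvation(t, p)
        rho = stats.spearmanr(out["supply"], out["fold_change"]).statistic
        assert abs(rho) < 0.06

    def test_fold_change_consistent_with_densities(self):
        t = self.table(20, 3)
        t["rd_normal"] = np.linspace(0.5, 2.0, 20)
        out = gen_starvation(t, PlantedParams(0.3, 0.1, 0.2, n_genes=20, seed=24))
        np.testing.assert_allclose(out["rd_starved"] / out["rd_normal"], out["fold_change"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="rd_normal"):
            gen_starvation(
                pd.DataFrame({"gene_id": ["a", "b", "c"], "supply": [1.0, 2.0, 3.0]}),
                PlantedParams(0.3, 0.1, 0.2, n_genes=3, seed=1),
            )
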