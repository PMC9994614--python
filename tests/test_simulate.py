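import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

import overyield as oy
from overyield import simulate as sim
from overyield.errors import DesignError


class TestGenerateDesign:
    def test_default_design_matches_dominance_layout(self):
        species, design = sim.generate_design(sim.default_config(seed=0))
        plots = design.groupby("plot_id")
        sizes = plots["species_id"].size()
        assert len(sizes) == 85
        assert sizes.value_counts().to_dict() == {1: 7, 2: 46, 6: 24, 9: 8}
        # every unordered pair of the seven active species occurs twice
        active = set(species.loc[species["active"], "species_id"])
        pair_plots = [
            frozenset(g["species_id"]) for _, g in plots if len(g) == 2
        ]
        for pair in itertools.combinations(sorted(active), 2):
            assert pair_plots.count(frozenset(pair)) == 2
        # proportions are equal within plot and sum to one
        sums = design.groupby("plot_id")["sown_proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_replicates_of_an_identity_sit_in_different_blocks(self):
        _, design = sim.generate_design(sim.default_config(seed=5))
        per_plot = design.groupby("plot_id").agg(
            mixture_id=("mixture_id", "first"), block=("block", "first")
        )
        counts = per_plot.groupby("mixture_id").agg(
            reps=("block", "size"), blocks=("block", "nunique")
        )
        two_reps = counts[counts["reps"] == 2]
        assert (two_reps["blocks"] == 2).all()

    def test_same_seed_reproduces_design(self):
        a = sim.generate_design(sim.default_config(seed=9))[1]
        b = sim.generate_design(sim.default_config(seed=9))[1]
        pd.testing.assert_frame_equal(a, b)

    def test_richness_level_beyond_pool_errors(self):
        config = sim.default_config(seed=0)
        config.species = [sp for sp in config.species if sp.active]  # 7 species
        with pytest.raises(DesignError):
            sim.generate_design(config)


class TestGenerateBiomass:
    def _noise_free(self, **overrides):
        config = sim.default_config(seed=0)
        config.biomass_noise_cv = 0.0
        config.biomass_block_sd = 0.0
        for sp in config.species:
            sp.mono_cv = 0.0
        for key, value in overrides.items():
            setattr(config, key, value)
        dataset, truth = oy.simulate_experiment(config, include_traits=False)
        active = oy.drop_inactive(dataset)
        totals, _ = oy.partition_dataset(active, truth.reference())
        return totals, truth

    def test_null_model_gives_exactly_zero_effects(self):
        totals, _ = self._noise_free(ce_slope=0.0, se_dominance=0.0)
        np.testing.assert_allclose(totals[["NE", "CE", "SE"]], 0.0, atol=1e-9)

    def test_uniform_gain_is_pure_complementarity(self):
        totals, _ = self._noise_free(ce_slope=0.25, se_dominance=0.0)
        mixtures = totals[totals["S"] >= 2]
        np.testing.assert_allclose(mixtures["SE"], 0.0, atol=1e-9)
        assert (mixtures["CE"] > 0).all()
        by_s = mixtures.groupby("S")["CE"].mean()
        assert by_s.is_monotonic_increasing

    def test_dominance_boost_splits_into_both_components(self):
        totals, truth = self._noise_free(ce_slope=0.0, se_dominance=0.5)
        dominant = truth.dominant_species
        _, design = sim.generate_design(sim.default_config(seed=0))
        with_dom = design.groupby("plot_id")["species_id"].agg(lambda s: dominant in set(s))
        mixtures = totals[totals["S"] >= 2]
        hit = mixtures[with_dom.loc[mixtures.index]]
        miss = mixtures[~with_dom.loc[mixtures.index]]
        assert (hit["SE"] > 0).all()
        assert (hit["CE"] > 0).all()
        np.testing.assert_allclose(miss[["NE", "CE", "SE"]], 0.0, atol=1e-9)

    def test_ground_truth_equals_noise_free_partition(self):
        totals, truth = self._noise_free()
        pd.testing.assert_frame_equal(totals, truth.effects)

    def test_bit_identical_tables_for_identical_seed(self, tmp_path):
        for sub in ("a", "b"):
            dataset, truth = oy.simulate_experiment(seed=42)
            sim.write_simulation(dataset, truth, tmp_path / sub)
        for name in ("species.csv", "design.csv", "biomass.csv", "traits.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_extinction_thinning_reduces_realized_richness(self):
        config = sim.default_config(seed=8)
        config.extinction_prob = 0.3
        dataset, _ = oy.simulate_experiment(config)
        plots = dataset.plot_frame()
        mixtures = plots[plots["sown_richness"] >= 6]
        assert (mixtures["realized_richness"] < 7).any()


class TestCEslopeRecovery:
    def test_median_recovered_slope_within_twenty_percent(self):
        """Relative complementarity per log2 richness, re-estimated from
        100 noisy replicate experiments with the estimated monoculture
        reference, recovers the configured slope."""
        config = sim.default_config(seed=5)
        species, design = sim.generate_design(config)
        active = {sp.species_id for sp in config.active_species()}
        active_design = design.loc[design["species_id"].isin(active)].copy()
        active_design["sown_proportion"] /= active_design.groupby("plot_id")[
            "sown_proportion"
        ].transform("sum")
        active_species = species.loc[species["active"]]
        slopes = []
        for i in range(100):
            biomass, _ = sim.generate_biomass(design, config, np.random.default_rng(60000 + i))
            ds = oy.Dataset(
                species=active_species, design=active_design, biomass=biomass,
                traits=pd.DataFrame(columns=["plot_id", "species_id", "variable", "value", "unit"]),
            )
            ref = oy.build_monoculture_reference(ds)
            totals, _ = oy.partition_table(active_design, biomass, ref)
            mixtures = totals[totals["S"] >= 2]
            expected_yield = (
                active_design.assign(M=active_design["species_id"].map(ref.M))
                .assign(w=lambda t: t["sown_proportion"] * t["M"])
                .groupby("plot_id")["w"].sum()
            )
            relative_ce = mixtures["CE"] / expected_yield.loc[mixtures.index]
            x = np.log2(mixtures["S"].to_numpy(float))
            slopes.append(np.polyfit(x, relative_ce.to_numpy(float), 1)[0])
        median = float(np.median(slopes))
        assert abs(median - config.ce_slope) <= 0.2 * config.ce_slope


class TestTraitsAndSoil:
    def test_zero_plasticity_and_noise_reproduce_species_means(self):
        config = sim.default_config(seed=2)
        for sp in config.species:
            sp.trait_plasticity = {t: 0.0 for t in sim.SPECIES_TRAITS}
        config.trait_noise_sd = {t: 0.0 for t in sim.SPECIES_TRAITS}
        config.trait_block_sd = {t: 0.0 for t in sim.SPECIES_TRAITS}
        dataset, _ = oy.simulate_experiment(config)
        values = dataset.species_trait_values("plant_height")
        means = {sp.species_id: sp.trait_means["plant_height"] for sp in config.species}
        for plot_values in values.values():
            for species_id, value in plot_values.items():
                assert value == pytest.approx(means[species_id])

    def test_negative_ph_slope_recovered_in_most_replicates(self):
        """The configured soil-pH decline along the richness gradient is
        re-estimated with the correct sign in >=95% of 200 replicates."""
        config = sim.default_config(seed=6)
        dataset0, _ = oy.simulate_experiment(config, include_traits=False)
        design = dataset0.design
        plots = dataset0.plot_frame()
        x = np.log2(plots["sown_richness"].to_numpy(float))
        negative = 0
        for i in range(200):
            traits = sim.generate_traits_and_soil(
                design, dataset0.biomass, config, np.random.default_rng(70000 + i)
            )
            ph_rows = traits.loc[traits["species_id"].isna() & (traits["variable"] == "ph")]
            y = pd.Series(
                ph_rows["value"].to_numpy(float), index=list(ph_rows["plot_id"])
            ).loc[plots.index].to_numpy()
            negative += np.polyfit(x, y, 1)[0] < 0
        assert negative >= 0.95 * 200

    def test_amf_values_stay_in_percent_range(self, default_simulation):
        dataset, _ = default_simulation
        rows = dataset.traits[dataset.traits["variable"] == "amf_colonization"]
        assert rows["value"].between(0, 100).all()


class TestConfigSerialization:
    def test_yaml_round_trip(self, tmp_path):
        config = sim.default_config(seed=17)
        path = tmp_path / "sim.yaml"
        sim.config_to_yaml(config, path)
        again = sim.config_from_yaml(path)
        assert again == config

    def test_round_tripped_config_simulates_identically(self, tmp_path):
        config = sim.default_config(seed=17)
        path = tmp_path / "sim.yaml"
        sim.config_to_yaml(config, path)
        again = sim.config_from_yaml(path)
        a, _ = oy.simulate_experiment(config)
        b, _ = oy.simulate_experiment(again)
        pd.testing.assert_frame_equal(a.biomass, b.biomass)
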