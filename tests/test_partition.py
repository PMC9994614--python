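import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import overyield as oy
from overyield.errors import ConfigurationError, DesignError, ValidationError

from conftest import loreau_hector_oracle, make_dataset


def _plot(species, proportions, biomass, plot_id="x1"):
    design = oy.PlotDesign(
        plot_id=plot_id, block="B1", mixture_id="mix",
        sown_species=tuple(species),
        sown_proportion=dict(zip(species, proportions)),
    )
    obs = oy.MixtureObservation(plot_id=plot_id, biomass=dict(zip(species, biomass)))
    return obs, design


class TestMonocultureReference:
    def test_averages_replicate_monocultures(self):
        ds = make_dataset(
            [("A", "grass", True)],
            [("m1", "B1", "mono_A", "A", 1.0), ("m2", "B2", "mono_A", "A", 1.0)],
            [("m1", "A", 180.0), ("m2", "A", 220.0)],
        )
        ref = oy.build_monoculture_reference(ds)
        assert ref.M["A"] == pytest.approx(200.0)
        assert ref.n_replicates["A"] == 2

    def test_single_monoculture(self):
        ds = make_dataset(
            [("A", "grass", True)],
            [("m1", "B1", "mono_A", "A", 1.0)],
            [("m1", "A", 150.0)],
        )
        assert oy.build_monoculture_reference(ds).M["A"] == pytest.approx(150.0)

    def test_missing_monoculture_advises_deactivation(self):
        ds = make_dataset(
            [("A", "grass", True), ("B", "forb", True)],
            [
                ("m1", "B1", "mono_A", "A", 1.0),
                ("x1", "B1", "pair", "A", 0.5),
                ("x1", "B1", "pair", "B", 0.5),
            ],
            [("m1", "A", 150.0), ("x1", "A", 70.0), ("x1", "B", 30.0)],
        )
        with pytest.raises(ConfigurationError, match="deactivate"):
            oy.build_monoculture_reference(ds)


class TestPartitionPlot:
    REF = oy.MonocultureReference(M={"A": 200.0, "B": 100.0}, n_replicates={"A": 1, "B": 1})

    def test_selection_only_mixture(self):
        # equal sowing, strong species see opposite relative-yield deviations
        obs, design = _plot(["A", "B"], [0.5, 0.5], [150.0, 25.0])
        result = oy.partition_plot(obs, design, self.REF)
        assert result.ne == pytest.approx(25.0)
        assert result.ce == pytest.approx(0.0, abs=1e-12)
        assert result.se == pytest.approx(25.0)
        assert (result.ne, result.ce, result.se) == pytest.approx(
            loreau_hector_oracle([200, 100], [0.5, 0.5], [150, 25])
        )

    def test_complementarity_only_mixture(self):
        # both species share the same proportional gain: selection vanishes
        obs, design = _plot(["A", "B"], [0.5, 0.5], [120.0, 60.0])
        result = oy.partition_plot(obs, design, self.REF)
        assert result.ne == pytest.approx(30.0)
        assert result.ce == pytest.approx(30.0)
        assert result.se == pytest.approx(0.0, abs=1e-12)
        assert (result.ne, result.ce, result.se) == pytest.approx(
            loreau_hector_oracle([200, 100], [0.5, 0.5], [120, 60])
        )

    def test_monoculture_reports_zero_effects(self):
        obs, design = _plot(["A"], [1.0], [240.0])
        result = oy.partition_plot(obs, design, self.REF)
        assert (result.ne, result.ce, result.se) == (0.0, 0.0, 0.0)
        assert result.d_ry[0] == pytest.approx(0.2)

    def test_all_extinct_mixture_gives_negative_net_effect(self):
        obs, design = _plot(["A", "B"], [0.5, 0.5], [0.0, 0.0])
        result = oy.partition_plot(obs, design, self.REF)
        assert result.ne == pytest.approx(-150.0)  # -(0.5*200 + 0.5*100)
        assert np.allclose(result.d_ry, [-0.5, -0.5])

    def test_missing_reference_species_errors(self):
        obs, design = _plot(["A", "C"], [0.5, 0.5], [10.0, 10.0])
        with pytest.raises(ConfigurationError):
            oy.partition_plot(obs, design, self.REF)

    def test_empty_plot_errors(self):
        obs, design = _plot([], [], [])
        with pytest.raises(ValidationError):
            oy.partition_plot(obs, design, self.REF)


@st.composite
def random_plot(draw):
    S = draw(st.integers(min_value=2, max_value=8))
    M = draw(
        st.lists(st.floats(10.0, 500.0), min_size=S, max_size=S)
    )
    raw_p = draw(st.lists(st.floats(0.05, 1.0), min_size=S, max_size=S))
    p = np.array(raw_p) / np.sum(raw_p)
    Y = draw(st.lists(st.floats(0.0, 400.0), min_size=S, max_size=S))
    return np.array(M), p, np.array(Y)


class TestPartitionProperties:
    @given(random_plot())
    def test_identity_and_oracle_equivalence(self, mpy):
        M, p, Y = mpy
        species = [f"s{i}" for i in range(len(M))]
        ref = oy.MonocultureReference(M=dict(zip(species, M)), n_replicates={})
        obs, design = _plot(species, p, Y)
        result = oy.partition_plot(obs, design, ref)
        scale = max(1.0, abs(result.ne))
        assert abs(result.ne - result.ce - result.se) < 1e-9 * scale
        ne_direct = float((M * result.d_ry).sum())
        assert result.ne == pytest.approx(ne_direct, rel=1e-9, abs=1e-9)
        oracle = loreau_hector_oracle(M, p, Y)
        assert (result.ne, result.ce, result.se) == pytest.approx(oracle, rel=1e-9, abs=1e-8)

    @given(random_plot(), st.floats(0.01, 50.0))
    def test_scale_equivariance(self, mpy, c):
        M, p, Y = mpy
        species = [f"s{i}" for i in range(len(M))]
        ref1 = oy.MonocultureReference(M=dict(zip(species, M)), n_replicates={})
        refc = oy.MonocultureReference(M=dict(zip(species, c * M)), n_replicates={})
        obs1, design = _plot(species, p, Y)
        obsc, _ = _plot(species, p, c * Y)
        r1 = oy.partition_plot(obs1, design, ref1)
        rc = oy.partition_plot(obsc, design, refc)
        assert rc.ne == pytest.approx(c * r1.ne, rel=1e-9, abs=1e-8)
        assert rc.ce == pytest.approx(c * r1.ce, rel=1e-9, abs=1e-8)
        assert rc.se == pytest.approx(c * r1.se, rel=1e-9, abs=1e-8)

    def test_zero_mean_deviation_kills_complementarity(self):
        # constructed so that mean(dRY) = 0 exactly
        ref = oy.MonocultureReference(M={"A": 300.0, "B": 50.0}, n_replicates={})
        obs, design = _plot(["A", "B"], [0.5, 0.5], [300.0 * 0.7, 50.0 * 0.3])
        result = oy.partition_plot(obs, design, ref)
        assert result.ce == pytest.approx(0.0, abs=1e-12)

    def test_equal_monoculture_yields_kill_selection(self):
        ref = oy.MonocultureReference(M={"A": 120.0, "B": 120.0}, n_replicates={})
        obs, design = _plot(["A", "B"], [0.5, 0.5], [90.0, 20.0])
        result = oy.partition_plot(obs, design, ref)
        assert result.se == pytest.approx(0.0, abs=1e-12)


class TestSignedSqrt:
    @pytest.mark.parametrize(("y", "expected"), [(0.0, 0.0), (-4.0, -2.0), (25.0, 5.0)])
    def test_examples(self, y, expected):
        assert oy.signed_sqrt(y) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_odd_and_order_preserving(self, a, b):
        assert oy.signed_sqrt(-a) == pytest.approx(-oy.signed_sqrt(a))
        if a < b:
            assert oy.signed_sqrt(a) <= oy.signed_sqrt(b)


class TestGrandMeanTest:
    def _frames(self, seed=1):
        dataset, _ = oy.simulate_experiment(seed=seed)
        plots = dataset.plot_frame()
        active = oy.drop_inactive(dataset)
        totals, _ = oy.partition_dataset(active)
        return totals, plots

    def test_all_zero_effects_give_f_zero_p_one(self):
        dataset, _ = oy.simulate_experiment(seed=2)
        plots = dataset.plot_frame()
        totals = pd.DataFrame(
            {"S": plots["sown_richness"].clip(upper=7), "NE": 0.0, "CE": 0.0, "SE": 0.0},
            index=plots.index,
        )
        report = oy.test_effects_positive(totals, plots)
        assert (report["F"] == 0).all()
        assert (report["p"] == 1).all()

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        dataset, _ = oy.simulate_experiment(seed=2)
        plots = dataset.plot_frame()
        totals = pd.DataFrame(
            {
                "S": plots["sown_richness"].clip(upper=7),
                "NE": 50.0 + rng.normal(0, 1, len(plots)),
            },
            index=plots.index,
        )
        report = oy.test_effects_positive(totals, plots, effects=("NE",))
        assert report.loc["NE", "p"] < 1e-3

    def test_monocultures_excluded_from_test(self):
        totals, plots = self._frames()
        report = oy.test_effects_positive(totals, plots)
        n_mixtures = int((totals["S"] >= 2).sum())
        rank_upper = report.loc["NE", "df2"] + 1  # df2 = n - rank
        assert rank_upper < n_mixtures

    def test_saturated_model_errors(self):
        plots = pd.DataFrame(
            {
                "block": ["B1", "B1", "B2", "B2"],
                "mixture_id": ["m1", "m2", "m3", "m4"],
                "sown_richness": [2, 2, 6, 6],
            },
            index=["p1", "p2", "p3", "p4"],
        )
        totals = pd.DataFrame(
            {"S": [2, 2, 6, 6], "NE": [1.0, 2.0, 3.0, 4.0]}, index=plots.index
        )
        with pytest.raises(DesignError):
            oy.test_effects_positive(totals, plots, effects=("NE",))
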