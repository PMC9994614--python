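import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import overyield as oy
from overyield import simulate as sim

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(species_rows, design_rows, biomass_rows, trait_rows=()):
    """Assemble a Dataset from plain row tuples (no file round-trip)."""
    species = pd.DataFrame(species_rows, columns=["species_id", "functional_group", "active"])
    design = pd.DataFrame(
        design_rows, columns=["plot_id", "block", "mixture_id", "species_id", "sown_proportion"]
    )
    biomass = pd.DataFrame(biomass_rows, columns=["plot_id", "species_id", "biomass_g_m2"])
    traits = pd.DataFrame(
        list(trait_rows), columns=["plot_id", "species_id", "variable", "value", "unit"]
    )
    return oy.Dataset(species=species, design=design, biomass=biomass, traits=traits)


@pytest.fixture
def toy_dataset():
    """Smallest meaningful design: two monocultures and one 2-species plot."""
    return make_dataset(
        [("A", "grass", True), ("B", "forb", True)],
        [
            ("m1", "B1", "mono_A", "A", 1.0),
            ("m2", "B1", "mono_B", "B", 1.0),
            ("x1", "B2", "pair_AB", "A", 0.5),
            ("x1", "B2", "pair_AB", "B", 0.5),
        ],
        [("m1", "A", 200.0), ("m2", "B", 100.0), ("x1", "A", 150.0), ("x1", "B", 25.0)],
        [
            ("m1", "A", "plant_height", 40.0, "cm"),
            ("m2", "B", "plant_height", 20.0, "cm"),
            ("x1", "A", "plant_height", 50.0, "cm"),
            ("x1", "B", "plant_height", 10.0, "cm"),
            ("x1", None, "ph", 7.1, "unitless"),
        ],
    )


@pytest.fixture(scope="session")
def default_simulation():
    """One default 85-plot virtual experiment shared across tests."""
    dataset, truth = oy.simulate_experiment(seed=1)
    return dataset, truth


@pytest.fixture(scope="session")
def small_config():
    """A compact 18-plot design (4 species; richness 1, 2, 4) for
    oracle comparisons that enumerate projections explicitly."""
    species = []
    for sid, group, mono, dom, height in [
        ("Sa", "grass", 300.0, 1.0, 40.0),
        ("Sb", "grass", 120.0, 0.0, 25.0),
        ("Sc", "forb", 150.0, 0.0, 30.0),
        ("Sd", "legume", 80.0, 0.0, 15.0),
    ]:
        species.append(
            sim.SpeciesSpec(
                species_id=sid, functional_group=group, mono_yield=mono,
                dominance=dom,
                trait_means={"plant_height": height},
                trait_plasticity={"plant_height": 2.0},
            )
        )
    return sim.GeneratorConfig(
        seed=0,
        richness_levels=(1, 2, 4),
        species=species,
        full_mixture_replicates=2,
        trait_noise_sd={"plant_height": 2.0},
        trait_block_sd={"plant_height": 1.0},
        plot_variables={"ph": sim.PlotVariableSpec(7.0, -0.05, -0.05, 0.05, 0.03)},
    )


def loreau_hector_oracle(M, p, Y):
    """Independent brute-force partition: NE from total yields, CE and SE
    from the community-level mean/covariance form."""
    M, p, Y = (np.asarray(v, dtype=float) for v in (M, p, Y))
    S = len(M)
    d_ry = Y / M - p
    ne = float(Y.sum() - (p * M).sum())
    ce = float(S * d_ry.mean() * M.mean())
    se = float(S * np.mean((d_ry - d_ry.mean()) * (M - M.mean())))
    return ne, ce, se


def sequential_projection_ss(y, stages):
    """Type-I sums of squares by explicit Gram-Schmidt orthogonalization,
    one SS increment per stage of design columns."""
    y = np.asarray(y, dtype=float)
    basis: list[np.ndarray] = []
    out = []
    for stage in stages:
        ss_stage = 0.0
        for col in np.atleast_2d(stage.T):
            v = col.astype(float).copy()
            for b in basis:
                v -= (v @ b) * b
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                b = v / norm
                basis.append(b)
                ss_stage += float((y @ b) ** 2)
        out.append(ss_stage)
    return out
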