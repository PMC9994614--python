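"""Generator of virtual dominance-design biodiversity experiments.

The generator emulates the statistical structure of a long-running
grassland sown-diversity experiment built around potentially dominant
species: a pool of nine species (five grasses, two legumes, two forbs) of
which two are extinct (flagged inactive) leaving seven analyzable species
(four grasses, one forb, two legumes); sown richness levels 1, 2, 6 and
9; four blocks; duplicated mixture identities distributed over blocks;
and one dominant tall grass with the highest monoculture yield.

The default design has 85 plots: 7 monocultures (one per active
species), 46 two-species plots (all 21 active pairs twice plus four
single-replicate pairs involving an extinct species), 24 six-species
plots (12 balanced compositions twice), and 8 nine-species plots (the
full pool, eight replicates).

Biomass model (all per plot, S = number of active sown species,
p = 1/S over the active species — survivors occupy the ground left by
extinct neighbours):

    monoculture:  Y = mu_M * b(block) * eps           (lognormal noise)
    mixture:      Y_i = p * mu_M,i * (1 + ce_slope * log2 S
                        + se_dominance * 1[i = dominant]) * b(block) * eps_i

with mean-one multiplicative lognormal noise and mean-one lognormal block
factors.  A uniform proportional gain (ce_slope) produces a pure
complementarity effect; the dominant-species boost (se_dominance)
produces a mixture of selection and complementarity, both recoverable
exactly by feeding the noise-free yields through the partitioning
routines (that is what :class:`GroundTruth` stores).

Species-level traits follow  t = species mean + plasticity * log2 S +
block shift + Gaussian noise; plot-level variables (community root
traits, soil properties) follow  intercept + slope * log2 S +
shift * 1[dominant present] + block shift + Gaussian noise.  With the
default coefficients, soil organic carbon, total N and plant-available P
and K rise along the richness gradient while soil pH falls, and both
respond additionally to the presence of the dominant grass.
"""
from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError
from .io import BIOMASS_COLUMNS, DESIGN_COLUMNS, TRAITS_COLUMNS, Dataset, validate_dataset
from .partition import MonocultureReference, partition_table

__all__ = [
    "SpeciesSpec",
    "PlotVariableSpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "null_config",
    "identity_only_config",
    "richness_only_config",
    "anticorrelated_plasticity_config",
    "generate_design",
    "generate_biomass",
    "generate_traits_and_soil",
    "simulate_experiment",
    "write_simulation",
    "config_to_yaml",
    "config_from_yaml",
]

SPECIES_TRAITS = ("plant_height", "sla", "leaf_n", "leaf_p", "leaf_k", "amf_colonization")

TRAIT_UNITS = {
    "plant_height": "cm",
    "sla": "mm2_mg",
    "leaf_n": "mg_g",
    "leaf_p": "mg_g",
    "leaf_k": "mg_g",
    "amf_colonization": "percent",
    "rld": "cm_cm3",
    "srl": "m_g",
    "ph": "unitless",
    "organic_c": "g_kg",
    "total_n": "g_kg",
    "avail_p": "mg_kg",
    "avail_k": "mg_kg",
}


@dataclasses.dataclass
class SpeciesSpec:
    """Per-species generator parameters.

    ``mono_yield`` is the expected monoculture biomass mu_M (g m^-2),
    ``mono_cv`` its plot-to-plot coefficient of variation, ``dominance``
    an ordering weight (the species with the largest weight is the
    dominant), and ``trait_means``/``trait_plasticity`` the species trait
    intercepts and their shifts per unit log2 richness.
    """

    species_id: str
    functional_group: str
    mono_yield: float
    mono_cv: float = 0.2
    dominance: float = 0.0
    active: bool = True
    trait_means: dict[str, float] = dataclasses.field(default_factory=dict)
    trait_plasticity: dict[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class PlotVariableSpec:
    """Linear model for a plot-level variable (root trait or soil property)."""

    intercept: float
    richness_slope: float = 0.0
    dominant_shift: float = 0.0
    noise_sd: float = 0.0
    block_sd: float = 0.0
    lower: float | None = None
    upper: float | None = None


@dataclasses.dataclass
class GeneratorConfig:
    seed: int = 0
    n_blocks: int = 4
    richness_levels: tuple[int, ...] = (1, 2, 6, 9)
    species: list[SpeciesSpec] = dataclasses.field(default_factory=list)
    ce_slope: float = 0.25
    se_dominance: float = 0.5
    biomass_noise_cv: float = 0.2
    biomass_block_sd: float = 0.1
    mono_replicates: int = 1
    pair_replicates: int = 2
    extinct_pair_partners: int = 2
    intermediate_identities: int = 12
    intermediate_replicates: int = 2
    full_mixture_replicates: int = 8
    extinction_prob: float = 0.0
    trait_noise_sd: dict[str, float] = dataclasses.field(default_factory=dict)
    trait_block_sd: dict[str, float] = dataclasses.field(default_factory=dict)
    plot_variables: dict[str, PlotVariableSpec] = dataclasses.field(default_factory=dict)

    def active_species(self) -> list[SpeciesSpec]:
        return [sp for sp in self.species if sp.active]

    def dominant_species(self) -> str | None:
        candidates = [sp for sp in self.active_species() if sp.dominance > 0]
        if not candidates:
            return None
        return max(candidates, key=lambda sp: sp.dominance).species_id


@dataclasses.dataclass
class GroundTruth:
    """Noise-free quantities implied by a configuration and design."""

    dominant_species: str | None
    true_monoculture_yield: dict[str, float]
    effects: pd.DataFrame  # per plot: S, NE, CE, SE before noise
    trait_plasticity: dict[str, dict[str, float]]
    plot_variable_coefficients: dict[str, dict[str, float]]

    def reference(self) -> MonocultureReference:
        """The true monoculture means as a partitioning reference."""
        return MonocultureReference(
            M=dict(self.true_monoculture_yield),
            n_replicates={sp: 0 for sp in self.true_monoculture_yield},
        )


# ---------------------------------------------------------------------------
# default configuration: the dominance-design study conditions
# ---------------------------------------------------------------------------

_DEFAULT_PLASTICITY = {
    # cm (or trait units) per unit log2 richness; species grow taller in
    # mixtures, while leaf N, leaf P and mycorrhization shift downward.
    "plant_height": 1.5,
    "sla": 0.0,
    "leaf_n": -0.8,
    "leaf_p": -0.15,
    "leaf_k": 0.0,
    "amf_colonization": -2.0,
}

_DEFAULT_TRAIT_NOISE = {
    "plant_height": 3.0,
    "sla": 2.0,
    "leaf_n": 2.0,
    "leaf_p": 0.3,
    "leaf_k": 2.0,
    "amf_colonization": 8.0,
}

# (group, mono_yield, dominance, height, sla, leaf_n, leaf_p, leaf_k, amf, active)
_DEFAULT_POOL = [
    ("Arr.ela", "grass", 350.0, 1.0, 45.6, 24.4, 23.7, 3.6, 25.5, 40.6, True),
    ("Alo.pra", "grass", 120.0, 0.0, 29.0, 17.1, 17.7, 2.8, 23.8, 30.7, True),
    ("Dac.glo", "grass", 90.0, 0.0, 23.7, 23.3, 22.0, 3.3, 26.3, 33.5, True),
    ("Poa.tri", "grass", 45.0, 0.0, 12.5, 29.7, 16.1, 2.6, 27.8, 11.0, True),
    ("Phl.pra", "grass", 0.0, 0.0, 30.0, 20.0, 18.0, 3.0, 24.0, 30.0, False),
    ("Ger.pra", "forb", 130.0, 0.0, 27.9, 18.2, 26.3, 4.2, 14.2, 65.5, True),
    ("Ant.syl", "forb", 0.0, 0.0, 40.0, 22.0, 28.0, 3.5, 20.0, 50.0, False),
    ("Tri.pra", "legume", 90.0, 0.0, 15.2, 25.5, 40.7, 2.5, 10.2, 77.6, True),
    ("Tri.rep", "legume", 15.0, 0.0, 11.9, 19.9, 41.3, 2.6, 8.7, 86.5, True),
]

_DEFAULT_PLOT_VARIABLES = {
    "rld": PlotVariableSpec(20.0, 3.0, 2.0, 2.0, 1.0, lower=0.0),
    "srl": PlotVariableSpec(100.0, -5.0, 0.0, 8.0, 4.0, lower=0.0),
    "ph": PlotVariableSpec(7.3, -0.08, -0.05, 0.05, 0.05),
    "organic_c": PlotVariableSpec(13.0, 0.6, 0.4, 0.5, 0.3, lower=0.0),
    "total_n": PlotVariableSpec(1.30, 0.05, 0.03, 0.05, 0.03, lower=0.0),
    "avail_p": PlotVariableSpec(45.0, 2.0, 1.5, 3.0, 1.5, lower=0.0),
    "avail_k": PlotVariableSpec(150.0, 5.0, 3.0, 10.0, 5.0, lower=0.0),
}


def default_config(seed: int = 0) -> GeneratorConfig:
    """The default 85-plot dominance-design configuration."""
    species = []
    for sid, group, mono, dom, height, sla, ln, lp, lk, amf, active in _DEFAULT_POOL:
        species.append(
            SpeciesSpec(
                species_id=sid,
                functional_group=group,
                mono_yield=mono,
                mono_cv=0.2,
                dominance=dom,
                active=active,
                trait_means={
                    "plant_height": height,
                    "sla": sla,
                    "leaf_n": ln,
                    "leaf_p": lp,
                    "leaf_k": lk,
                    "amf_colonization": amf,
                },
                trait_plasticity=dict(_DEFAULT_PLASTICITY),
            )
        )
    return GeneratorConfig(
        seed=seed,
        species=species,
        trait_noise_sd=dict(_DEFAULT_TRAIT_NOISE),
        trait_block_sd={k: v / 2.0 for k, v in _DEFAULT_TRAIT_NOISE.items()},
        plot_variables={k: dataclasses.replace(v) for k, v in _DEFAULT_PLOT_VARIABLES.items()},
    )


def null_config(seed: int = 0) -> GeneratorConfig:
    """All effect parameters zero: no biodiversity effects, no plasticity,
    no richness or dominance responses — only block structure and noise."""
    config = default_config(seed)
    config.ce_slope = 0.0
    config.se_dominance = 0.0
    for sp in config.species:
        sp.trait_plasticity = {t: 0.0 for t in SPECIES_TRAITS}
    for spec in config.plot_variables.values():
        spec.richness_slope = 0.0
        spec.dominant_shift = 0.0
    return config


def identity_only_config(seed: int = 0, ph_shift: float = -0.15) -> GeneratorConfig:
    """Scenario where soil pH responds only to the presence of the dominant
    grass; any apparent richness trend is carried entirely by the rising
    frequency of that species along the richness gradient."""
    config = null_config(seed)
    config.plot_variables["ph"].dominant_shift = ph_shift
    return config


def richness_only_config(seed: int = 0, ph_slope: float = -0.08) -> GeneratorConfig:
    """Scenario where soil pH responds to log2 richness with no species
    identity effect at all."""
    config = null_config(seed)
    config.plot_variables["ph"].richness_slope = ph_slope
    return config


def anticorrelated_plasticity_config(seed: int = 0, height_plasticity: float = -3.0) -> GeneratorConfig:
    """Scenario with opposing composition and adjustment trends for plant
    height: the tall dominant grass gains weight in species-rich plots
    (composition/abundance component rises) while individuals shrink with
    richness (adjustment component falls), producing a negative
    covariation share."""
    config = default_config(seed)
    for sp in config.species:
        sp.trait_plasticity = {t: 0.0 for t in SPECIES_TRAITS}
        sp.trait_plasticity["plant_height"] = height_plasticity
    return config


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

def _balanced_subsets(pool: list[str], size: int, count: int, rng) -> list[tuple[str, ...]]:
    """``count`` distinct subsets of ``pool`` of the given size with
    species occurrence counts as even as the combinatorics allow."""
    max_combinations = 1
    for i in range(size):
        max_combinations = max_combinations * (len(pool) - i) // (i + 1)
    if count > max_combinations:
        raise DesignError(
            f"cannot draw {count} distinct subsets of size {size} from a pool of {len(pool)}"
        )
    counts = {sp: 0 for sp in pool}
    subsets: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(count):
        for attempt in range(200):
            jitter = rng.permutation(len(pool))
            order = sorted(range(len(pool)), key=lambda i: (counts[pool[i]], jitter[i]))
            chosen = [pool[i] for i in order[:size]]
            # later attempts swap random members in to escape repeats that
            # pure count-ordering cannot avoid
            for _swap in range(min(attempt, size)):
                out_idx = int(rng.integers(size))
                candidates = [sp for sp in pool if sp not in chosen]
                chosen[out_idx] = candidates[int(rng.integers(len(candidates)))]
            subset = tuple(sorted(chosen))
            if subset not in seen:
                break
        else:
            raise DesignError("failed to construct distinct balanced subsets")
        seen.add(subset)
        subsets.append(subset)
        for sp in subset:
            counts[sp] += 1
    return subsets


def _assign_blocks(identities: list[tuple[str, int]], n_blocks: int, rng) -> list[str]:
    """Block per plot; replicates of an identity go to distinct blocks
    whenever replicate count <= block count, and block sizes stay even."""
    loads = np.zeros(n_blocks)
    blocks: dict[tuple[str, int], int] = {}
    order = rng.permutation(len(identities))
    grouped: dict[str, list[int]] = {}
    for idx in order:
        identity, _rep = identities[idx]
        grouped.setdefault(identity, []).append(idx)
    for identity in grouped:
        used: set[int] = set()
        for idx in grouped[identity]:
            candidates = [b for b in range(n_blocks) if b not in used] or list(range(n_blocks))
            jitter = rng.permutation(n_blocks)
            best = min(candidates, key=lambda b: (loads[b], jitter[b]))
            loads[best] += 1
            used.add(best)
            blocks[identities[idx]] = best
    return [f"B{blocks[key] + 1}" for key in identities]


def generate_design(config: GeneratorConfig, rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (species table, long design table) for the configuration.

    Monocultures are sown for every active species; pairs of active
    species are fully crossed and replicated; each extinct species joins a
    few single-replicate pairs; intermediate richness levels use balanced
    subsets of the full pool; the top level sows the complete pool.
    Deterministic given the configuration seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = [sp.species_id for sp in config.species]
    active = [sp.species_id for sp in config.active_species()]
    if not active:
        raise DesignError("species pool has no active species")
    levels = sorted(set(config.richness_levels))
    if levels and max(levels) > len(pool):
        raise DesignError(
            f"richness level {max(levels)} infeasible with a pool of {len(pool)} species"
        )
    compositions: list[tuple[str, tuple[str, ...], int]] = []  # (mixture_id, sown, replicates)
    inactive = [sid for sid in pool if sid not in active]
    for level in levels:
        if level == 1:
            for sid in active:
                compositions.append((f"mono_{sid}", (sid,), config.mono_replicates))
        elif level == 2:
            for k, pair in enumerate(itertools.combinations(active, 2), start=1):
                compositions.append((f"pair_{k:02d}", pair, config.pair_replicates))
            k = 0
            for sid in inactive:
                partners = rng.choice(active, size=min(config.extinct_pair_partners, len(active)), replace=False)
                for partner in sorted(partners):
                    k += 1
                    compositions.append((f"xpair_{k:02d}", tuple(sorted((sid, partner))), 1))
        elif level == len(pool):
            compositions.append(("full_pool", tuple(pool), config.full_mixture_replicates))
        else:
            subsets = _balanced_subsets(pool, level, config.intermediate_identities, rng)
            for k, subset in enumerate(subsets, start=1):
                compositions.append((f"mix{level}_{k:02d}", subset, config.intermediate_replicates))

    identities = [
        (mixture_id, rep)
        for mixture_id, _sown, reps in compositions
        for rep in range(reps)
    ]
    blocks = _assign_blocks(identities, config.n_blocks, rng)
    sown_by_identity = {mixture_id: sown for mixture_id, sown, _ in compositions}

    rows = []
    for plot_number, ((mixture_id, _rep), block) in enumerate(zip(identities, blocks), start=1):
        plot_id = f"p{plot_number:03d}"
        sown = sown_by_identity[mixture_id]
        for sid in sown:
            rows.append((plot_id, block, mixture_id, sid, 1.0 / len(sown)))
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    species = pd.DataFrame(
        {
            "species_id": [sp.species_id for sp in config.species],
            "functional_group": [sp.functional_group for sp in config.species],
            "active": [sp.active for sp in config.species],
        }
    )
    return species, design


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

def _lognormal_mean1(cv: float, rng, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=size))


def _plot_structure(design: pd.DataFrame, active: set[str]):
    """Per plot: (block, mixture_id, active sown species, sown set)."""
    out = {}
    for plot_id, rows in design.groupby("plot_id", sort=False):
        sown = tuple(rows["species_id"])
        out[plot_id] = (
            str(rows["block"].iloc[0]),
            str(rows["mixture_id"].iloc[0]),
            tuple(sid for sid in sown if sid in active),
            sown,
        )
    return out


def generate_biomass(
    design: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw species biomasses for every plot and compute the ground truth.

    Only active species produce biomass (extinct species yield nothing and
    get no biomass rows, as they are never sampled).  Survivors divide the
    plot evenly: expected proportions are 1/S over the S active sown
    species.  The ground-truth table holds the per-plot NE/CE/SE implied
    by the noise-free yields, obtained by passing those yields through the
    partitioning routines against the true monoculture means.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    specs = {sp.species_id: sp for sp in config.species}
    active = {sp.species_id for sp in config.active_species()}
    dominant = config.dominant_species()
    blocks = sorted(design["block"].unique())
    block_factor = dict(zip(blocks, _lognormal_mean1(config.biomass_block_sd, rng, size=len(blocks))))

    structure = _plot_structure(design, active)
    rows = []
    truth_rows = []
    for plot_id, (block, _mixture, act, _sown) in structure.items():
        S = len(act)
        if S == 0:
            continue
        p = 1.0 / S
        for sid in act:
            spec = specs[sid]
            if S == 1:
                noise = _lognormal_mean1(spec.mono_cv, rng)
                y = spec.mono_yield * block_factor[block] * noise
                expected = spec.mono_yield
            else:
                mult = 1.0 + config.ce_slope * np.log2(S)
                if dominant is not None and sid == dominant:
                    mult += config.se_dominance
                noise = _lognormal_mean1(config.biomass_noise_cv, rng)
                expected = p * spec.mono_yield * mult
                y = expected * block_factor[block] * noise
            if config.extinction_prob > 0 and S >= 2 and rng.random() < config.extinction_prob:
                y = 0.0
            rows.append((plot_id, sid, float(y)))
            truth_rows.append((plot_id, sid, float(expected)))
    biomass = pd.DataFrame(rows, columns=BIOMASS_COLUMNS)

    true_M = {sid: specs[sid].mono_yield for sid in active}
    reference = MonocultureReference(M=true_M, n_replicates={sid: 0 for sid in true_M})
    noise_free = pd.DataFrame(truth_rows, columns=BIOMASS_COLUMNS)
    active_design = design.loc[design["species_id"].isin(active)].copy()
    sums = active_design.groupby("plot_id")["sown_proportion"].transform("sum")
    active_design["sown_proportion"] = active_design["sown_proportion"] / sums
    effects, _ = partition_table(active_design, noise_free, reference)

    truth = GroundTruth(
        dominant_species=dominant,
        true_monoculture_yield=true_M,
        effects=effects,
        trait_plasticity={
            sp.species_id: dict(sp.trait_plasticity) for sp in config.active_species()
        },
        plot_variable_coefficients={
            name: {
                "intercept": spec.intercept,
                "richness_slope": spec.richness_slope,
                "dominant_shift": spec.dominant_shift,
            }
            for name, spec in config.plot_variables.items()
        },
    )
    return biomass, truth


# ---------------------------------------------------------------------------
# traits and soil
# ---------------------------------------------------------------------------

def generate_traits_and_soil(
    design: pd.DataFrame,
    biomass: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Species-level trait values for species present at harvest, plus
    plot-level community root traits and soil properties."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    specs = {sp.species_id: sp for sp in config.species}
    active = {sp.species_id for sp in config.active_species()}
    dominant = config.dominant_species()
    blocks = sorted(design["block"].unique())

    trait_shift = {
        (trait, block): rng.normal(0.0, config.trait_block_sd.get(trait, 0.0))
        for trait in SPECIES_TRAITS
        for block in blocks
    }
    plot_shift = {
        (name, block): rng.normal(0.0, spec.block_sd)
        for name, spec in sorted(config.plot_variables.items())
        for block in blocks
    }

    present = biomass.loc[biomass["biomass_g_m2"] > 0]
    present_pairs = set(zip(present["plot_id"], present["species_id"]))
    structure = _plot_structure(design, active)

    rows = []
    for plot_id, (block, _mixture, act, _sown) in structure.items():
        S = max(len(act), 1)
        log_s = np.log2(S)
        for sid in act:
            if (plot_id, sid) not in present_pairs:
                continue
            spec = specs[sid]
            for trait in SPECIES_TRAITS:
                if trait not in spec.trait_means:
                    continue
                value = (
                    spec.trait_means[trait]
                    + spec.trait_plasticity.get(trait, 0.0) * log_s
                    + trait_shift[(trait, block)]
                    + rng.normal(0.0, config.trait_noise_sd.get(trait, 0.0))
                )
                if trait == "amf_colonization":
                    value = float(np.clip(value, 0.0, 100.0))
                else:
                    value = float(max(value, 0.0))
                rows.append((plot_id, sid, trait, value, TRAIT_UNITS[trait]))
        has_dominant = dominant is not None and dominant in act
        for name, spec in sorted(config.plot_variables.items()):
            value = (
                spec.intercept
                + spec.richness_slope * log_s
                + (spec.dominant_shift if has_dominant else 0.0)
                + plot_shift[(name, block)]
                + rng.normal(0.0, spec.noise_sd)
            )
            if spec.lower is not None:
                value = max(value, spec.lower)
            if spec.upper is not None:
                value = min(value, spec.upper)
            rows.append((plot_id, None, name, float(value), TRAIT_UNITS[name]))
    return pd.DataFrame(rows, columns=TRAITS_COLUMNS)


# ---------------------------------------------------------------------------
# top-level driver and serialization
# ---------------------------------------------------------------------------

def simulate_experiment(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    include_traits: bool = True,
    validate: bool = True,
) -> tuple[Dataset, GroundTruth]:
    """Generate a complete virtual experiment.

    ``seed`` overrides ``config.seed``; identical configuration and seed
    produce bit-identical tables.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    species, design = generate_design(config, rng)
    biomass, truth = generate_biomass(design, config, rng)
    if include_traits:
        traits = generate_traits_and_soil(design, biomass, config, rng)
    else:
        traits = pd.DataFrame(columns=TRAITS_COLUMNS)
    dataset = Dataset(species=species, design=design, biomass=biomass, traits=traits)
    if validate:
        validate_dataset(dataset)
    return dataset, truth


def write_simulation(dataset: Dataset, truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset tables plus a truth.json with the ground truth."""
    from .io import write_dataset

    out = Path(out_dir)
    paths = write_dataset(dataset, out)
    truth_payload = {
        "dominant_species": truth.dominant_species,
        "true_monoculture_yield": truth.true_monoculture_yield,
        "trait_plasticity": truth.trait_plasticity,
        "plot_variable_coefficients": truth.plot_variable_coefficients,
        "effects": truth.effects.reset_index().to_dict(orient="records"),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["richness_levels"] = list(config.richness_levels)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    payload = yaml.safe_load(Path(path).read_text())
    species = [SpeciesSpec(**sp) for sp in payload.pop("species", [])]
    plot_variables = {
        name: PlotVariableSpec(**spec)
        for name, spec in payload.pop("plot_variables", {}).items()
    }
    payload["richness_levels"] = tuple(payload.get("richness_levels", (1, 2, 6, 9)))
    return GeneratorConfig(species=species, plot_variables=plot_variables, **payload)
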