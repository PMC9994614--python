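"""Data model, tabular readers/writers, and validation for designed
biodiversity-experiment datasets.

A dataset consists of four long/tidy tables:

``species.csv``
    species_id, functional_group (grass | forb | legume | unknown),
    active (species flagged inactive, e.g. extinct pool-wide, are dropped
    from all computations by :func:`drop_inactive`).
``design.csv``
    plot_id, block, mixture_id, species_id, sown_proportion — one row per
    plot × sown species.  Replicate plots sown with the identical species
    set share a ``mixture_id``.
``biomass.csv``
    plot_id, species_id, biomass_g_m2 — observed aboveground biomass of the
    sown species (weeds and dead material are outside the data model).
``traits.csv``
    plot_id, species_id, variable, value, unit — species-level trait
    measurements (species_id set) and plot-level variables such as
    community root traits and soil properties (species_id empty).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

SPECIES_COLUMNS = ["species_id", "functional_group", "active"]
DESIGN_COLUMNS = ["plot_id", "block", "mixture_id", "species_id", "sown_proportion"]
BIOMASS_COLUMNS = ["plot_id", "species_id", "biomass_g_m2"]
TRAITS_COLUMNS = ["plot_id", "species_id", "variable", "value", "unit"]

FUNCTIONAL_GROUPS = {"grass", "forb", "legume", "unknown"}

#: Tolerance for the per-plot sum of sown proportions.
PROPORTION_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class PlotDesign:
    """Sown composition of one plot."""

    plot_id: str
    block: str
    mixture_id: str
    sown_species: tuple[str, ...]
    sown_proportion: Mapping[str, float]

    @property
    def sown_richness(self) -> int:
        return len(self.sown_species)


@dataclasses.dataclass(frozen=True)
class MixtureObservation:
    """Observed species biomasses (g m^-2) of one plot.

    Species sown but absent at harvest appear with biomass 0; they remain
    part of the plot's sown set and carry negative relative-yield
    deviations downstream.
    """

    plot_id: str
    biomass: Mapping[str, float]

    @property
    def total_biomass(self) -> float:
        return float(sum(self.biomass.values()))

    def realized_richness(self, threshold: float = 0.0) -> int:
        return compute_realized_richness(self, threshold)


def compute_realized_richness(obs: MixtureObservation, threshold: float = 0.0) -> int:
    """Number of sown species with biomass strictly above ``threshold``.

    The default threshold of 0 counts any positive biomass as presence.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return int(sum(1 for v in obs.biomass.values() if v > threshold))


@dataclasses.dataclass
class Dataset:
    """In-memory container for one experiment.

    The four tables are plain :class:`pandas.DataFrame` objects following
    the column schemas at the top of this module.  Accessors build the
    light per-plot objects used by the analysis modules.
    """

    species: pd.DataFrame
    design: pd.DataFrame
    biomass: pd.DataFrame
    traits: pd.DataFrame

    # -- species pool -----------------------------------------------------
    def all_species(self) -> list[str]:
        return list(self.species["species_id"])

    def active_species(self) -> list[str]:
        mask = self.species["active"].astype(bool)
        return list(self.species.loc[mask, "species_id"])

    def functional_group(self, species_id: str) -> str:
        row = self.species.loc[self.species["species_id"] == species_id]
        if row.empty:
            raise ReferentialError(f"unknown species_id {species_id!r}")
        return str(row["functional_group"].iloc[0])

    # -- per-plot views ---------------------------------------------------
    def plot_ids(self) -> list[str]:
        return list(dict.fromkeys(self.design["plot_id"]))

    def plot_design(self, plot_id: str) -> PlotDesign:
        rows = self.design.loc[self.design["plot_id"] == plot_id]
        if rows.empty:
            raise ReferentialError(f"unknown plot_id {plot_id!r}")
        species = tuple(rows["species_id"])
        props = dict(zip(rows["species_id"], rows["sown_proportion"].astype(float)))
        return PlotDesign(
            plot_id=plot_id,
            block=str(rows["block"].iloc[0]),
            mixture_id=str(rows["mixture_id"].iloc[0]),
            sown_species=species,
            sown_proportion=props,
        )

    def observation(self, plot_id: str) -> MixtureObservation:
        design = self.plot_design(plot_id)
        rows = self.biomass.loc[self.biomass["plot_id"] == plot_id]
        observed = dict(zip(rows["species_id"], rows["biomass_g_m2"].astype(float)))
        biomass = {sp: float(observed.get(sp, 0.0)) for sp in design.sown_species}
        return MixtureObservation(plot_id=plot_id, biomass=biomass)

    def plot_frame(self) -> pd.DataFrame:
        """Per-plot summary used by the statistical modules.

        Columns: block, mixture_id, sown_richness, realized_richness,
        total_biomass, sown_species (frozenset).  Indexed by plot_id in
        design order.
        """
        grouped = self.design.groupby("plot_id", sort=False)
        frame = grouped.agg(
            block=("block", "first"),
            mixture_id=("mixture_id", "first"),
            sown_richness=("species_id", "size"),
        )
        frame["sown_species"] = grouped["species_id"].agg(frozenset)
        positive = self.biomass.loc[self.biomass["biomass_g_m2"] > 0]
        realized = positive.groupby("plot_id")["species_id"].nunique()
        frame["realized_richness"] = realized.reindex(frame.index, fill_value=0).astype(int)
        total = self.biomass.groupby("plot_id")["biomass_g_m2"].sum()
        frame["total_biomass"] = total.reindex(frame.index, fill_value=0.0)
        return frame

    # -- trait views ------------------------------------------------------
    def species_trait_values(self, trait_name: str) -> dict[str, dict[str, float]]:
        """Plot-specific species-level trait values, ``{plot: {species: value}}``."""
        rows = self.traits.loc[
            (self.traits["variable"] == trait_name) & self.traits["species_id"].notna()
        ]
        out: dict[str, dict[str, float]] = {}
        for plot_id, sub in rows.groupby("plot_id", sort=False):
            out[str(plot_id)] = dict(zip(sub["species_id"], sub["value"].astype(float)))
        return out

    def plot_variable(self, variable: str) -> pd.Series:
        """Plot-level variable (community root trait or soil property)."""
        rows = self.traits.loc[
            (self.traits["variable"] == variable) & self.traits["species_id"].isna()
        ]
        return pd.Series(
            rows["value"].astype(float).to_numpy(), index=list(rows["plot_id"]), name=variable
        )

    def species_trait_names(self) -> list[str]:
        rows = self.traits.loc[self.traits["species_id"].notna()]
        return sorted(rows["variable"].unique())

    def plot_variable_names(self) -> list[str]:
        rows = self.traits.loc[self.traits["species_id"].isna()]
        return sorted(rows["variable"].unique())


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    for column in columns:
        if column not in df.columns:
            raise SchemaError(f"missing required column {column!r} in {table} table")


def validate_dataset(dataset: Dataset) -> None:
    """Check all schema, domain, and cross-reference invariants.

    Raises :class:`SchemaError`, :class:`ReferentialError`, or
    :class:`ValidationError` on the first violation found.
    """
    species, design = dataset.species, dataset.design
    biomass, traits = dataset.biomass, dataset.traits

    _require_columns(species, SPECIES_COLUMNS, "species")
    _require_columns(design, DESIGN_COLUMNS, "design")
    _require_columns(biomass, BIOMASS_COLUMNS, "biomass")
    _require_columns(traits, TRAITS_COLUMNS, "traits")

    # species pool
    if species["species_id"].duplicated().any():
        raise ValidationError("duplicate species_id in species table")
    if len(species) == 0 or not species["active"].astype(bool).any():
        raise ValidationError("species pool must contain at least one active species")
    bad_groups = set(species["functional_group"]) - FUNCTIONAL_GROUPS
    if bad_groups:
        raise ValidationError(f"unknown functional_group value(s): {sorted(bad_groups)}")
    pool = set(species["species_id"])

    # design
    if design[["plot_id", "species_id"]].duplicated().any():
        raise ValidationError("duplicate (plot_id, species_id) row in design table")
    unknown = set(design["species_id"]) - pool
    if unknown:
        raise ReferentialError(f"design refers to unknown species: {sorted(unknown)}")
    props = design["sown_proportion"].astype(float)
    if not np.isfinite(props).all() or (props < 0).any() or (props > 1).any():
        raise ValidationError("sown_proportion values must be finite and within [0, 1]")
    sums = design.groupby("plot_id")["sown_proportion"].sum()
    off = sums[(sums - 1.0).abs() > PROPORTION_TOL]
    if not off.empty:
        raise ValidationError(
            f"sown proportions do not sum to 1 for plot(s) {list(off.index)[:5]}"
        )
    for column in ("block", "mixture_id"):
        n_unique = design.groupby("plot_id")[column].nunique()
        if (n_unique > 1).any():
            raise ValidationError(f"plot with inconsistent {column} in design table")
    # replicate plots of one mixture identity must share the sown set
    sets_by_plot = design.groupby("plot_id").agg(
        mixture_id=("mixture_id", "first"), sown=("species_id", frozenset)
    )
    n_sets = sets_by_plot.groupby("mixture_id")["sown"].nunique()
    bad = n_sets[n_sets > 1]
    if not bad.empty:
        raise ValidationError(
            f"mixture identity with differing sown sets: {list(bad.index)[:5]}"
        )

    # biomass
    sown_pairs = set(zip(design["plot_id"], design["species_id"]))
    plots = set(design["plot_id"])
    if biomass[["plot_id", "species_id"]].duplicated().any():
        raise ValidationError("duplicate (plot_id, species_id) row in biomass table")
    values = biomass["biomass_g_m2"].astype(float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValidationError("biomass values must be finite and non-negative")
    for plot_id, species_id in zip(biomass["plot_id"], biomass["species_id"]):
        if plot_id not in plots:
            raise ReferentialError(f"biomass row for unknown plot {plot_id!r}")
        if (plot_id, species_id) not in sown_pairs:
            raise ReferentialError(
                f"biomass row for species {species_id!r} not sown in plot {plot_id!r}"
            )

    # traits
    if len(traits):
        trait_values = traits["value"].astype(float)
        if not np.isfinite(trait_values).all():
            raise ValidationError("trait values must be finite")
        units = traits.groupby("variable")["unit"].nunique()
        mixed = units[units > 1]
        if not mixed.empty:
            raise ValidationError(
                f"variable(s) with inconsistent units: {list(mixed.index)[:5]}"
            )
        species_rows = traits.loc[traits["species_id"].notna()]
        for plot_id, species_id in zip(species_rows["plot_id"], species_rows["species_id"]):
            if (plot_id, species_id) not in sown_pairs:
                raise ReferentialError(
                    f"trait row for species {species_id!r} not sown in plot {plot_id!r}"
                )
        plot_rows = traits.loc[traits["species_id"].isna()]
        unknown_plots = set(plot_rows["plot_id"]) - plots
        if unknown_plots:
            raise ReferentialError(
                f"trait rows for unknown plot(s): {sorted(unknown_plots)[:5]}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _empty_traits() -> pd.DataFrame:
    return pd.DataFrame(columns=TRAITS_COLUMNS)


def read_dataset(
    design_path: str | Path,
    biomass_path: str | Path,
    traits_path: str | Path | None = None,
    species_path: str | Path | None = None,
    *,
    delimiter: str = ",",
    validate: bool = True,
) -> Dataset:
    """Read and cross-validate a dataset from delimited text tables.

    ``traits_path`` and ``species_path`` are optional; without a species
    table the pool is inferred from the design (all species active,
    functional group ``unknown``).
    """
    design = pd.read_csv(design_path, delimiter=delimiter, dtype={"plot_id": str, "block": str, "mixture_id": str, "species_id": str})
    biomass = pd.read_csv(biomass_path, delimiter=delimiter, dtype={"plot_id": str, "species_id": str})
    if traits_path is not None:
        traits = pd.read_csv(traits_path, delimiter=delimiter, dtype={"plot_id": str, "species_id": str, "variable": str, "unit": str})
    else:
        traits = _empty_traits()
    if species_path is not None:
        species = pd.read_csv(species_path, delimiter=delimiter, dtype={"species_id": str, "functional_group": str})
    else:
        _require_columns(design, ["species_id"], "design")
        species = pd.DataFrame(
            {
                "species_id": sorted(set(design["species_id"])),
                "functional_group": "unknown",
                "active": True,
            }
        )
    if "active" in species.columns:
        species["active"] = species["active"].astype(bool)
    dataset = Dataset(species=species, design=design, biomass=biomass, traits=traits)
    if validate:
        validate_dataset(dataset)
    return dataset


def write_dataset(dataset: Dataset, out_dir: str | Path, *, delimiter: str = ",") -> dict[str, Path]:
    """Write the four tables to ``out_dir`` and return the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": out / "species.csv",
        "design": out / "design.csv",
        "biomass": out / "biomass.csv",
        "traits": out / "traits.csv",
    }
    dataset.species.to_csv(paths["species"], sep=delimiter, index=False)
    dataset.design.to_csv(paths["design"], sep=delimiter, index=False)
    dataset.biomass.to_csv(paths["biomass"], sep=delimiter, index=False)
    dataset.traits.to_csv(paths["traits"], sep=delimiter, index=False)
    return paths


def drop_inactive(dataset: Dataset, *, renormalize: bool = True) -> Dataset:
    """Remove inactive (e.g. extinct) species from every table.

    Sown proportions of the remaining species are renormalized per plot so
    the design invariant (proportions sum to 1) is preserved; a plot left
    with no active species is dropped entirely.  The declared sown
    richness of the original design is a design property and should be
    taken from the unfiltered dataset's :meth:`Dataset.plot_frame` when it
    is needed as a model covariate.
    """
    active = set(dataset.active_species())
    design = dataset.design.loc[dataset.design["species_id"].isin(active)].copy()
    if renormalize:
        sums = design.groupby("plot_id")["sown_proportion"].transform("sum")
        design["sown_proportion"] = design["sown_proportion"] / sums
    biomass = dataset.biomass.loc[dataset.biomass["species_id"].isin(active)].copy()
    keep_plots = set(design["plot_id"])
    biomass = biomass.loc[biomass["plot_id"].isin(keep_plots)]
    traits = dataset.traits.loc[
        dataset.traits["plot_id"].isin(keep_plots)
        & (dataset.traits["species_id"].isna() | dataset.traits["species_id"].isin(active))
    ].copy()
    species = dataset.species.loc[dataset.species["active"].astype(bool)].copy()
    return Dataset(species=species, design=design.reset_index(drop=True),
                   biomass=biomass.reset_index(drop=True), traits=traits.reset_index(drop=True))
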