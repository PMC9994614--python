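"""Loreau–Hector additive partitioning of overyielding.

For a plot sown with S species, let ``M_i`` be the monoculture yield of
species i (averaged over its monoculture plots), ``Y_i`` its observed
yield in the mixture, ``RY_exp,i`` its expected relative yield (the sown
proportion, 1/S for an equal-density sowing), and

    RY_obs,i = Y_i / M_i,      dRY_i = RY_obs,i - RY_exp,i.

The net biodiversity effect and its two components are

    NE = sum_i M_i * dRY_i
    SE = sum_i (dRY_i - mean(dRY)) * (M_i - mean(M))     (selection)
    CE = sum_i [ M_i * dRY_i ] - SE                       (complementarity)

so that NE = CE + SE holds as an algebraic identity.  The selection
effect is S times the (population) covariance between dRY and M: it is
large when productive species over- or under-perform disproportionally.
The complementarity effect equals S * mean(dRY) * mean(M): it reflects
average proportional gains shared across species.

Species sown but absent at harvest contribute Y_i = 0 (dRY_i =
-RY_exp,i) and stay in the partition; dropping them would bias NE upward.
Monocultures carry no biodiversity effect by construction and are
reported as NE = CE = SE = 0.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DesignError, ValidationError
from .io import Dataset, MixtureObservation, PlotDesign

__all__ = [
    "MonocultureReference",
    "PartitionResult",
    "build_monoculture_reference",
    "partition_plot",
    "partition_table",
    "partition_dataset",
    "signed_sqrt",
    "test_effects_positive",
]


@dataclasses.dataclass(frozen=True)
class MonocultureReference:
    """Per-species monoculture yields M_i (g m^-2) and replicate counts."""

    M: Mapping[str, float]
    n_replicates: Mapping[str, int]

    def require(self, species_id: str) -> float:
        try:
            return float(self.M[species_id])
        except KeyError:
            raise ConfigurationError(
                f"no monoculture reference for species {species_id!r}; "
                "deactivate the species or supply a monoculture plot"
            ) from None


@dataclasses.dataclass
class PartitionResult:
    """Per-plot partition with per-species internals.

    Arrays are aligned with ``species_ids``; totals are in g m^-2.
    """

    plot_id: str
    S: int
    species_ids: list[str]
    M: np.ndarray
    ry_expected: np.ndarray
    ry_observed: np.ndarray
    d_ry: np.ndarray
    se_i: np.ndarray
    ce_i: np.ndarray
    ne: float
    ce: float
    se: float

    def species_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "species_id": self.species_ids,
                "M": self.M,
                "ry_expected": self.ry_expected,
                "ry_observed": self.ry_observed,
                "d_ry": self.d_ry,
                "se_i": self.se_i,
                "ce_i": self.ce_i,
            }
        )


def build_monoculture_reference(dataset: Dataset) -> MonocultureReference:
    """Average monoculture biomass per species over all its monoculture plots.

    Monoculture plots are those sown with a single species; plots from all
    blocks enter the average to level out block-to-block soil differences.
    Raises :class:`ConfigurationError` for an active species without a
    positive monoculture yield — the caller should deactivate such species
    (the treatment given to species that went extinct pool-wide).
    """
    counts = dataset.design.groupby("plot_id")["species_id"].transform("size")
    mono = dataset.design.loc[counts == 1, ["plot_id", "species_id"]]
    biomass = dataset.biomass.set_index(["plot_id", "species_id"])["biomass_g_m2"]
    yields: dict[str, list[float]] = {}
    for plot_id, species_id in zip(mono["plot_id"], mono["species_id"]):
        value = float(biomass.get((plot_id, species_id), 0.0))
        yields.setdefault(species_id, []).append(value)
    M = {sp: float(np.mean(vals)) for sp, vals in yields.items()}
    n = {sp: len(vals) for sp, vals in yields.items()}
    for species_id in dataset.active_species():
        if species_id not in M:
            raise ConfigurationError(
                f"active species {species_id!r} has no monoculture plot; "
                "deactivate it to exclude it from the partition"
            )
        if M[species_id] <= 0:
            raise ConfigurationError(
                f"active species {species_id!r} has monoculture yield <= 0; "
                "deactivate it to exclude it from the partition"
            )
    return MonocultureReference(M=M, n_replicates=n)


def partition_plot(
    obs: MixtureObservation,
    design: PlotDesign,
    ref: MonocultureReference,
) -> PartitionResult:
    """Additive partition of one plot's overyielding into CE and SE.

    Expected relative yields equal the sown proportions.  Monocultures
    (S = 1) are defined to carry no biodiversity effect and return
    NE = CE = SE = 0; they are excluded from the greater-than-zero tests.
    """
    species = list(design.sown_species)
    S = len(species)
    if S == 0:
        raise ValidationError(f"plot {design.plot_id!r} has no sown species")
    M = np.array([ref.require(sp) for sp in species], dtype=float)
    ry_exp = np.array([design.sown_proportion[sp] for sp in species], dtype=float)
    Y = np.array([obs.biomass.get(sp, 0.0) for sp in species], dtype=float)
    ry_obs = Y / M
    d_ry = ry_obs - ry_exp
    if S == 1:
        zero = np.zeros(1)
        return PartitionResult(
            plot_id=design.plot_id, S=1, species_ids=species, M=M,
            ry_expected=ry_exp, ry_observed=ry_obs, d_ry=d_ry,
            se_i=zero, ce_i=zero, ne=0.0, ce=0.0, se=0.0,
        )
    se_i = (d_ry - d_ry.mean()) * (M - M.mean())
    ce_i = M * d_ry - se_i
    se = float(se_i.sum())
    ce = float(ce_i.sum())
    return PartitionResult(
        plot_id=design.plot_id, S=S, species_ids=species, M=M,
        ry_expected=ry_exp, ry_observed=ry_obs, d_ry=d_ry,
        se_i=se_i, ce_i=ce_i, ne=ce + se, ce=ce, se=se,
    )


def partition_table(
    design: pd.DataFrame,
    biomass: pd.DataFrame,
    ref: MonocultureReference,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition every plot of a long design/biomass table pair.

    Returns ``(totals, per_species)``: totals has one row per plot with
    columns S, NE, CE, SE (indexed by plot_id, design order); per_species
    holds the relative-yield internals.
    """
    observed = biomass.set_index(["plot_id", "species_id"])["biomass_g_m2"].to_dict()
    totals: list[tuple[str, int, float, float, float]] = []
    per_species: list[pd.DataFrame] = []
    for plot_id, rows in design.groupby("plot_id", sort=False):
        pdesign = PlotDesign(
            plot_id=str(plot_id),
            block=str(rows["block"].iloc[0]),
            mixture_id=str(rows["mixture_id"].iloc[0]),
            sown_species=tuple(rows["species_id"]),
            sown_proportion=dict(zip(rows["species_id"], rows["sown_proportion"].astype(float))),
        )
        obs = MixtureObservation(
            plot_id=str(plot_id),
            biomass={sp: float(observed.get((plot_id, sp), 0.0)) for sp in pdesign.sown_species},
        )
        result = partition_plot(obs, pdesign, ref)
        totals.append((result.plot_id, result.S, result.ne, result.ce, result.se))
        per_species.append(result.species_frame())
    totals_df = pd.DataFrame(totals, columns=["plot_id", "S", "NE", "CE", "SE"]).set_index("plot_id")
    species_df = pd.concat(per_species, ignore_index=True) if per_species else pd.DataFrame()
    return totals_df, species_df


def partition_dataset(
    dataset: Dataset,
    ref: MonocultureReference | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition every plot of a dataset; builds the monoculture reference
    from the dataset itself when ``ref`` is not supplied."""
    if ref is None:
        ref = build_monoculture_reference(dataset)
    return partition_table(dataset.design, dataset.biomass, ref)


def signed_sqrt(y):
    """Square-root transform with sign reconstruction: sign(y) * sqrt(|y|).

    Odd and order-preserving; the conventional variance-stabilizing
    transform for biodiversity effects, which can take either sign.
    """
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * np.sqrt(np.abs(y))
    return out if out.ndim else float(out)


def test_effects_positive(
    totals: pd.DataFrame,
    plots: pd.DataFrame,
    *,
    effects: tuple[str, ...] = ("NE", "CE", "SE"),
    transform=signed_sqrt,
    richness_coding: str = "log2",
) -> pd.DataFrame:
    """Test whether the grand mean of each biodiversity effect differs from 0.

    An ANOVA of the (transformed) effect on block + sown richness +
    mixture identity is fitted over the mixture plots (S >= 2), and the
    grand mean is tested against zero with the model's residual mean
    square: F = n * ybar^2 / MS_resid on (1, residual df) degrees of
    freedom.  The residual stratum after mixture identity is used as the
    error term.

    ``plots`` is the per-plot frame of the full dataset (block,
    mixture_id, sown_richness), aligned to ``totals`` by plot id.
    """
    mixtures = totals.loc[totals["S"] >= 2]
    if len(mixtures) < 2:
        raise DesignError("need at least two mixture plots to test biodiversity effects")
    info = plots.loc[mixtures.index]
    X = _anova_design(info, richness_coding)
    n, rank = X.shape[0], int(np.linalg.matrix_rank(X))
    df_resid = n - rank
    if df_resid <= 0:
        raise DesignError(
            "saturated ANOVA (0 residual df); drop terms or add replicate plots"
        )
    records = []
    for effect in effects:
        y = np.asarray(transform(mixtures[effect].to_numpy()), dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        ss_mean = n * float(y.mean()) ** 2
        if ss_mean == 0.0 and rss == 0.0:
            F, p = 0.0, 1.0
        else:
            ms_resid = rss / df_resid
            F = ss_mean / ms_resid if ms_resid > 0 else np.inf
            p = float(stats.f.sf(F, 1, df_resid))
        records.append(
            {
                "effect": effect,
                "grand_mean_transformed": float(y.mean()),
                "F": float(F),
                "df1": 1,
                "df2": df_resid,
                "p": p,
                "error_stratum": "residual",
            }
        )
    return pd.DataFrame.from_records(records).set_index("effect")


def _anova_design(info: pd.DataFrame, richness_coding: str) -> np.ndarray:
    """Design matrix [intercept | block | richness | mixture identity]."""
    n = len(info)
    cols = [np.ones((n, 1))]
    cols.append(pd.get_dummies(info["block"], drop_first=True).to_numpy(dtype=float))
    richness = info["sown_richness"].to_numpy(dtype=float)
    if richness_coding == "log2":
        cols.append(np.log2(richness)[:, None])
    elif richness_coding == "factor":
        cols.append(pd.get_dummies(richness.astype(int), drop_first=True).to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown richness_coding {richness_coding!r}")
    cols.append(pd.get_dummies(info["mixture_id"], drop_first=True).to_numpy(dtype=float))
    return np.hstack([c for c in cols if c.size])
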