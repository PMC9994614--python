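"""Community-weighted means (CWM) and their decomposition into
composition/abundance versus intraspecific-adjustment components.

For a plot with species biomass proportions p_i (over species present at
harvest) and plot-specific trait values t_i,

    CWM_specific = sum_i p_i * t_i.

Replacing t_i by the species' trait value averaged across all plots
(t_bar_i) gives the composition/abundance component,

    CWM_fixed = sum_i p_i * t_bar_i,

whose variation stems only from who is present and how abundant.  The
intraspecific adjustment component is the difference,

    CWM_adjust = CWM_specific - CWM_fixed,

so specific = fixed + adjust holds exactly per plot.

Sequential (Type-I) ANOVAs with the term order block -> species richness
-> mixture identity are fitted to each of the three components, and the
richness sum of squares of each is expressed as a percentage of the TOTAL
sum of squares of CWM_specific, making the three shares commensurable.
The covariation share is then defined by the identity

    specific% = fixed% + adjust% + covariation%

and is negative when the composition/abundance and adjustment components
trend in opposite directions along the richness gradient.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, ValidationError
from .io import Dataset, MixtureObservation

__all__ = [
    "CWMDecomposition",
    "VarianceAttribution",
    "cwm",
    "species_mean_traits",
    "decompose_cwm",
    "attribute_variance",
    "ztransform",
]


@dataclasses.dataclass(frozen=True)
class CWMDecomposition:
    plot_id: str
    trait_name: str
    cwm_specific: float
    cwm_fixed: float
    cwm_adjust: float


@dataclasses.dataclass(frozen=True)
class VarianceAttribution:
    """Richness-explained variance shares (% of the total SS of
    CWM_specific) for the three CWM components."""

    trait_name: str
    ss_total: float
    pct_richness_specific: float
    pct_richness_fixed: float
    pct_richness_adjust: float

    @property
    def pct_richness_covariation(self) -> float:
        return (
            self.pct_richness_specific
            - self.pct_richness_fixed
            - self.pct_richness_adjust
        )


def cwm(
    obs: MixtureObservation,
    trait_values: Mapping[str, float],
    *,
    missing: str = "error",
) -> float:
    """Biomass-weighted community mean of one trait for one plot.

    Weights are the realized biomass proportions among species present at
    harvest (absent species get weight zero).  ``missing`` controls what
    happens when a present species has no trait value: ``"error"`` raises,
    ``"renormalize"`` reweights over the species with values and warns.
    """
    present = {sp: b for sp, b in obs.biomass.items() if b > 0}
    if not present:
        raise ValidationError(
            f"plot {obs.plot_id!r} has zero total biomass; CWM undefined"
        )
    lacking = [sp for sp in present if sp not in trait_values]
    if lacking:
        if missing == "error":
            raise ConfigurationError(
                f"missing trait value for present species {lacking} in plot {obs.plot_id!r}"
            )
        if missing != "renormalize":
            raise ValueError(f"unknown missing policy {missing!r}")
        warnings.warn(
            f"plot {obs.plot_id!r}: renormalizing CWM weights over species "
            f"with trait values (missing: {lacking})",
            stacklevel=2,
        )
        present = {sp: b for sp, b in present.items() if sp in trait_values}
        if not present:
            raise ValidationError(
                f"plot {obs.plot_id!r} has no present species with trait values"
            )
    total = sum(present.values())
    return float(sum(b / total * trait_values[sp] for sp, b in present.items()))


def species_mean_traits(dataset: Dataset) -> pd.DataFrame:
    """Species trait values averaged (unweighted) across all plots where
    the species was measured.  Index: species_id; columns: trait names."""
    rows = dataset.traits.loc[dataset.traits["species_id"].notna()]
    if rows.empty:
        raise ConfigurationError("dataset contains no species-level trait records")
    means = (
        rows.astype({"value": float})
        .groupby(["species_id", "variable"])["value"]
        .mean()
        .unstack("variable")
    )
    return means


def decompose_cwm(
    dataset: Dataset,
    trait_name: str,
    *,
    missing: str = "error",
) -> pd.DataFrame:
    """Per-plot CWM decomposition for one species-level trait.

    Returns a frame indexed by plot_id with columns cwm_specific,
    cwm_fixed, cwm_adjust; plots with zero total biomass are skipped.
    """
    plot_values = dataset.species_trait_values(trait_name)
    means = species_mean_traits(dataset)
    if trait_name not in means.columns:
        raise ConfigurationError(f"no species-level records for trait {trait_name!r}")
    pool_means = means[trait_name].dropna().to_dict()
    records = []
    for plot_id in dataset.plot_ids():
        obs = dataset.observation(plot_id)
        if obs.total_biomass <= 0:
            continue
        specific = cwm(obs, plot_values.get(plot_id, {}), missing=missing)
        fixed = cwm(obs, pool_means, missing=missing)
        records.append(
            CWMDecomposition(
                plot_id=plot_id,
                trait_name=trait_name,
                cwm_specific=specific,
                cwm_fixed=fixed,
                cwm_adjust=specific - fixed,
            )
        )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records]).set_index("plot_id")
    return frame[["cwm_specific", "cwm_fixed", "cwm_adjust"]]


def _sequential_rss(y: np.ndarray, stages: list[np.ndarray]) -> list[float]:
    """Residual sums of squares along a growing sequence of design matrices."""
    rss = []
    X = np.empty((len(y), 0))
    for stage in stages:
        X = np.hstack([X, stage]) if stage.size else X
        if X.shape[1] == 0:
            rss.append(float((y**2).sum()))
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss.append(float(((y - X @ beta) ** 2).sum()))
    return rss


def attribute_variance(
    decomp: pd.DataFrame,
    plots: pd.DataFrame,
    *,
    trait_name: str = "",
    richness_coding: str = "log2",
) -> VarianceAttribution:
    """Sequential sum-of-squares attribution of richness-explained variance.

    For each component (specific, fixed, adjust) an ANOVA with the term
    sequence block -> richness -> mixture identity is fitted and the
    Type-I richness SS is extracted.  Because richness precedes mixture
    identity, the richness SS does not depend on the identity term; the
    identity term only shapes the residual stratum.  ``richness_coding``
    is ``"log2"`` (continuous log2 of sown richness, the default used for
    the linear mixed models as well) or ``"factor"``.

    Percentages are of the total (mean-corrected) SS of cwm_specific.
    """
    info = plots.loc[decomp.index]
    richness = info["sown_richness"].to_numpy(dtype=float)
    if len(np.unique(richness)) < 2:
        raise DesignError("need at least two richness levels for variance attribution")
    n = len(info)
    intercept = np.ones((n, 1))
    block = pd.get_dummies(info["block"], drop_first=True).to_numpy(dtype=float)
    if richness_coding == "log2":
        rich = np.log2(richness)[:, None]
    elif richness_coding == "factor":
        rich = pd.get_dummies(richness.astype(int), drop_first=True).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown richness_coding {richness_coding!r}")
    mixture = pd.get_dummies(info["mixture_id"], drop_first=True).to_numpy(dtype=float)

    base = np.hstack([intercept, block])
    if np.linalg.matrix_rank(np.hstack([base, rich])) <= np.linalg.matrix_rank(base):
        raise DesignError("richness term is aliased with block in this design")

    specific = decomp["cwm_specific"].to_numpy(dtype=float)
    ss_total = float(((specific - specific.mean()) ** 2).sum())
    if ss_total <= 0:
        raise ValidationError("cwm_specific has zero total sum of squares")

    pct = {}
    for component in ("cwm_specific", "cwm_fixed", "cwm_adjust"):
        y = decomp[component].to_numpy(dtype=float)
        rss = _sequential_rss(y, [intercept, block, rich, mixture])
        ss_rich = rss[1] - rss[2]
        pct[component] = 100.0 * ss_rich / ss_total
    return VarianceAttribution(
        trait_name=trait_name or str(decomp.get("trait_name", "")),
        ss_total=ss_total,
        pct_richness_specific=pct["cwm_specific"],
        pct_richness_fixed=pct["cwm_fixed"],
        pct_richness_adjust=pct["cwm_adjust"],
    )


def ztransform(values) -> np.ndarray:
    """Standardize to mean 0 and sample standard deviation 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError("ztransform requires at least two distinct values")
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd
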