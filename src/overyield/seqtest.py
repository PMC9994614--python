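"""Two-order stepwise model comparison: species richness vs. species identity.

Species richness and the presence of particular species are partially
confounded in biodiversity designs (a frequent species is, by
construction, more often present in species-rich plots), so each is
tested in both positions of a stepwise sequence of linear mixed models
with random intercepts for block and mixture identity, fitted by maximum
likelihood:

    model 1:  y ~ richness + identity + (1|block) + (1|mixture)
    model 2:  y ~ identity + richness + (1|block) + (1|mixture)

Each added fixed term is assessed by a 1-df likelihood-ratio test against
the preceding model.  The verdict rules:

* species identity counts as significant only if it is significant in
  BOTH orders (after richness in model 1 and before it in model 2);
* the richness effect counts as "neutralized" when it is at least
  marginally significant when fitted first (model 1) but loses
  significance once fitted after identity (model 2) — evidence that the
  presence of the focal species, not richness per se, carries the effect.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .lmm import fit_lmm_ml

__all__ = ["SequentialTestResult", "fit_model_sequence", "classify_table"]


@dataclasses.dataclass
class SequentialTestResult:
    response_name: str
    focal_species: str
    richness_variable: str
    alpha: float
    marginal_alpha: float
    chi2_richness_model1: float
    p_richness_model1: float
    chi2_identity_model1: float
    p_identity_model1: float
    chi2_identity_model2: float
    p_identity_model2: float
    chi2_richness_model2: float
    p_richness_model2: float
    richness_coef: float
    identity_coef: float

    @property
    def richness_direction(self) -> int:
        return int(np.sign(self.richness_coef))

    @property
    def identity_direction(self) -> int:
        return int(np.sign(self.identity_coef))

    @property
    def species_identity_significant(self) -> bool:
        """Significant in both orderings (the conservative rule)."""
        return (
            self.p_identity_model1 < self.alpha
            and self.p_identity_model2 < self.alpha
        )

    @property
    def richness_significant_model1(self) -> bool:
        return self.p_richness_model1 < self.alpha

    @property
    def richness_marginal_model1(self) -> bool:
        return self.p_richness_model1 < self.marginal_alpha

    @property
    def richness_neutralized(self) -> bool:
        """Richness (at least marginally) significant when fitted first but
        not significant once fitted after species identity."""
        return self.richness_marginal_model1 and self.p_richness_model2 >= self.alpha


def _lrt(ll_full: float, ll_reduced: float) -> tuple[float, float]:
    chi2 = max(0.0, 2.0 * (ll_full - ll_reduced))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def fit_model_sequence(
    response: pd.Series,
    plots: pd.DataFrame,
    focal_species: str,
    *,
    richness: str = "sown",
    richness_coding: str = "log2",
    alpha: float = 0.05,
    marginal_alpha: float = 0.10,
    response_name: str | None = None,
) -> SequentialTestResult:
    """Run the two-order stepwise procedure for one response and one species.

    ``response`` is a per-plot series (the caller applies any transform
    beforehand, e.g. :func:`~overyield.partition.signed_sqrt` for
    biodiversity effects); ``plots`` is a per-plot frame with columns
    block, mixture_id, sown_richness, realized_richness, sown_species.
    ``richness`` selects the sown or realized richness variable;
    ``richness_coding`` is ``"log2"`` (default) or ``"linear"``.
    """
    info = plots.loc[response.index]
    y = response.to_numpy(dtype=float)
    presence = info["sown_species"].map(lambda s: focal_species in s).to_numpy(dtype=float)
    n_present = int(presence.sum())
    if n_present < 2 or len(presence) - n_present < 2:
        raise ConfigurationError(
            f"focal species {focal_species!r} must be present in >=2 and absent "
            f"from >=2 plots (present in {n_present}/{len(presence)})"
        )
    column = {"sown": "sown_richness", "realized": "realized_richness"}.get(richness)
    if column is None:
        raise ValueError(f"unknown richness variable {richness!r}")
    richness_values = info[column].to_numpy(dtype=float)
    if richness_coding == "log2":
        rich = np.log2(np.maximum(richness_values, 1.0))
    elif richness_coding == "linear":
        rich = richness_values
    else:
        raise ValueError(f"unknown richness_coding {richness_coding!r}")

    factors = {"block": info["block"].to_numpy()}
    mixture = info["mixture_id"].to_numpy()
    if pd.Series(mixture).value_counts().max() > 1:
        factors["mixture"] = mixture
    else:
        warnings.warn(
            "every mixture identity has a single plot; dropping the mixture "
            "random factor (confounded with the residual)",
            stacklevel=2,
        )

    n = len(y)
    ones = np.ones((n, 1))
    X_null = ones
    X_r = np.column_stack([ones, rich])
    X_i = np.column_stack([ones, presence])
    X_ri = np.column_stack([ones, rich, presence])

    ll_null = fit_lmm_ml(y, X_null, factors).loglik
    ll_r = fit_lmm_ml(y, X_r, factors).loglik
    ll_i = fit_lmm_ml(y, X_i, factors).loglik
    full = fit_lmm_ml(y, X_ri, factors)
    ll_ri = full.loglik

    chi2_r1, p_r1 = _lrt(ll_r, ll_null)
    chi2_i1, p_i1 = _lrt(ll_ri, ll_r)
    chi2_i2, p_i2 = _lrt(ll_i, ll_null)
    chi2_r2, p_r2 = _lrt(ll_ri, ll_i)

    return SequentialTestResult(
        response_name=response_name or (response.name or "response"),
        focal_species=focal_species,
        richness_variable=richness,
        alpha=alpha,
        marginal_alpha=marginal_alpha,
        chi2_richness_model1=chi2_r1,
        p_richness_model1=p_r1,
        chi2_identity_model1=chi2_i1,
        p_identity_model1=p_i1,
        chi2_identity_model2=chi2_i2,
        p_identity_model2=p_i2,
        chi2_richness_model2=chi2_r2,
        p_richness_model2=p_r2,
        richness_coef=float(full.beta[1]),
        identity_coef=float(full.beta[2]),
    )


def classify_table(results: list[SequentialTestResult]) -> pd.DataFrame:
    """Summarize two-order results across responses and focal species.

    One row per response: the model-1 richness chi2/p (identical across
    focal species of the same response by construction), a +/- cell per
    focal species shown only when identity is significant in both orders,
    and the neutralization verdict ("Yes" when some species' identity
    effect neutralizes the richness effect, "No" when richness stays
    significant, blank when model 1 shows no richness effect at all).
    """
    by_response: dict[str, list[SequentialTestResult]] = {}
    for result in results:
        by_response.setdefault(result.response_name, []).append(result)
    species_order = list(dict.fromkeys(r.focal_species for r in results))
    records = []
    for response_name, group in by_response.items():
        first = group[0]
        record: dict[str, object] = {
            "response": response_name,
            "richness_chi2": first.chi2_richness_model1,
            "richness_p": first.p_richness_model1,
        }
        for species in species_order:
            cell = ""
            for result in group:
                if result.focal_species != species:
                    continue
                if result.species_identity_significant:
                    cell = "+" if result.identity_direction >= 0 else "-"
            record[species] = cell
        if not first.richness_marginal_model1:
            verdict = ""
        elif any(
            r.richness_neutralized and r.species_identity_significant for r in group
        ):
            verdict = "Yes"
        else:
            verdict = "No"
        record["richness_neutralized"] = verdict
        records.append(record)
    return pd.DataFrame.from_records(records).set_index("response")
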