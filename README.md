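# overyield

Analysis toolkit for the question every grassland biodiversity experiment
asks: **do species mixtures produce more biomass than expected from their
monocultures — and why?**  It is written for community ecologists working
with designed sown-diversity experiments (blocks, replicated mixture
identities, a fixed species pool) and covers three linked analyses plus a
simulator of virtual experiments with known ground truth.

## What it computes

**1. Additive partitioning of overyielding (Loreau–Hector).**
For a plot sown with *S* species with monoculture yields *Mᵢ*, observed
mixture yields *Yᵢ* and expected relative yields *RY*ₑ,ᵢ (the sown
proportions), define ΔRYᵢ = *Yᵢ*/*Mᵢ* − *RY*ₑ,ᵢ.  The net biodiversity
effect and its two components are

```
NE = Σᵢ Mᵢ·ΔRYᵢ
SE = Σᵢ (ΔRYᵢ − mean ΔRY)(Mᵢ − mean M)        selection
CE = Σᵢ Mᵢ·ΔRYᵢ − SE                           complementarity
```

so NE = CE + SE exactly.  Effects are tested against zero with an ANOVA
(block + sown richness + mixture identity) after a signed square-root
transform, sign(y)·√|y|.

**2. CWM traits and intraspecific decomposition (Lepš).**
The community-weighted mean of a trait, CWM = Σ pᵢtᵢ with biomass
proportions pᵢ, is split into a composition/abundance part (same weights,
species trait values averaged across all plots) and an intraspecific
adjustment part (the remainder).  Sequential (Type-I) ANOVAs with the
term order block → richness → mixture identity attribute
richness-explained variance to each part; a covariation share (which can
be negative, when composition and adjustment trend oppositely) closes the
identity specific% = fixed% + adjust% + covariation%.

**3. Two-order richness-vs-identity model comparison.**
Species richness and the presence of a particular species are confounded
by design, so each response is fitted by maximum-likelihood linear mixed
models (random intercepts for block and mixture identity) in both
stepwise orders — richness first, identity first — with 1-df
likelihood-ratio tests per added term.  Identity counts only if
significant in *both* orders; a richness effect that dies once identity
is fitted first is flagged **neutralized** (the species, not richness per
se, carries it).

**4. Synthetic dominance-design experiments.**
The generator emulates a 9-species pool (two species extinct, leaving 4
grasses, 1 forb, 2 legumes), richness levels 1/2/6/9 over 85 plots in 4
blocks, a dominant tall grass, tunable complementarity and selection
effects, trait plasticity along the richness gradient, and soil
properties (pH down, organic C, total N, available P/K up) responding to
richness and dominant-species presence — all with exact per-plot ground
truth for recovery tests.

## Worked example

```
$ overyield simulate --seed 7 --out-dir demo/
$ overyield partition --design demo/design.csv --biomass demo/biomass.csv \
    --species demo/species.csv --out demo/partition.csv
wrote demo/partition.csv (85 plots)
        grand_mean_transformed            F  df1  df2             p
effect
NE                    7.725294  1768.775795    1   37  7.631661e-33
CE                    7.108626  2087.988139    1   37  3.751101e-34
SE                    2.038128    56.649811    1   37  5.700431e-09
```

All three biodiversity effects are positive across mixtures (grand means
on the signed-√ scale, tested against the residual mean square on 1 and
37 df): the virtual communities overyield, mostly through
complementarity, with a smaller selection component.

```
$ overyield decompose --design demo/design.csv --biomass demo/biomass.csv \
    --species demo/species.csv --traits demo/traits.csv \
    --trait plant_height --out demo/attr.csv
trait_name,ss_total,pct_richness_specific,pct_richness_fixed,pct_richness_adjust,pct_richness_covariation
plant_height,8418.93,12.25,7.41,0.60,4.23
```

Richness explains 12.2% of the variance in CWM plant height: 7.4 points
come from composition/abundance (tall dominant more frequent and heavier
in species-rich plots), 0.6 from individuals growing taller in mixtures,
and 4.2 from the positive covariation of the two.

```
$ overyield seqtest --design demo/design.csv --biomass demo/biomass.csv \
    --species demo/species.csv --response NE --focal Arr.ela --focal Poa.tri \
    --out demo/seq.csv
          richness_chi2  richness_p Arr.ela Poa.tri richness_neutralized
response
NE             3.962889    0.046514       +                          Yes
```

At this seed, the richness effect on NE (χ² = 3.96, p = 0.047 with
richness fitted first) disappears once the dominant grass's presence is
fitted first, while the identity effect survives both orders —
the classic neutralization verdict.

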