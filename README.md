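# rootdepth

Inverse estimation of tree **effective rooting depth (ERD)** from diameter
growth, leaf hydraulics and modelled soil water potential.

Field measurements of rooting depth are nearly impossible for large
tropical trees, yet rooting depth controls which trees die in droughts.
This package implements a desk-scale version of an inverse approach: the
depth whose soil-water-potential dynamics best explain a species'
multi-year diameter-growth dynamics is taken as that species' effective
rooting depth — a central tendency of water uptake, not a maximum rooting
depth. It is written for plant ecophysiologists and ecohydrologists who
want to run, test or extend the method without access to the original
field data: every stage has a seeded synthetic forward model, so the whole
pipeline is exercisable and testable offline.

## The model

Leaf hydraulic conductance declines exponentially with water potential
(the vulnerability curve):

    K_leaf(ψ) = A e^(−B|ψ|),     FLC(ψ) = K_leaf(ψ) / K_max = e^(−B|ψ|)

with species parameters A (conductance scale) and B (decline rate,
MPa⁻¹), fitted from (ψ, K) measurements or predicted from wood specific
gravity (WSG) and leaf mass per area (LMA) via empirical polynomial
proxies. Pre-dawn ψ_leaf tracks ψ_soil, so FLC evaluated on ψ_soil at
depth *z* approximates the stomatal limitation a tree rooted at *z*
experiences.

Species growth per census interval *t* is regressed on the interval mean
of the daily product of standardized FLC and a standardized GPP-proxy
transform of vapour pressure deficit (VPD̂):

    G_{s,t|z} = β₀ + β₁ · (1/n_t) Σᵢ FLC*_{s,i|z} · VPD̂*ᵢ + ε

evaluated at every candidate soil layer *z* of a 13-node column
(0.01–13 m). Per hydrological realization the best depth maximizes R²;
species ERD is the median of best-fit depths across the calibrated
ensemble of realizations, with a standard error from their spread.

The water-potential field ψ_soil(z, t) comes from a 9-parameter layered
daily water balance (Campbell retention and conductivity, exponential
root-extraction profile, donor/receiver-limited drainage cascade),
calibrated by Latin-Hypercube sampling against observation streams with
an equally weighted standardized-RMSE objective. Downstream analyses
flag hydrological droughts (days beyond the 5th percentile of the
day-of-year ψ climatology), compute mortality rates
M = (D/N)·(100/d) % yr⁻¹, species exposure (% of days with ψ at the ERD
layer more negative than Ψ₂₀, the potential at 20% conductance loss),
and ERD–trait and ERD–mortality associations.

## Worked example

Generate a small synthetic community with known rooting depths, run the
inversion against its hydrological ensemble, and compare:

```python
from rootdepth import SyntheticConfig, generate_world, estimate_community_erd

config = SyntheticConfig(n_species=6, n_years=25, n_realizations=8, seed=42,
                         true_layer_indices=(5, 6, 7, 8, 9, 10))
world = generate_world(config)
erd, fits = estimate_community_erd(
    world.growth, world.curves, world.psi_ensemble,
    world.vpd_hat_star, world.intervals, world.grid.z,
)
print(erd.merge(world.species[["species", "true_erd_m"]], on="species")
         .to_string(index=False))
```

```
species  erd_m     se_m  n_realizations  true_erd_m
   sp00   0.21 0.030237               8        0.37
   sp01   0.62 0.197620               8        0.62
   sp02   1.00 0.462500               8        1.00
   sp03   1.70 0.000000               8        1.70
   sp04   2.90 0.150000               8        2.90
   sp05   4.70 0.507357               8        4.70
```

`erd_m` is the median best-fit depth (m) across the 8 hydrological
realizations and `se_m` its standard error. Five of six species are
recovered exactly at default growth noise (25% of the growth-signal SD);
the shallowest is misplaced by one layer — shallow layers are the most
confusable because adjacent thin layers wet and dry almost together.
`fits` holds the full per-(species, realization, depth) regression
diagnostics behind these medians.

A thin CLI covers the shell-facing stages (`rootdepth synth`,
`rootdepth droughts`, `rootdepth erd`, `rootdepth mortality`); see
`rootdepth --help`.

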