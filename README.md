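# hybridfba

Constraint-based metabolic flux prediction that couples a stoichiometric
model with the empirical correlation structure of measured exchange fluxes.

Standard flux balance analysis (FBA) computes steady-state fluxes `v` of a
genome-scale metabolic model by linear programming,

```
max c_vᵀ v     s.t.   S_int v = 0,   LB ≤ v ≤ UB,   r_exch = S_ext v
```

but its solution intervals are typically far wider than the biological
variability actually observed, because the stoichiometric constraints say
nothing about regulation. `hybridfba` adds a *nonparametric* constraint
block learned from data: exchange-rate measurements from repeated
cultivations (experiments × species) are auto-scaled and decomposed by PCA,
`r̄ = Scores·Coeffᵀ`, and the mechanistic exchange rates are then required
to stay inside a band around the PCA reconstruction,

```
µ − RF·σ  ≤  S_ext v − (σ ∘ Coeff[:, :NPC]) s  ≤  µ + RF·σ
```

with `s` the component scores (extra decision variables), `µ, σ` the
autoscaling vectors, `NPC` the number of retained components and `RF` the
relaxation factor in per-species SD units. `NPC = 0` removes the block and
recovers plain FBA; `RF → ∞` relaxes it to inactivity. Because the band
adds one two-sided constraint per measured species but only `NPC`
variables, the hybrid LP has `n_species − NPC` fewer degrees of freedom
than FBA. Optional box constraints `r_mean ± k·σ` on selected species
define test scenarios, and the usual analysis toolkit operates on the same
LP: min–max objective intervals, flux variability analysis under an
objective tolerance band, shadow prices from the LP multipliers, and
subsystem activities. A feed-design module converts a flux solution into a
feed recipe `C_F = c_Glc · r/r_Glc` and a feedforward controller
`F = a·X_V·V`, with an in-silico fed-batch simulator to evaluate it.

The package is aimed at bioprocess modellers working with CHO (or similar)
fed-batch cultures who have a metabolic reconstruction and a historical set
of exponential-phase exchange-rate estimates, and want predictions — and
feeds designed from them — that respect both.

Modules: `gem_io` (SBML/COBRA-JSON models, medium-specific reduction),
`rates` (specific-rate estimation from fed-batch time series, including the
abiotic glutamine-decomposition correction), `fluxpca` (autoscaling, SVD
PCA, component selection), `hybridcore` (the hybrid LP and its analyses),
`feed_design`, and `synthetic` (fixtures with known ground truth).

## Worked example

```python
import hybridfba as h
from hybridfba.hybridcore import build_problem, minmax_interval, standard_scenarios

model = h.make_toy_gem("cho-mini-27")          # 27 reactions, 27 species
ds, truth = h.simulate_flux_dataset(model, h.SyntheticSpec(seed=1))
pca = h.fit_pca(ds)
print(h.select_npc(pca, 0.90))                  # -> 4

stats = h.dataset_statistics(ds)                # mean / SD / CV per species
case7 = standard_scenarios(stats["mean"])[6]    # only Glc and Gln bounded, ±1σ

fba = minmax_interval(build_problem(model, scenario=case7,
                                    r_mean=stats["mean"], sigma=stats["sd"],
                                    objective="biomass"))
hyb = minmax_interval(build_problem(model, pca=pca, npc=4, rf=1.0,
                                    scenario=case7, r_mean=stats["mean"],
                                    sigma=stats["sd"], objective="biomass"))
print(f"FBA    [{fba.j_min:.3f}, {fba.j_max:.3f}]  half {fba.half_interval:.3f}")
print(f"hybrid [{hyb.j_min:.3f}, {hyb.j_max:.3f}]  half {hyb.half_interval:.3f}")
print(f"true growth {truth['base_growth']:.3f}, observed SD {stats['sd']['mu']:.3f}")
```

prints

```
4
FBA    [0.000, 1.837]  half 0.918
hybrid [0.354, 0.902]  half 0.628
true growth 0.629, observed SD 0.066
```

The dataset was generated with four latent directions of variation; the
90%-explained-variance rule recovers NPC = 4. With only glucose and
glutamine constrained, the plain-FBA growth interval spans from washout to
nearly three times the true rate and its half-interval over-predicts by
more than 4 SD, while the hybrid half-interval lands within 0.02 SD of the
generating growth rate (0.629 in this toy's flux units).

The same steps are available from the shell:

```
hybridfba synth --topology cho-mini-27 --n 21 --latent 4 --seed 7 --out fixtures/
hybridfba pca --rates fixtures/dataset.csv --threshold 0.90 --out pca.json
hybridfba solve --model fixtures/model.json --pca pca.json --npc 4 --rf 1.0 \
    --scenario case6.yaml --objective biomass --out solution.json
hybridfba feed --solution solution.json --cglc 2.0 --out feed.csv
```

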