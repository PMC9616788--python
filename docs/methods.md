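# Methods

## Model representation

A metabolic model is held as the linear system `0 = S_int v`,
`LB ≤ v ≤ UB`, `r_exch = S_ext v`. Intracellular metabolites are balanced
(rows of `S_int`); extracellular species are *unbalanced* and their net
production is the exchange-rate vector `r_exch` (uptake negative, secretion
positive — matching the sign convention of the bundled CHO-K1 summary
table, where the mean glucose flux is −0.384 mmol·gDW⁻¹·h⁻¹). Units are
mmol·gDW⁻¹·h⁻¹ throughout, with the biomass flux in h⁻¹; the two coexist
in one vector and no internal conversion is applied.

Models loaded through cobrapy that carry explicit boundary reactions are
normalised on load: the metabolites of boundary reactions become the
extracellular block and the boundary reactions are dropped. At steady state
the flux of an exchange reaction equals the net stoichiometric production of
its metabolite, so this is an exact equivalence, not an approximation.
Reversibility is encoded purely in the bounds; an SBML reversibility flag
that contradicts the bounds is overridden (bounds win) and recorded in the
model's notes.

### Medium-specific reduction

`reduce_to_medium` closes every exchange species not listed in the medium
by moving its `S_ext` row into the balance block (net exchange forced to
zero — algebraically identical to clamping an exchange reaction to
`[0, 0]`). Reactions whose flux range under the closed medium is `[0, 0]`
within `1e-9` (per-reaction min/max LP) are removed, as are metabolites
left without reactions. Closed species that still participate in surviving
reactions remain as internal balance rows. The caller must list *all*
species allowed to cross the boundary — substrates, secreted products and
the growth pseudo-species alike; omitting an essential one blocks the
biomass reaction and raises. Only exchange-closure plus consistency pruning
is performed; no lumping or pooling of reactions is attempted.

### Degrees of freedom and measurement validation

The degrees of freedom are `n_reactions − rank(S_int)` with numpy's
SVD-based rank (default tolerance `max(dim)·eps·σ_max`).
`validate_against_measurements` fits
`min ‖S_ext v − r_measured‖²` subject to the balances and bounds — a convex
QP with linear equality and box constraints, solved by SLSQP from an
LP-feasible start (no dedicated QP solver with equality support is a
package dependency; at the model sizes this package targets SLSQP converges
reliably, and the LP start is returned if it ever scores better). A
near-zero SSR certifies that the measured rates are stoichiometrically
attainable; the largest residual names the inconsistent species.

## Specific-rate estimation

A specific rate is the slope of cumulative formed quantity (mmol) against
the integral of viable cell mass, IVC (gDW·h), both computed by cumulative
trapezoids from sampled (time, VCD, volume, concentration) data. Formed
quantities subtract bolus feed additions, so the series is continuous
across feeding events. The growth rate is the slope of biomass (gDW)
against IVC, which equals µ exactly under exponential growth and makes µ
independent of the dry-weight conversion.

Tunable parameters:

- **Dry weight per cell** (`dw_pg`, default 250 pg·cell⁻¹). This converts
  Mcell-based cell counts into gDW and *linearly scales every metabolite
  rate* (not µ); it is the single most important calibration input when
  absolute fluxes matter and should be set from a measured correlation.
- **Estimation window** (default the full course; the shipped CLI default
  is 0–70 h, the exponential phase of a typical fed-batch).
- **Glutamine decomposition constant** `k_d` (h⁻¹, default 0 = no
  correction). Glutamine decomposes abiotically with first-order kinetics
  into equimolar pyrrolidone carboxylate and ammonium. The correction adds
  the integrated abiotic loss `∫k_d·C_Gln·V dt` back to the Gln
  formed-quantity series and subtracts it from the NH4 series; the two
  corrections cancel exactly at every time point, conserving mass. The
  constant is medium- and pH-dependent and must be supplied by the user.
- **Regression method**: iteratively reweighted least squares with Tukey
  bisquare weights, tuning constant 4.685 (the conventional 95%-efficiency
  value), via statsmodels RLM; plain OLS is available. Both fit an
  intercept; the slope is the rate.

## Flux PCA

Datasets are auto-scaled column-wise to zero mean and unit *sample*
(n−1) variance; a zero-variance column is an error (it cannot be scaled and
carries no correlation information). The SVD of the scaled matrix gives
orthonormal loadings, scores and explained-variance fractions; all
`min(n−1, p)` components are retained in the `PCAModel` and truncation to
NPC happens when the LP is assembled. Component signs follow a fixed
convention (largest-magnitude loading positive) so results are reproducible
across platforms; the LP itself is sign-agnostic. `select_npc` returns the
smallest NPC whose cumulative explained variance reaches the threshold
(default 90%). Missing values are rejected rather than imputed.

## The hybrid LP

The decision vector is `[v; s]` with `s` the NPC retained scores.
Constraint blocks, exactly as assembled in `HybridProblem.arrays()`:

- mass balances `[S_int, 0]·x = 0` and flux bounds;
- per measured species one two-sided PCA band
  `µ_i − RF·σ_i ≤ (S_ext v)_i − σ_i·Coeff[i, :NPC]·s ≤ µ_i + RF·σ_i`,
  i.e. the mechanistic and PCA-reconstructed exchange rates must agree to
  within RF per-species SDs (at any feasible point the mismatch ε satisfies
  `|ε_i|/σ_i ≤ RF`, which `pca_band_slack` verifies);
- score bounds, defaulting to ±3 training-score SDs per component
  (`score_bound_mult=3`). These bounds are a modelling choice: wide bounds
  recover the unbounded case, and the RF→∞ limit test uses
  `score_bound_mult=1e6` for exactly that reason;
- optional measured-rate boxes `r_mean ± k·σ` for the species in the
  scenario's `bound_mask`, plus explicit fixed `[lo, hi]` overrides (used
  e.g. to pin growth in feed-design runs).

`Scenario` objects make the standard eight-case suite declarative: cases
1–5 bound every species except growth at k = 1, 2, 3, 4, 6; case 6 bounds
the substrates only (negative mean rate); cases 7–8 bound only glucose and
glutamine at k = 1 and 3.

LPs are solved with HiGHS dual simplex (`scipy.optimize.linprog`,
feasibility tolerances 1e-9). Maximisation negates the objective
internally; multipliers are re-signed so every reported shadow price is
dJ/d(outward relaxation of that constraint by one unit) for the stated
sense, pinned by a finite-difference test. Infeasible problems are
diagnosed by re-solving with one constraint group relaxed at a time (PCA
band, score bounds, exchange boxes) and reporting which relaxation restores
feasibility.

Structural facts used as test invariants: the feasible set is nested in RF
(the optimum is monotone and converges to standard FBA), nested under added
PCA constraints (the hybrid min–max interval is contained in the FBA
interval), and adding a score variable can only enlarge the feasible set,
so the max-growth prediction is monotone non-decreasing in NPC. Each band
is one two-sided constraint per measured species against NPC new variables,
so the hybrid LP has `n_species − NPC` fewer degrees of freedom than FBA
(27 − NPC on the 27-species fixture).

### Min–max intervals, FVA, degeneracy

Point predictions use the half-interval value: the midpoint of the min–max
objective interval. FVA adds the objective band
`[min((1−tol)J, (1+tol)J), max(...)]` — endpoints ordered by value, since
a fixed factor ordering breaks for negative optima (byproduct-minimisation
objectives are negative when byproducts are consumed) — and computes
per-reaction extrema; a numerically infeasible band is widened once by
`1e-9·max(1, |J|)` before erroring. Alternate optima are inherent to LP;
`solve` returns the solver's vertex and `check_degeneracy` flags nonzero
FVA ranges at `tol=0`. No lexicographic or parsimonious tie-break is
applied.

### Calibration

`calibrate` is two-stage: (1) at a fixed small RF, pick the NPC on the grid
whose maximisation optimum is closest to the reference value (ties toward
smaller NPC; infeasible points skipped); (2) scan the RF grid upward and
return the smallest RF for which every scenario in the suite is feasible at
the chosen NPC. The prediction is the maximisation optimum (the
half-interval variant is available through `minmax_interval`). Because the
prediction is monotone in NPC, the reference must exceed the low-NPC
plateau for the argmin to select an interior NPC; with the synthetic
fixture the natural reference is the generating envelope's maximum
supported growth (see below), which the prediction staircase reaches
exactly at the true latent dimension and overshoots by ~RF·σ thereafter.

### Sensitivities

`biomass_sensitivity` multiplies every nonzero biomass stoichiometric
coefficient by an independent lognormal factor (stated relative SD, fixed
seed), re-solves, and reports the objective and per-flux spreads over the
feasible draws; the perturbation→0 limit leaves the problem unchanged.
`subsystem_activity` sums `|v_r|` per annotated subsystem ("unassigned" for
unlabelled reactions) and reports deltas against a reference flux vector —
by convention the FVA half-interval fluxes.

## Feed design

`design_feed` turns an exchange-rate vector into a feed: concentrations
relative to glucose, `C_F,i = c_Glc·r_i/r_Glc`, for the consumed species
(secreted species are excluded with a note; an explicit exclude list lets
users keep species such as lactate or pyruvate out of a feed even when the
design predicts their consumption). If solubility limits are given, every
concentration must stay below 75% of its limit, otherwise `c_Glc` is scaled
down until the binding compound sits exactly at the cap. The feedforward
controller is `F = a·X_V·V` with `a = r_Glc/c_Glc` expressed per Mcell; the
dry-weight factor that bridges gDW-based fluxes and Mcell-based counts is
applied in exactly this one place. The identity `F·C_F,i = r_i·X·V` then
holds algebraically for every fed species, so in a closed-loop simulation
substrate *amounts* are conserved exactly (concentrations drift only by
feed-volume dilution).

`simulate_fedbatch` integrates `dV/dt = F`, `d(X_V V)/dt = µ·X_V·V`,
`d(C_i V)/dt = r_i·X_dw·V + F·C_F,i` with classical fixed-step RK4
(default 0.05 h); halving `dt` and comparing trajectories is the intended
convergence check and is exercised in the tests. A daily-bolus mode
accumulates the controller's demand and delivers it at a fixed interval. A
concentration reaching zero raises a `DepletionEvent` carrying the
truncated trajectory — depletion is reported, never silently clipped.

## Synthetic fixtures

The generators exist to test the mathematics with known ground truth; they
do not model CHO kinetics (no Monod terms, no inhibition, no death phase).

**Toy networks.** `linear` (unique flux distribution once one exchange is
fixed), `branched` (one free split that biomass maximisation drives to its
bound), `cho-mini` (7 reactions: glycolysis producing 2 pyruvate per
glucose, reversible lactate and pyruvate exchange, a TCA proxy, glutamine
transport and glutaminolysis, and a biomass reaction consuming 3 PYR +
0.2 GLN — closed-form maximal growth `min((2b+q)/3.2, 5q)` under uptake
caps b, q with lactate/pyruvate uptake closed), and `cho-mini-27`, which
adds 20 amino-acid-like uptake reactions with fixed stoichiometry to reach
27 reactions and 27 exchange species, so the `27 − NPC` freedom arithmetic
of the full-scale problem is reproduced exactly.

**Flux datasets.** The default fixture is 21 experiments × 27 species with
four latent directions and 5% multiplicative rate noise. The construction
is designed so the latent dimension is *identifiable*:

- the base state `v0` is a scaled Chebyshev centre of the flux polytope
  (strictly interior, so perturbations remain feasible);
- latent coordinates use a sample-orthogonal design (QR of a centred
  Gaussian matrix, rescaled to zero mean and exactly unit sample variance),
  eliminating the ~1/√21 chance correlations an iid draw would inject;
- three "metabolic variation" components live in the achievable,
  biomass-free subspace (null space of `S_int` stacked with the
  biomass-flux selector), so their growth loadings are exactly zero; they
  are built orthogonal *in the autoscaled metric* and their per-species
  energies are balanced by alternating projections, so the PCA recovers
  them without rotation and the explained-variance budget is hit
  deterministically;
- the growth component is the most parsimonious flux re-allocation
  achieving a 10% relative growth swing (minimal weighted side-loadings
  subject to the biomass swing), blended with a small uniform productivity
  component (`growth_side = 0.03`) that lifts its eigenvalue clear of the
  noise floor. Growth being the least process-sensitive descriptor mirrors
  what CHO campaign data show; its measurement noise is 1% (µ is estimated
  from the whole VCD profile, metabolite rates from single assays);
- with `signal_cv = 0.17` the cumulative explained variance lands at
  ≈ 0.87 for three components and ≈ 0.95 for four, placing the 90%
  threshold mid-gap; over 40 seeds the selection returned 4 every time.

The truth dict records the base rates, flux-space directions, achieved
exchange loadings, latent coordinates, and `max_supported_growth` — the
growth of the most productive state the generating envelope supports
(base + 3·Σ|growth loadings|), which is the natural calibration reference
for a maximisation prediction. Samples that would leave the flux box shrink
all amplitudes by a common recorded factor rather than clipping
individually, preserving the orthogonal design. What passing these tests
does *not* show: that real campaign data have exact low-rank structure,
sample-orthogonal variation, or species-proportional noise — on real data
NPC selection and calibration should be treated as diagnostics, not
oracles.

**Time courses.** Exponential growth at the true µ, concentrations
integrated by RK4 on a 0.01 h grid from the true specific rates (defaults
taken from published exponential-phase CHO magnitudes: µ = 0.0282 h⁻¹,
glucose −0.384, lactate 0.256, glutamine −0.0737, ammonium
0.0592 mmol·gDW⁻¹·h⁻¹), optional daily boluses, optional first-order
glutamine decay with equimolar ammonium production, optional measurement
noise. Sampling every 6 h over 0–72 h keeps the trapezoidal IVC bias
(≈ (µΔt)²/12 ≈ 0.2%) below the 0.5% noise-free recovery requirement the
tests impose. A concentration heading negative shortens the horizon and
records the truncation.

## Numerical choices

- LP: HiGHS dual simplex, primal/dual feasibility 1e-9.
- Blocked-reaction tolerance in reduction: |flux| < 1e-9.
- Rank tolerance: numpy default unless overridden.
- FVA band: endpoints ordered by value; one epsilon-widening retry.
- PCA: full SVD (deterministic), sample-SD scaling, fixed sign convention.
- All generators are pure functions of (spec, seed); every stochastic test
  is seeded.

## Known limitations

- `validate_against_measurements` relies on SLSQP and is not intended for
  full genome-scale models (hundreds of reactions are fine; thousands may
  need a dedicated QP solver).
- Alternate LP optima make individual flux values non-unique; only
  objective values, intervals and FVA ranges are stable deliverables.
- The medium-reduction procedure implements exchange-closure and
  consistency pruning only; published reduced models built with additional
  lumping steps will not be reproduced reaction-for-reaction.
- The feed controller is feedforward: it tracks VCD but does not correct
  concentration deviations, so model-plant mismatch accumulates in the
  simulated concentrations exactly as it would in a reactor.
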