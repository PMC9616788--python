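"""Assembly and analysis of the hybrid semi-parametric FBA linear program.

The decision vector is the concatenation of the metabolic fluxes ``v`` and
the principal-component scores ``s`` (NPC of them).  The LP is

    min/max  J = c_vᵀ v + c_scoresᵀ s

subject to
  (a) mechanistic constraints:    S_int v = 0,   LB_v ≤ v ≤ UB_v
  (b) empirical (PCA) constraints, one band per measured species:
          mu − RF·sigma ≤ S_ext v − (sigma ∘ Coeff[:, :NPC]) s ≤ mu + RF·sigma
      together with score bounds LB_s ≤ s ≤ UB_s
  (c) measured exchange-rate bounds for selected species:
          r_mean − k·σ ≤ S_ext v ≤ r_mean + k·σ

``mu``/``sigma`` are the autoscaling vectors of the flux PCA; ∘ is the
row-wise (Hadamard) product scaling each species' loadings by its SD.  NPC=0
removes block (b) entirely and recovers standard FBA; RF → ∞ relaxes the PCA
bands to inactivity, so the hybrid optimum converges to the FBA optimum.
Each PCA band adds one two-sided constraint per measured species while only
NPC score variables are added, so the hybrid LP has (n_species − NPC) fewer
degrees of freedom than standard FBA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._lp import solve_lp
from .fluxpca import PCAModel
from .gem_io import GEMModel

__all__ = [
    "Scenario", "HybridProblem", "HybridSolution", "MinMax",
    "CalibrationResult", "CalibrationError",
    "standard_scenarios", "build_problem", "solve", "minmax_interval",
    "calibrate", "fva", "shadow_prices", "subsystem_activity",
    "biomass_sensitivity", "exchange_objective",
]


class CalibrationError(RuntimeError):
    """No (NPC, RF) pair on the grid yields a feasible scenario suite."""


@dataclass
class Scenario:
    """Which measured species receive r_mean ± k·σ bounds, and with what k.

    ``k`` may be a scalar or a per-species mapping; ``fixed`` adds explicit
    [lo, hi] exchange bounds that override the k·σ rule (used e.g. to pin the
    growth rate in feed-design runs).
    """

    name: str
    bounded_species: list[str]
    k: float | dict = 1.0
    fixed: dict = field(default_factory=dict)

    def k_for(self, species: str) -> float:
        if isinstance(self.k, dict):
            return float(self.k[species])
        return float(self.k)


def standard_scenarios(r_mean: pd.Series, growth: str = "mu",
                       glc: str = "Glc", gln: str = "Gln") -> list[Scenario]:
    """The eight-case test suite used to probe predictive power.

    Cases 1–5: every measured species except growth bounded at k = 1, 2, 3,
    4, 6.  Case 6: substrates only (species with negative mean rate) at k=1.
    Cases 7–8: only glucose and glutamine, at k=1 and k=3.
    """
    species = list(r_mean.index)
    non_growth = [s for s in species if s != growth]
    substrates = [s for s in non_growth if r_mean[s] < 0]
    for sp in (glc, gln):
        if sp not in species:
            raise KeyError(f"species {sp!r} needed for cases 7/8 not in data")
    return [
        Scenario("case1", non_growth, 1.0),
        Scenario("case2", non_growth, 2.0),
        Scenario("case3", non_growth, 3.0),
        Scenario("case4", non_growth, 4.0),
        Scenario("case5", non_growth, 6.0),
        Scenario("case6", substrates, 1.0),
        Scenario("case7", [glc, gln], 1.0),
        Scenario("case8", [glc, gln], 3.0),
    ]


def exchange_objective(model: GEMModel, weights: dict) -> np.ndarray:
    """c_v that scores the weighted sum of exchange rates Σ w_i·r_exch,i."""
    c = np.zeros(model.n_reactions)
    for sp, w in weights.items():
        c += w * model.S_ext[model.species_index(sp)]
    return c


def _objective_vector(model: GEMModel, objective) -> np.ndarray:
    if objective is None:
        if model.biomass_rxn is None:
            raise ValueError("no objective given and model has no biomass reaction")
        objective = model.biomass_rxn
    if isinstance(objective, str):
        c = np.zeros(model.n_reactions)
        c[model.reaction_index(objective)] = 1.0
        return c
    if isinstance(objective, dict):
        c = np.zeros(model.n_reactions)
        for rid, w in objective.items():
            c[model.reaction_index(rid)] = w
        return c
    c = np.asarray(objective, dtype=float)
    if len(c) != model.n_reactions:
        raise ValueError("objective vector length mismatch")
    return c


@dataclass
class HybridProblem:
    """A fully specified hybrid LP; constraint matrices are assembled lazily."""

    model: GEMModel
    pca: PCAModel | None
    npc: int
    rf: float
    r_mean: pd.Series | None          # measured mean exchange rates (Eq-5 block)
    sigma: pd.Series | None           # measured exchange-rate SDs
    bound_mask: list[str]             # species receiving r_mean ± kσ rows
    k: float | dict
    c_v: np.ndarray
    c_scores: np.ndarray
    lb_scores: np.ndarray
    ub_scores: np.ndarray
    fixed_exchange: dict = field(default_factory=dict)

    # -- dimensions --------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return self.model.n_reactions + self.npc

    @property
    def pca_species(self) -> list[str]:
        return self.pca.species if self.pca is not None and self.npc > 0 else []

    def with_model(self, model: GEMModel) -> "HybridProblem":
        return replace(self, model=model)

    def with_objective(self, objective, c_scores=None) -> "HybridProblem":
        return replace(self, c_v=_objective_vector(self.model, objective),
                       c_scores=np.zeros(self.npc) if c_scores is None
                       else np.asarray(c_scores, float))

    # -- LP materialisation ------------------------------------------------
    def arrays(self):
        """Return (c, A_eq, b_eq, A_ub, b_ub, bounds, row_labels).

        Two-sided constraint bands are stacked as paired ≤ rows; row labels
        are (group, name, side) with group in {"pca", "exchange"}.
        """
        m = self.model
        n, p = m.n_reactions, self.npc
        A_eq = np.hstack([m.S_int, np.zeros((m.S_int.shape[0], p))])
        b_eq = np.zeros(A_eq.shape[0])

        rows, rhs, labels = [], [], []
        if p > 0:
            coeff = self.pca.coeff.to_numpy()[:, :p]
            sig = self.pca.sigma.to_numpy()
            mu = self.pca.mu.to_numpy()
            for i, sp in enumerate(self.pca.species):
                a = np.concatenate([m.S_ext[m.species_index(sp)],
                                    -sig[i] * coeff[i]])
                rows.append(a)
                rhs.append(mu[i] + self.rf * sig[i])
                labels.append(("pca", sp, "upper"))
                rows.append(-a)
                rhs.append(-(mu[i] - self.rf * sig[i]))
                labels.append(("pca", sp, "lower"))

        for sp, lo, hi in self._exchange_bounds():
            a = np.concatenate([m.S_ext[m.species_index(sp)], np.zeros(p)])
            if np.isfinite(hi):
                rows.append(a)
                rhs.append(hi)
                labels.append(("exchange", sp, "upper"))
            if np.isfinite(lo):
                rows.append(-a)
                rhs.append(-lo)
                labels.append(("exchange", sp, "lower"))

        A_ub = np.array(rows) if rows else None
        b_ub = np.array(rhs) if rows else None
        bounds = list(zip(m.lb, m.ub)) + list(zip(self.lb_scores, self.ub_scores))
        c = np.concatenate([self.c_v, self.c_scores])
        return c, A_eq, b_eq, A_ub, b_ub, bounds, labels

    def _exchange_bounds(self):
        out = []
        for sp in self.bound_mask:
            if sp in self.fixed_exchange:
                continue
            kk = self.k[sp] if isinstance(self.k, dict) else self.k
            mean, sd = float(self.r_mean[sp]), float(self.sigma[sp])
            out.append((sp, mean - kk * sd, mean + kk * sd))
        for sp, (lo, hi) in self.fixed_exchange.items():
            out.append((sp, lo, hi))
        return out


def build_problem(model: GEMModel, pca: PCAModel | None = None, npc: int = 0,
                  rf: float = 1.0, k: float | dict = 1.0,
                  r_mean: pd.Series | None = None,
                  sigma: pd.Series | None = None,
                  bound_mask=None, objective=None, c_scores=None,
                  scenario: Scenario | None = None,
                  score_bound_mult: float = 3.0,
                  lb_scores=None, ub_scores=None) -> HybridProblem:
    """Assemble a :class:`HybridProblem`.

    With ``npc=0`` no PCA rows or score variables exist and the problem is
    standard FBA.  ``scenario`` is a shorthand that fills ``bound_mask``,
    ``k`` and fixed exchange bounds.  Score bounds default to
    ±``score_bound_mult`` × the training-score SD per component (wide bounds
    recover the unbounded case).
    """
    if npc < 0:
        raise ValueError("npc must be >= 0")
    if rf < 0:
        raise ValueError("relaxation factor must be >= 0")
    if npc > 0:
        if pca is None:
            raise ValueError("npc > 0 requires a fitted PCA model")
        if npc > pca.n_components:
            raise ValueError(f"npc={npc} exceeds available components "
                             f"({pca.n_components})")
        missing = [s for s in pca.species if s not in model.exchange_species]
        if missing:
            raise ValueError(f"PCA species not in model exchanges: {missing}")

    fixed = {}
    if scenario is not None:
        bound_mask = list(scenario.bounded_species)
        k = scenario.k
        fixed = dict(scenario.fixed)
    bound_mask = [] if bound_mask is None else list(bound_mask)
    if bound_mask or fixed:
        if r_mean is None or sigma is None:
            if bound_mask:
                raise ValueError("exchange bounds need r_mean and sigma")
    for sp in list(bound_mask) + list(fixed):
        model.species_index(sp)   # raises with the offending name

    if npc > 0:
        sd = pca.score_stats["sd"].to_numpy()[:npc]
        lo = -score_bound_mult * sd if lb_scores is None else np.asarray(lb_scores, float)
        hi = score_bound_mult * sd if ub_scores is None else np.asarray(ub_scores, float)
    else:
        lo = hi = np.zeros(0)

    return HybridProblem(
        model=model, pca=pca, npc=npc, rf=float(rf), r_mean=r_mean,
        sigma=sigma, bound_mask=bound_mask, k=k,
        c_v=_objective_vector(model, objective),
        c_scores=np.zeros(npc) if c_scores is None else np.asarray(c_scores, float),
        lb_scores=lo, ub_scores=hi, fixed_exchange=fixed)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class HybridSolution:
    """Optimum of a hybrid LP with named Lagrange multipliers.

    Multiplier convention: each price is dJ/d(outward relaxation of that
    constraint by one unit), for the objective in its stated sense.
    Non-binding inequality constraints carry a zero multiplier.
    """

    v: pd.Series
    scores: pd.Series
    J: float
    status: str
    sense: str
    r_exch: pd.Series
    multipliers: pd.DataFrame
    degenerate: bool | None = None
    message: str = ""


def solve(problem: HybridProblem, sense: str = "max") -> HybridSolution:
    """Solve the hybrid LP by dual simplex (HiGHS).

    Maximisation is handled by negating the objective internally; reported
    multipliers always refer to the stated sense.  On infeasibility the
    status carries a hint from a staged constraint-group relaxation probe.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c, A_eq, b_eq, A_ub, b_ub, bounds, labels = problem.arrays()
    res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                   bounds=bounds, sense=sense)
    m = problem.model
    n = m.n_reactions
    score_idx = [f"PC{i+1}" for i in range(problem.npc)]
    if res.status != 0:
        status = {2: "infeasible", 3: "unbounded"}.get(res.status, "numerical")
        msg = res.message
        if status == "infeasible":
            msg = f"{msg}; {_diagnose_infeasibility(problem)}"
        empty = pd.DataFrame(columns=["group", "name", "side", "price"])
        return HybridSolution(
            v=pd.Series(np.nan, index=m.reaction_ids),
            scores=pd.Series(np.nan, index=score_idx),
            J=np.nan, status=status, sense=sense,
            r_exch=pd.Series(np.nan, index=m.exchange_species),
            multipliers=empty, message=msg)

    x = res.x
    v = pd.Series(x[:n], index=m.reaction_ids, name="v")
    scores = pd.Series(x[n:], index=score_idx, name="scores")

    rows = []
    eq_marg = res.eqlin.marginals if A_eq.shape[0] else []
    for met, lam in zip(m.metabolite_ids, eq_marg):
        rows.append(("mass_balance", met, "eq", float(lam)))
    if A_ub is not None:
        for (group, name, side), lam in zip(labels, res.ineqlin.marginals):
            # rhs of every stacked row increases by 1 under outward relaxation
            rows.append((group, name, side, float(lam)))
    for j, rid in enumerate(m.reaction_ids):
        rows.append(("flux_bound", rid, "lower", float(-res.lower.marginals[j])))
        rows.append(("flux_bound", rid, "upper", float(res.upper.marginals[j])))
    for i, pc in enumerate(score_idx):
        rows.append(("score_bound", pc, "lower", float(-res.lower.marginals[n + i])))
        rows.append(("score_bound", pc, "upper", float(res.upper.marginals[n + i])))
    mult = pd.DataFrame(rows, columns=["group", "name", "side", "price"])

    return HybridSolution(
        v=v, scores=scores, J=float(res.fun), status="optimal", sense=sense,
        r_exch=m.exchange_rates(x[:n]), multipliers=mult, message=res.message)


def _diagnose_infeasibility(problem: HybridProblem) -> str:
    """Relax constraint groups one at a time to locate the conflict."""
    probes = []
    if problem.npc > 0:
        probes.append(("PCA band", replace(problem, rf=1e9)))
        probes.append(("score bounds",
                       replace(problem, lb_scores=np.full(problem.npc, -1e9),
                               ub_scores=np.full(problem.npc, 1e9))))
    if problem.bound_mask or problem.fixed_exchange:
        probes.append(("exchange bounds",
                       replace(problem, bound_mask=[], fixed_exchange={})))
    for name, relaxed in probes:
        c, A_eq, b_eq, A_ub, b_ub, bounds, _ = relaxed.arrays()
        res = solve_lp(np.zeros(relaxed.n_vars), A_eq=A_eq, b_eq=b_eq,
                       A_ub=A_ub, b_ub=b_ub, bounds=bounds)
        if res.status == 0:
            return f"relaxing the {name} restores feasibility"
    return "infeasibility persists after single-group relaxation probes"


def pca_band_slack(problem: HybridProblem, solution: HybridSolution) -> pd.Series:
    """Per-species mismatch ε between mechanistic and PCA-reconstructed
    exchange rates at a solution; |ε|/sigma ≤ RF at any feasible point."""
    if problem.npc == 0:
        raise ValueError("no PCA constraints in this problem")
    m = problem.model
    coeff = problem.pca.coeff.to_numpy()[:, :problem.npc]
    sig = problem.pca.sigma.to_numpy()
    mu = problem.pca.mu.to_numpy()
    s = solution.scores.to_numpy()
    eps = []
    for i, sp in enumerate(problem.pca.species):
        r_mech = float(m.S_ext[m.species_index(sp)] @ solution.v.to_numpy())
        r_pca = mu[i] + sig[i] * (coeff[i] @ s)
        eps.append(r_mech - r_pca)
    return pd.Series(eps, index=problem.pca.species, name="epsilon")


@dataclass
class MinMax:
    j_min: float
    j_max: float

    @property
    def half_interval(self) -> float:
        return 0.5 * (self.j_min + self.j_max)


def minmax_interval(problem: HybridProblem, objective_flux: str | None = None) -> MinMax:
    """Minimise and maximise a single flux; the half-interval midpoint is the
    point prediction."""
    p = problem if objective_flux is None else problem.with_objective(objective_flux)
    lo = solve(p, sense="min")
    hi = solve(p, sense="max")
    for sol in (lo, hi):
        if sol.status != "optimal":
            raise RuntimeError(f"minmax solve {sol.sense} failed: {sol.status} "
                               f"({sol.message})")
    return MinMax(j_min=lo.J, j_max=hi.J)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    npc: int
    rf: float
    table: pd.DataFrame


def calibrate(model: GEMModel, pca: PCAModel, scenario: Scenario,
              npc_grid, rf_grid, reference_value: float,
              r_mean: pd.Series, sigma: pd.Series,
              scenarios: list[Scenario] | None = None,
              rf_small: float = 0.5, objective=None) -> CalibrationResult:
    """Two-stage calibration of (NPC, RF).

    Stage 1 fixes a small RF and picks NPC minimising the absolute error
    between the maximisation optimum and ``reference_value`` (ties broken
    toward smaller NPC; infeasible grid points are skipped).  Stage 2 scans
    ``rf_grid`` upward and returns the smallest RF for which every scenario
    in ``scenarios`` (default: the calibration scenario alone) is feasible at
    the chosen NPC.
    """
    npc_grid = list(npc_grid)
    rf_grid = sorted(rf_grid)
    if not npc_grid or not rf_grid:
        raise ValueError("calibration grids must be non-empty")
    if not np.isfinite(reference_value):
        raise ValueError("reference value must be finite")

    records = []
    best_npc, best_err = None, np.inf
    for npc in npc_grid:
        prob = build_problem(model, pca=pca, npc=npc, rf=rf_small,
                             scenario=scenario, r_mean=r_mean, sigma=sigma,
                             objective=objective)
        sol = solve(prob, sense="max")
        pred = sol.J if sol.status == "optimal" else np.nan
        err = abs(pred - reference_value) if np.isfinite(pred) else np.nan
        records.append({"stage": "npc", "npc": npc, "rf": rf_small,
                        "prediction": pred, "feasible": sol.status == "optimal"})
        if np.isfinite(err) and err < best_err - 1e-15:
            best_npc, best_err = npc, err
    if best_npc is None:
        raise CalibrationError(
            f"no feasible NPC at RF={rf_small}:\n{pd.DataFrame(records)}")

    suite = scenarios if scenarios is not None else [scenario]
    best_rf = None
    for rf in rf_grid:
        ok = True
        for sc in suite:
            prob = build_problem(model, pca=pca, npc=best_npc, rf=rf,
                                 scenario=sc, r_mean=r_mean, sigma=sigma,
                                 objective=objective)
            sol = solve(prob, sense="max")
            feasible = sol.status == "optimal"
            records.append({"stage": "rf", "npc": best_npc, "rf": rf,
                            "prediction": sol.J if feasible else np.nan,
                            "feasible": feasible, "scenario": sc.name})
            ok = ok and feasible
        if ok and best_rf is None:
            best_rf = rf
    table = pd.DataFrame(records)
    if best_rf is None:
        raise CalibrationError(f"no RF on the grid makes all scenarios "
                               f"feasible at NPC={best_npc}:\n{table}")
    return CalibrationResult(npc=int(best_npc), rf=float(best_rf), table=table)


# ---------------------------------------------------------------------------
# variability, sensitivities
# ---------------------------------------------------------------------------

def fva(problem: HybridProblem, j_opt: float | None = None,
        tol: float = 0.05, sense: str = "max",
        reactions=None) -> pd.DataFrame:
    """Flux variability under an objective tolerance band.

    All problem constraints are kept and the objective is confined to
    ``[(1−tol)·J, (1+tol)·J]`` with the endpoints ordered by value, so a
    negative optimum is handled correctly.  Returns per-reaction
    ``[v_min, v_max]`` and the half-interval midpoint.
    """
    if j_opt is None:
        j_opt = solve(problem, sense=sense).J
    lo = min((1 - tol) * j_opt, (1 + tol) * j_opt)
    hi = max((1 - tol) * j_opt, (1 + tol) * j_opt)

    c, A_eq, b_eq, A_ub, b_ub, bounds, _ = problem.arrays()
    rxns = list(problem.model.reaction_ids) if reactions is None else list(reactions)
    idx = [problem.model.reaction_index(r) for r in rxns]

    def run(lo_, hi_):
        band = np.vstack([c, -c])
        A = band if A_ub is None else np.vstack([A_ub, band])
        b = (np.array([hi_, -lo_]) if b_ub is None
             else np.concatenate([b_ub, [hi_, -lo_]]))
        out = np.zeros((len(idx), 2))
        for k_, j in enumerate(idx):
            cj = np.zeros(problem.n_vars)
            cj[j] = 1.0
            for col, s in ((0, "min"), (1, "max")):
                res = solve_lp(cj, A_eq=A_eq, b_eq=b_eq, A_ub=A, b_ub=b,
                               bounds=bounds, sense=s)
                if res.status != 0:
                    raise RuntimeError(f"FVA LP failed for {rxns[k_]}: "
                                       f"{res.message}")
                out[k_, col] = res.fun
        return out

    try:
        ranges = run(lo, hi)
    except RuntimeError:
        eps = 1e-9 * max(1.0, abs(j_opt))
        ranges = run(lo - eps, hi + eps)   # numerical-band retry
    return pd.DataFrame({"v_min": ranges[:, 0], "v_max": ranges[:, 1],
                         "mid": ranges.mean(axis=1)}, index=rxns)


def shadow_prices(solution: HybridSolution, top: int | None = None) -> pd.DataFrame:
    """Constraint sensitivities ranked by magnitude.

    Each price is the first-order change in J per unit outward relaxation of
    the constraint; zero for non-binding inequalities (complementary
    slackness).
    """
    if solution.status != "optimal":
        raise ValueError("shadow prices require an optimal solution")
    if solution.degenerate:
        warnings.warn("degenerate optimum: shadow prices may be one of "
                      "several valid dual solutions", stacklevel=2)
    table = solution.multipliers.copy()
    table = table.reindex(table["price"].abs().sort_values(ascending=False).index)
    return table.head(top) if top else table.reset_index(drop=True)


def check_degeneracy(problem: HybridProblem, solution: HybridSolution,
                     tol: float = 1e-6) -> bool:
    """Flag alternate optima: any nonzero flux range on the optimal face."""
    ranges = fva(problem, j_opt=solution.J, tol=0.0, sense=solution.sense)
    deg = bool((ranges["v_max"] - ranges["v_min"] > tol).any())
    solution.degenerate = deg
    return deg


def subsystem_activity(flux_vector, model: GEMModel,
                       reference_flux_vector=None) -> pd.DataFrame:
    """Per-subsystem activity Σ|v_r| and its delta versus a reference.

    Reactions without a subsystem label are collected under "unassigned".
    """
    v = pd.Series(np.asarray(flux_vector, float).ravel(), index=model.reaction_ids)
    labels = [s if s else "unassigned" for s in model.subsystem]
    act = v.abs().groupby(pd.Index(labels, name="subsystem")).sum()
    out = pd.DataFrame({"activity": act})
    if reference_flux_vector is not None:
        ref = pd.Series(np.asarray(reference_flux_vector, float).ravel(),
                        index=model.reaction_ids)
        out["reference"] = ref.abs().groupby(pd.Index(labels)).sum()
        out["delta"] = out["activity"] - out["reference"]
    return out


@dataclass
class BiomassSensitivitySummary:
    J_values: np.ndarray
    flux_sd: pd.Series
    flux_mean: pd.Series
    n_feasible: int
    n_draws: int

    @property
    def J_sd(self) -> float:
        return float(np.std(self.J_values, ddof=1)) if len(self.J_values) > 1 else 0.0


def biomass_sensitivity(problem: HybridProblem, coefficient_perturbation: float,
                        n_draws: int = 30, seed: int = 0,
                        sense: str = "max") -> BiomassSensitivitySummary:
    """Resample biomass stoichiometric coefficients and re-solve.

    Each draw multiplies every nonzero coefficient of the biomass column of
    S_int by an independent lognormal factor with the stated relative SD, so
    the perturbation-to-zero limit leaves the problem unchanged.  Returns the
    spread of the objective and of every flux over the feasible draws.
    """
    if coefficient_perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    model = problem.model
    if model.biomass_rxn is None:
        raise ValueError("model has no biomass reaction")
    j = model.reaction_index(model.biomass_rxn)
    rng = np.random.default_rng(seed)
    Js, flux_rows = [], []
    for _ in range(n_draws):
        pert = model.copy()
        col = pert.S_int[:, j]
        nz = col != 0
        col[nz] = col[nz] * rng.lognormal(0.0, coefficient_perturbation, nz.sum())
        pert.S_int[:, j] = col
        sol = solve(problem.with_model(pert), sense=sense)
        if sol.status == "optimal":
            Js.append(sol.J)
            flux_rows.append(sol.v)
    if not Js:
        raise RuntimeError(f"all {n_draws} perturbed problems infeasible")
    fluxes = pd.DataFrame(flux_rows)
    return BiomassSensitivitySummary(
        J_values=np.array(Js),
        flux_sd=fluxes.std(axis=0, ddof=1) if len(Js) > 1
        else pd.Series(0.0, index=fluxes.columns),
        flux_mean=fluxes.mean(axis=0),
        n_feasible=len(Js), n_draws=n_draws)
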