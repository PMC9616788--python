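"""Metabolic-model I/O, validation and medium-specific reduction.

A genome-scale model is held as the linear system

    0 = S_int v,     LB_v <= v <= UB_v,     r_exch = S_ext v

where ``S_int`` stoichiometrically balances the intracellular metabolites and
``S_ext`` maps the flux vector onto the net exchange rates of the measurable
extracellular species.  Extracellular species are *not* balanced: their rows
live in ``S_ext`` and their net production/consumption is the exchange flux
``r_exch`` (uptake negative, secretion positive).

Models are read from SBML or COBRA-style JSON through cobrapy.  A model that
carries explicit boundary (exchange/sink/demand) reactions is normalised on
load: the metabolites touched by boundary reactions form the extracellular
block and the boundary reactions themselves are dropped — at steady state the
flux of an exchange reaction equals the net stoichiometric production of its
metabolite, so the two representations are exactly equivalent.  Models without
boundary reactions (the convention used by this package's own JSON output)
declare extracellular species via the boundary compartment (default ``"e"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._lp import solve_lp

__all__ = [
    "GEMModel",
    "ResidualReport",
    "ModelFormatError",
    "ModelValidationError",
    "InfeasibleReductionError",
    "load_model",
    "write_model",
    "from_cobra",
    "to_cobra",
    "reduce_to_medium",
    "degrees_of_freedom",
    "validate_against_measurements",
]

#: |flux| below which a reaction is considered blocked during reduction
BLOCKED_TOL = 1e-9


class ModelFormatError(ValueError):
    """The input file does not parse in the named standard."""


class ModelValidationError(ValueError):
    """The parsed model violates a structural invariant."""


class InfeasibleReductionError(RuntimeError):
    """Medium reduction blocked an essential reaction (e.g. biomass)."""


@dataclass
class GEMModel:
    """Stoichiometric model split into intracellular and exchange blocks.

    Fluxes are in mmol·gDW⁻¹·h⁻¹ (the biomass flux in h⁻¹); stoichiometric
    coefficients are dimensionless.  Reversibility is encoded purely in the
    bounds: irreversible reactions have ``lb = 0``.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]          # intracellular, balanced
    exchange_species: list[str]        # extracellular, rows of S_ext
    S_int: np.ndarray                  # (n_int, n_rxn)
    S_ext: np.ndarray                  # (n_ext, n_rxn)
    lb: np.ndarray
    ub: np.ndarray
    subsystem: list[str] = field(default_factory=list)
    biomass_rxn: str | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.S_int = np.atleast_2d(np.asarray(self.S_int, dtype=float))
        self.S_ext = np.atleast_2d(np.asarray(self.S_ext, dtype=float))
        if self.S_int.size == 0:
            self.S_int = self.S_int.reshape(0, len(self.reaction_ids))
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if not self.subsystem:
            self.subsystem = [""] * self.n_reactions
        self.validate()

    # -- basic queries -----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def species_index(self, species: str) -> int:
        try:
            return self.exchange_species.index(species)
        except ValueError:
            raise KeyError(f"unknown exchange species {species!r}") from None

    def validate(self) -> None:
        n = self.n_reactions
        if self.S_int.shape[1] != n or self.S_ext.shape[1] != n:
            raise ModelValidationError(
                f"matrix/ bound dimension mismatch: {self.S_int.shape}, "
                f"{self.S_ext.shape}, {n} reactions")
        if len(self.lb) != n or len(self.ub) != n:
            raise ModelValidationError("bounds length != number of reactions")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.where(self.lb > self.ub)[0]]
            raise ModelValidationError(f"LB > UB for {bad}")
        if self.S_ext.shape[0] != len(self.exchange_species):
            raise ModelValidationError("S_ext rows != exchange species")
        if self.S_int.shape[0] != len(self.metabolite_ids):
            raise ModelValidationError("S_int rows != metabolite ids")
        if len(set(self.exchange_species)) != len(self.exchange_species):
            raise ModelValidationError("duplicate exchange species")
        if self.biomass_rxn is not None and self.biomass_rxn not in self.reaction_ids:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_rxn!r} not in model")

    def copy(self) -> "GEMModel":
        return replace(
            self,
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            exchange_species=list(self.exchange_species),
            S_int=self.S_int.copy(), S_ext=self.S_ext.copy(),
            lb=self.lb.copy(), ub=self.ub.copy(),
            subsystem=list(self.subsystem), notes=list(self.notes))

    def exchange_rates(self, v: np.ndarray) -> pd.Series:
        """r_exch = S_ext v, as a Series indexed by exchange species."""
        return pd.Series(self.S_ext @ np.asarray(v, float),
                         index=self.exchange_species, name="r_exch")


# ---------------------------------------------------------------------------
# cobrapy interop
# ---------------------------------------------------------------------------

def from_cobra(cmodel, boundary_compartment: str = "e") -> GEMModel:
    """Convert a cobrapy model to a :class:`GEMModel`.

    Boundary reactions (single-metabolite exchanges, sinks, demands) are
    removed and their metabolites become the extracellular block; if none are
    present, metabolites in ``boundary_compartment`` are taken as
    extracellular.  Source order of reactions and metabolites is preserved.
    """
    boundary = list(cmodel.boundary)
    if boundary:
        ext_ids = {m.id for r in boundary for m in r.metabolites}
    else:
        ext_ids = {m.id for m in cmodel.metabolites
                   if m.compartment == boundary_compartment}
    if not ext_ids:
        raise ModelValidationError(
            "model has no exchange/boundary reactions and no metabolites in "
            f"compartment {boundary_compartment!r}")

    boundary_ids = {r.id for r in boundary}
    rxns = [r for r in cmodel.reactions if r.id not in boundary_ids]
    met_int = [m.id for m in cmodel.metabolites if m.id not in ext_ids]
    met_ext = [m.id for m in cmodel.metabolites if m.id in ext_ids]
    int_pos = {m: i for i, m in enumerate(met_int)}
    ext_pos = {m: i for i, m in enumerate(met_ext)}

    n = len(rxns)
    S_int = np.zeros((len(met_int), n))
    S_ext = np.zeros((len(met_ext), n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    subsystem = []
    notes: list[str] = []
    biomass = None
    for j, r in enumerate(rxns):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        subsystem.append(r.subsystem or "")
        if getattr(r, "objective_coefficient", 0.0):
            biomass = r.id
        for m, coef in r.metabolites.items():
            if m.id in ext_pos:
                S_ext[ext_pos[m.id], j] = coef
            else:
                S_int[int_pos[m.id], j] = coef
    return GEMModel(
        reaction_ids=[r.id for r in rxns], metabolite_ids=met_int,
        exchange_species=met_ext, S_int=S_int, S_ext=S_ext, lb=lb, ub=ub,
        subsystem=subsystem, biomass_rxn=biomass, notes=notes)


def to_cobra(model: GEMModel, add_boundary: bool = True):
    """Build a cobrapy model from a :class:`GEMModel`.

    With ``add_boundary=True`` every exchange species receives an open
    exchange reaction ``EX_<species>`` (bounds ±1e6) so the model is directly
    usable by standard FBA tooling; with ``add_boundary=False`` the
    extracellular metabolites are written unbalanced in compartment ``"e"``
    (this package's round-trip JSON convention).
    """
    import cobra

    cmodel = cobra.Model("hybridfba_model")
    mets_int = {m: cobra.Metabolite(m, compartment="c")
                for m in model.metabolite_ids}
    mets_ext = {s: cobra.Metabolite(s, compartment="e")
                for s in model.exchange_species}
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        # plain python floats: the SBML writer rejects numpy scalars
        rxn.lower_bound, rxn.upper_bound = float(model.lb[j]), float(model.ub[j])
        rxn.subsystem = model.subsystem[j]
        stoich = {}
        for i, m in enumerate(model.metabolite_ids):
            if model.S_int[i, j]:
                stoich[mets_int[m]] = model.S_int[i, j]
        for i, s in enumerate(model.exchange_species):
            if model.S_ext[i, j]:
                stoich[mets_ext[s]] = model.S_ext[i, j]
        rxn.add_metabolites(stoich)
        reactions.append(rxn)
    cmodel.add_reactions(reactions)
    if add_boundary:
        ex_rxns = []
        for s in model.exchange_species:
            ex = cobra.Reaction(f"EX_{s}")
            ex.lower_bound, ex.upper_bound = -1e6, 1e6
            ex.add_metabolites({mets_ext[s]: -1.0})
            ex_rxns.append(ex)
        cmodel.add_reactions(ex_rxns)
    if model.biomass_rxn is not None:
        cmodel.objective = model.biomass_rxn
    return cmodel


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_model(source, format: str | None = None,
               boundary_compartment: str = "e") -> GEMModel:
    """Read an SBML or COBRA-style JSON model file.

    ``format`` is ``"sbml"`` or ``"cobra-json"``; when omitted it is inferred
    from the file suffix.  Reversibility is always taken from the bounds; an
    SBML reaction flagged irreversible whose lower bound is negative loads as
    reversible with a recorded warning (bounds win).
    """
    import cobra.io

    path = Path(source)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "cobra-json"
    try:
        if format == "sbml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmodel = cobra.io.read_sbml_model(str(path))
        elif format == "cobra-json":
            cmodel = cobra.io.load_json_model(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (ValueError, KeyError) as exc:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ModelFormatError(f"cannot parse {path} as {format}: {exc}") from exc

    model = from_cobra(cmodel, boundary_compartment=boundary_compartment)
    if format == "sbml":
        model.notes.extend(_sbml_reversibility_conflicts(path, model))
    for note in model.notes:
        warnings.warn(note, stacklevel=2)
    return model


def _sbml_reversibility_conflicts(path: Path, model: GEMModel) -> list[str]:
    """Flag reactions whose SBML reversible attribute conflicts with bounds."""
    try:
        import libsbml
    except ImportError:  # pragma: no cover
        return []
    doc = libsbml.readSBMLFromFile(str(path))
    sbml_model = doc.getModel()
    if sbml_model is None:
        return []
    flagged = []
    idx = {r: j for j, r in enumerate(model.reaction_ids)}
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = r.getId()
        # cobra strips the common 'R_' SBML prefix
        j = idx.get(rid, idx.get(rid.removeprefix("R_")))
        if j is None:
            continue
        if not r.getReversible() and model.lb[j] < 0:
            flagged.append(
                f"reaction {model.reaction_ids[j]!r} declared irreversible in "
                f"SBML but has lower bound {model.lb[j]}; bounds take "
                f"precedence (treated as reversible)")
    return flagged


def write_model(model: GEMModel, path) -> None:
    """Write a COBRA-style JSON file (extracellular block in compartment e)."""
    import cobra.io

    cobra.io.save_json_model(to_cobra(model, add_boundary=False), str(path))


# ---------------------------------------------------------------------------
# reduction, degrees of freedom, validation
# ---------------------------------------------------------------------------

def _closed_equality(model: GEMModel, closed: list[str]) -> np.ndarray:
    rows = [model.S_ext[model.species_index(s)] for s in closed]
    if rows:
        return np.vstack([model.S_int, np.array(rows)])
    return model.S_int


def flux_ranges(S_eq: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                reactions: list[int] | None = None) -> np.ndarray:
    """Per-reaction [min, max] flux under ``S_eq v = 0`` and bounds."""
    n = len(lb)
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S_eq.shape[0])
    idx = range(n) if reactions is None else reactions
    out = np.zeros((len(list(idx)), 2))
    idx = range(n) if reactions is None else reactions
    for k, j in enumerate(idx):
        c = np.zeros(n)
        c[j] = 1.0
        for col, sense in ((0, "min"), (1, "max")):
            res = solve_lp(c, A_eq=S_eq, b_eq=b_eq, bounds=bounds, sense=sense)
            if res.status != 0:
                raise InfeasibleReductionError(
                    f"flux range LP failed for reaction index {j} "
                    f"(status {res.status}): {res.message}")
            out[k, col] = res.fun
    return out


def reduce_to_medium(model: GEMModel, medium_species,
                     tol: float = BLOCKED_TOL) -> GEMModel:
    """Return a medium-specific, self-consistent submodel.

    Exchanges of species absent from ``medium_species`` are closed (their net
    exchange is forced to zero, i.e. their S_ext row becomes a balance row),
    reactions blocked under the closed medium are removed, and metabolites
    left without reactions are dropped.  ``medium_species`` must include every
    species that may still cross the boundary — substrates, secreted products
    and the growth "species" alike.
    """
    medium = set(medium_species)
    unknown = medium - set(model.exchange_species)
    if unknown:
        raise ModelValidationError(f"medium species not in model: {sorted(unknown)}")
    closed = [s for s in model.exchange_species if s not in medium]

    S_eq = _closed_equality(model, closed)
    ranges = flux_ranges(S_eq, model.lb, model.ub)
    blocked = np.max(np.abs(ranges), axis=1) < tol
    if model.biomass_rxn is not None and blocked[model.reaction_index(model.biomass_rxn)]:
        raise InfeasibleReductionError(
            f"reducing to medium {sorted(medium)} blocks the biomass reaction "
            f"{model.biomass_rxn!r}")

    keep = ~blocked
    rxn_ids = [r for r, k in zip(model.reaction_ids, keep) if k]
    S_int = model.S_int[:, keep]
    S_ext = model.S_ext[:, keep]

    # closed species whose balance still involves surviving reactions become
    # internal metabolites; all-zero rows disappear entirely.
    extra_rows, extra_ids = [], []
    for s in closed:
        row = S_ext[model.species_index(s)]
        if np.any(row != 0):
            extra_rows.append(row)
            extra_ids.append(s)
    keep_int = np.any(S_int != 0, axis=1)
    new_S_int = S_int[keep_int]
    new_met = [m for m, k in zip(model.metabolite_ids, keep_int) if k]
    if extra_rows:
        new_S_int = np.vstack([new_S_int, np.array(extra_rows)])
        new_met += extra_ids

    keep_ext = [i for i, s in enumerate(model.exchange_species)
                if s in medium and np.any(S_ext[i] != 0)]
    return GEMModel(
        reaction_ids=rxn_ids,
        metabolite_ids=new_met,
        exchange_species=[model.exchange_species[i] for i in keep_ext],
        S_int=new_S_int if new_S_int.size else np.zeros((0, len(rxn_ids))),
        S_ext=S_ext[keep_ext] if keep_ext else np.zeros((0, len(rxn_ids))),
        lb=model.lb[keep], ub=model.ub[keep],
        subsystem=[s for s, k in zip(model.subsystem, keep) if k],
        biomass_rxn=model.biomass_rxn,
        notes=list(model.notes))


def degrees_of_freedom(model: GEMModel, tol: float | None = None) -> int:
    """n_reactions − rank(S_int).

    The rank uses numpy's SVD-based estimate; ``tol`` (absolute singular-value
    cutoff) defaults to numpy's ``max(dim) * eps * s_max`` convention.
    """
    if model.S_int.shape[0] == 0:
        return model.n_reactions
    return model.n_reactions - int(np.linalg.matrix_rank(model.S_int, tol=tol))


@dataclass
class ResidualReport:
    """Least-squares fit of the model to measured exchange rates."""

    v: np.ndarray
    r_fit: pd.Series
    residuals: pd.Series          # fitted − measured, per species
    ssr: float
    success: bool
    message: str


def validate_against_measurements(model: GEMModel, r_measured) -> ResidualReport:
    """Fit ``min ||S_ext v − r_measured||²`` s.t. ``S_int v = 0`` and bounds.

    ``r_measured`` is a Series indexed by exchange species (any order, must
    cover a subset of the model's species) or an array aligned to
    ``exchange_species``.  A near-zero SSR confirms the measured rates are
    stoichiometrically attainable by the model.
    """
    from scipy.optimize import minimize

    if isinstance(r_measured, pd.Series):
        missing = set(r_measured.index) - set(model.exchange_species)
        if missing:
            raise ModelValidationError(f"unknown species in measurements: {sorted(missing)}")
        species = list(r_measured.index)
        r = r_measured.to_numpy(dtype=float)
    else:
        species = list(model.exchange_species)
        r = np.asarray(r_measured, dtype=float)
        if len(r) != len(species):
            raise ModelValidationError("measurement vector length mismatch")
    rows = [model.species_index(s) for s in species]
    E = model.S_ext[rows]

    # LP feasible start, then SLSQP on the convex QP
    res0 = solve_lp(np.zeros(model.n_reactions), A_eq=model.S_int,
                    b_eq=np.zeros(model.S_int.shape[0]),
                    bounds=list(zip(model.lb, model.ub)))
    if res0.status != 0:
        raise RuntimeError(f"no feasible flux distribution: {res0.message}")
    v0 = res0.x

    def obj(v):
        d = E @ v - r
        return 0.5 * d @ d

    def grad(v):
        return E.T @ (E @ v - r)

    cons = []
    if model.S_int.shape[0]:
        cons.append({"type": "eq",
                     "fun": lambda v: model.S_int @ v,
                     "jac": lambda v: model.S_int})
    opt = minimize(obj, v0, jac=grad, method="SLSQP",
                   bounds=list(zip(model.lb, model.ub)), constraints=cons,
                   options={"maxiter": 1000, "ftol": 1e-14})
    v = opt.x if obj(opt.x) <= obj(v0) else v0
    r_fit = pd.Series(E @ v, index=species, name="r_fit")
    resid = r_fit - pd.Series(r, index=species)
    return ResidualReport(v=v, r_fit=r_fit, residuals=resid.rename("residual"),
                          ssr=float(resid @ resid), success=bool(opt.success),
                          message=str(opt.message))
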