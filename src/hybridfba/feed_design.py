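"""Translate an exchange-flux solution into a feed recipe and controller.

The design principle is to feed, at every instant, exactly the substrate
consumption computed by the flux solution:

    F·C_F = r_exch · X_V · V                  (steady-state species balance)
    C_F,i = c_Glc · r_i / r_Glc               (concentrations relative to glucose)
    F     = (r_Glc / c_Glc) · X_V · V = a·X_V·V   (feedforward controller)

with F the feed rate (mL/h), C_F the feed concentrations (mmol/mL), c_Glc
the reference glucose feed concentration, X_V the viable cell density
(Mcell/mL) and V the culture volume (mL).  Flux solutions arrive in
mmol·gDW⁻¹·h⁻¹; a single dry-weight-per-cell factor converts them to the
per-cell basis of the controller — it is applied in exactly one place, the
construction of the controller gain ``a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import DEFAULT_DW_PG, TimeCourse, gdw_per_mcell

__all__ = ["FeedDesign", "design_feed", "feed_rate", "simulate_fedbatch",
           "DepletionEvent"]

log = logging.getLogger(__name__)


class DepletionEvent(RuntimeError):
    """A simulated concentration reached zero before the horizon."""

    def __init__(self, species: str, time: float, tc: "TimeCourse"):
        super().__init__(f"{species} depleted at t = {time:.2f} h")
        self.species = species
        self.time = time
        self.timecourse = tc


@dataclass
class FeedDesign:
    """A feed formulation plus its feedforward controller gain.

    ``c_f`` holds feed concentrations (mmol/mL) for the fed (consumed)
    species only; glucose sits exactly at ``c_glc``.  ``a`` is the controller
    gain in mL·Mcell⁻¹·h⁻¹.  ``source_fluxes`` is the full exchange-rate
    vector (mmol·gDW⁻¹·h⁻¹) the design was derived from.
    """

    c_f: pd.Series
    c_glc: float
    a: float
    source_fluxes: pd.Series
    excluded: list[str] = field(default_factory=list)
    binding_species: str | None = None
    dw_pg: float = DEFAULT_DW_PG


def design_feed(solution_fluxes: pd.Series, c_glc: float,
                glucose: str = "Glc", solubility_limits: pd.Series | None = None,
                solubility_fraction: float = 0.75,
                exclude=None, dw_pg: float = DEFAULT_DW_PG) -> FeedDesign:
    """Build a feed recipe from an exchange-flux vector (uptake negative).

    Fed species are those with negative (consumed) flux; secreted species are
    excluded with a logged note, as are any species listed in ``exclude``.
    If solubility limits (mmol/mL) are given, every concentration must stay
    below ``solubility_fraction`` (default 75%) of its limit; otherwise
    ``c_glc`` is scaled down to the largest compliant value and the binding
    compound is reported.
    """
    r = solution_fluxes.astype(float)
    if glucose not in r.index:
        raise KeyError(f"glucose species {glucose!r} not in flux vector")
    r_glc = float(r[glucose])
    if r_glc == 0:
        raise ZeroDivisionError(
            "glucose exchange flux is zero; the recipe normalises all "
            "concentrations to glucose — choose another reference species "
            "or supply a solution that consumes glucose")
    if r_glc > 0:
        raise ValueError("glucose must be consumed (negative flux) in the design")
    if c_glc <= 0:
        raise ValueError("reference glucose concentration must be positive")

    exclude = set(exclude or ())
    skipped = []
    fed = {}
    for sp, flux in r.items():
        if sp in exclude:
            skipped.append(sp)
            continue
        if flux >= 0:
            if flux > 0:
                log.info("species %s is secreted in the design; excluded from feed", sp)
            skipped.append(sp)
            continue
        fed[sp] = flux / r_glc          # ≥ 0: ratio of consumption to glucose

    ratios = pd.Series(fed, name="ratio")
    binding = None
    if solubility_limits is not None:
        caps = solubility_fraction * solubility_limits.reindex(ratios.index)
        caps = caps.dropna()
        # largest c_glc with ratio·c_glc ≤ cap for every limited species
        allowed = caps / ratios[caps.index]
        if len(allowed) and c_glc > allowed.min():
            binding = str(allowed.idxmin())
            c_glc = float(allowed.min())
            log.info("c_Glc scaled down to %.4g; %s sits at the %.0f%% "
                     "solubility cap", c_glc, binding, 100 * solubility_fraction)

    c_f = (ratios * c_glc).rename("c_f")
    r_glc_per_mcell = abs(r_glc) * gdw_per_mcell(dw_pg)   # mmol/(Mcell·h)
    return FeedDesign(c_f=c_f, c_glc=float(c_glc), a=r_glc_per_mcell / c_glc,
                      source_fluxes=r, excluded=skipped, binding_species=binding,
                      dw_pg=dw_pg)


def feed_rate(design: FeedDesign, Xv: float, V: float) -> float:
    """Feedforward feed rate F = a·X_V·V (mL/h); linear in both arguments."""
    if Xv < 0 or V < 0:
        raise ValueError("cell density and volume must be non-negative")
    return design.a * Xv * V


def simulate_fedbatch(design: FeedDesign, growth: dict, state0: dict,
                      horizon: float, dt: float = 0.05,
                      feed_on: bool = True,
                      bolus_interval: float | None = None) -> TimeCourse:
    """Integrate the controlled fed-batch mass balances.

        dV/dt      = F
        d(X_V·V)/dt = µ·X_V·V
        d(C_i·V)/dt = r_i·X_dw·V + F·C_F,i

    ``growth`` supplies ``{"mu": h⁻¹, "rates": Series mmol/gDW/h}`` (rates
    default to the design's source fluxes); ``state0`` supplies ``Xv``
    (Mcell/mL), ``V`` (mL) and ``C`` (Series, mM).  Classical RK4 with fixed
    step ``dt``; halve ``dt`` and compare trajectories to verify convergence.
    With ``bolus_interval`` set, the continuous feed is replaced by discrete
    boluses carrying the same integrated amount (the plant's daily-bolus
    mode); feed events are recorded either way.  A concentration reaching
    zero terminates the run with a :class:`DepletionEvent` carrying the
    truncated trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = float(growth["mu"])
    rates = growth.get("rates")
    rates = design.source_fluxes if rates is None else pd.Series(rates, dtype=float)
    species = list(state0["C"].index)
    r = rates.reindex(species).fillna(0.0).to_numpy()
    cf = design.c_f.reindex(species).fillna(0.0).to_numpy()
    gdw = gdw_per_mcell(design.dw_pg)

    n_steps = int(round(horizon / dt))
    t_grid = np.arange(n_steps + 1) * dt
    # state y = [V, XV (=Xv·V, Mcell), A_i (=C_i·V/1000, mmol)...]
    y = np.concatenate([[state0["V"], state0["Xv"] * state0["V"]],
                        state0["C"].to_numpy() * state0["V"] / 1000.0])

    def controller(yv):
        V, XV = yv[0], yv[1]
        return design.a * XV if feed_on else 0.0     # a·Xv·V = a·XV

    def rhs(yv, F):
        V, XV = yv[0], yv[1]
        dV = F
        dXV = mu * XV
        dA = r * (XV * gdw) + F * cf
        return np.concatenate([[dV, dXV], dA])

    traj = [y.copy()]
    feeds = []
    fed_since_bolus = np.zeros(len(species))
    vol_since_bolus = 0.0
    for step in range(n_steps):
        t_next = t_grid[step + 1]
        if bolus_interval is not None:
            # accumulate what the continuous controller would have delivered,
            # integrate feed-free, then dump the accumulated bolus
            Fc = controller(y)
            fed_since_bolus += Fc * cf * dt
            vol_since_bolus += Fc * dt
            F = 0.0
            k1 = rhs(y, F)
            k2 = rhs(y + 0.5 * dt * k1, F)
            k3 = rhs(y + 0.5 * dt * k2, F)
            k4 = rhs(y + dt * k3, F)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.isclose(t_next % bolus_interval, 0.0, atol=dt * 0.49) or \
                    np.isclose(t_next % bolus_interval, bolus_interval, atol=dt * 0.49):
                y[0] += vol_since_bolus
                y[2:] += fed_since_bolus
                for sp, amt in zip(species, fed_since_bolus):
                    if amt:
                        feeds.append({"time": t_next, "species": sp, "mmol": amt})
                fed_since_bolus = np.zeros(len(species))
                vol_since_bolus = 0.0
        else:
            k1 = rhs(y, controller(y))
            k2 = rhs(y + 0.5 * dt * k1, controller(y + 0.5 * dt * k1))
            k3 = rhs(y + 0.5 * dt * k2, controller(y + 0.5 * dt * k2))
            k4 = rhs(y + dt * k3, controller(y + dt * k3))
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj.append(y.copy())
        if np.any(y[2:] < -1e-9):
            bad = int(np.argmin(y[2:]))
            tc = _to_timecourse(np.array(traj), t_grid[:len(traj)], species, feeds)
            raise DepletionEvent(species[bad], t_grid[len(traj) - 1], tc)
    return _to_timecourse(np.array(traj), t_grid, species, feeds)


def _to_timecourse(traj, t, species, feeds) -> TimeCourse:
    V = traj[:, 0]
    Xv = traj[:, 1] / V
    C = pd.DataFrame(traj[:, 2:] * 1000.0 / V[:, None], columns=species)
    feeds_df = (pd.DataFrame(feeds) if feeds
                else pd.DataFrame(columns=["time", "species", "mmol"]))
    return TimeCourse(t=t, Xv=Xv, V=V, C=C, feeds=feeds_df)
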