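"""Specific exchange-rate estimation from fed-batch time series.

A specific rate q (mmol·gDW⁻¹·h⁻¹) is the slope of the cumulative formed
quantity of a species (mmol, negative when consumed) regressed against the
integral of viable cell mass, IVC (gDW·h).  Robust regression (bisquare IRLS)
is the default so that single aberrant samples do not corrupt the slope.
Glutamine decomposes abiotically with first-order kinetics into equimolar
pyrrolidone carboxylate and ammonium; the corresponding correction adds the
abiotic loss back to the Gln series and removes it from the NH4 series before
the biological rates are estimated.

Units: time h, viable cell density Mcell·mL⁻¹, volume mL, concentrations mM,
bolus feeds mmol.  Cell mass uses a configurable dry weight per cell
(default 250 pg·cell⁻¹), i.e. 1 Mcell = ``dw_pg × 1e-6`` g-DW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .fluxpca import FluxDataset

__all__ = [
    "TimeCourse", "RateEstimate", "DEFAULT_DW_PG",
    "integral_viable_mass", "formed_quantity", "correct_gln_decomposition",
    "estimate_rate", "estimate_growth_rate", "estimate_rates",
    "dataset_statistics", "gdw_per_mcell",
]

#: default dry weight per cell, pg; a calibration input that linearly scales
#: every mmol/gDW/h rate estimated by this module.
DEFAULT_DW_PG = 250.0


def gdw_per_mcell(dw_pg: float = DEFAULT_DW_PG) -> float:
    """Grams dry weight per million cells (1 Mcell = 1e6 cells)."""
    return dw_pg * 1e-12 * 1e6


@dataclass
class TimeCourse:
    """A sampled fed-batch culture.

    ``C`` holds one concentration column per species (mM); ``feeds`` lists
    bolus events as (time h, species, mmol added).
    """

    t: np.ndarray                      # h, strictly increasing
    Xv: np.ndarray                     # Mcell/mL
    V: np.ndarray                      # mL
    C: pd.DataFrame                    # len(t) × species, mM
    feeds: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["time", "species", "mmol"]))

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.Xv = np.asarray(self.Xv, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.C = pd.DataFrame(self.C)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(self.Xv < 0):
            raise ValueError("negative viable cell density")
        if np.any(self.V < 0):
            raise ValueError("negative volume")
        if len(self.C) != len(self.t):
            raise ValueError("C rows must match sampling times")
        if len(self.feeds):
            bad = (self.feeds["time"] < self.t[0]) | (self.feeds["time"] > self.t[-1])
            if bad.any():
                raise ValueError("feed events outside the time course window")
            unknown = set(self.feeds["species"]) - set(self.C.columns)
            if unknown:
                raise ValueError(f"feed events for unknown species: {sorted(unknown)}")

    @property
    def species(self) -> list[str]:
        return list(self.C.columns)

    def window_mask(self, window=None) -> np.ndarray:
        if window is None:
            return np.ones_like(self.t, dtype=bool)
        lo, hi = window
        if lo < self.t[0] - 1e-9 or hi > self.t[-1] + 1e-9:
            raise ValueError(f"window {window} outside time course "
                             f"[{self.t[0]}, {self.t[-1]}]")
        return (self.t >= lo - 1e-9) & (self.t <= hi + 1e-9)

    # -- plain-text I/O ----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time": self.t, "Xv": self.Xv, "V": self.V})
        df = pd.concat([df, self.C.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feeds_path=None) -> "TimeCourse":
        df = pd.read_csv(path)
        feeds = (pd.read_csv(feeds_path) if feeds_path is not None
                 else pd.DataFrame(columns=["time", "species", "mmol"]))
        species = [c for c in df.columns if c not in ("time", "Xv", "V")]
        return cls(t=df["time"].to_numpy(), Xv=df["Xv"].to_numpy(),
                   V=df["V"].to_numpy(), C=df[species], feeds=feeds)


@dataclass
class RateEstimate:
    species: str
    rate: float                  # mmol/gDW/h (growth: 1/h)
    stderr: float
    window: tuple[float, float]
    method: str
    n_points: int


def integral_viable_mass(tc: TimeCourse, window=None,
                         dw_pg: float = DEFAULT_DW_PG) -> pd.Series:
    """Cumulative trapezoidal integral of viable cell mass, gDW·h.

    Evaluated at every sampling point inside ``window``; starts at 0.
    """
    mask = tc.window_mask(window)
    t = tc.t[mask]
    biomass = tc.Xv[mask] * tc.V[mask] * gdw_per_mcell(dw_pg)   # gDW
    if len(t) == 1:
        return pd.Series([0.0], index=t, name="ivc")
    ivc = cumulative_trapezoid(biomass, t, initial=0.0)
    return pd.Series(ivc, index=t, name="ivc")


def formed_quantity(tc: TimeCourse, species: str, window=None) -> pd.Series:
    """Cumulative formed amount of a species, mmol (negative = consumed).

    formed(t) = C(t)·V(t) − C(t₀)·V(t₀) − Σ bolus additions in (t₀, t];
    bolus subtraction makes the series continuous across feed events.
    """
    if species not in tc.C.columns:
        raise KeyError(f"species {species!r} not measured")
    mask = tc.window_mask(window)
    t = tc.t[mask]
    amount = tc.C[species].to_numpy()[mask] * tc.V[mask] / 1000.0   # mM·mL → mmol
    fed = np.zeros_like(t)
    if len(tc.feeds):
        ev = tc.feeds[tc.feeds["species"] == species]
        for _, row in ev.iterrows():
            fed += np.where(t >= row["time"] - 1e-9, row["mmol"], 0.0)
        fed -= fed[0]
    return pd.Series(amount - amount[0] - fed, index=t, name=species)


def correct_gln_decomposition(tc: TimeCourse, k_d: float,
                              gln: str = "Gln", nh4: str = "NH4",
                              window=None) -> dict[str, pd.Series]:
    """Remove abiotic first-order Gln decomposition from formed quantities.

    The abiotic loss ``L(t) = ∫ k_d·C_Gln·V dt`` (trapezoidal, mmol) is added
    back to the Gln formed-quantity series (decomposition is not cellular
    consumption) and subtracted from the NH4 series (equimolar abiotic
    production).  The two corrections cancel exactly at every time point.
    """
    if k_d < 0:
        raise ValueError("decomposition constant k_d must be >= 0")
    mask = tc.window_mask(window)
    t = tc.t[mask]
    gln_formed = formed_quantity(tc, gln, window)
    nh4_formed = formed_quantity(tc, nh4, window)
    rate = k_d * tc.C[gln].to_numpy()[mask] * tc.V[mask] / 1000.0   # mmol/h
    loss = cumulative_trapezoid(rate, t, initial=0.0)
    return {gln: gln_formed + loss, nh4: nh4_formed - loss}


def _check_regression_inputs(formed, ivc):
    y = np.asarray(formed, dtype=float)
    x = np.asarray(ivc, dtype=float)
    if len(x) != len(y):
        raise ValueError("formed and ivc series differ in length")
    if len(x) < 3:
        raise ValueError("rate estimation needs at least 3 points")
    if np.any(np.diff(x) < -1e-12):
        raise ValueError("IVC must be non-decreasing")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate regressor: IVC has zero span")
    return y, x


def estimate_rate(formed: pd.Series, ivc: pd.Series,
                  method: str = "robust", species: str | None = None,
                  tuning: float = 4.685) -> RateEstimate:
    """Slope of formed quantity vs IVC through a fitted intercept.

    ``method="robust"`` uses iteratively reweighted least squares with Tukey
    bisquare weights (tuning constant 4.685); ``method="ols"`` is plain least
    squares.
    """
    import statsmodels.api as sm

    y, x = _check_regression_inputs(formed, ivc)
    X = sm.add_constant(x)
    if method == "robust":
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tuning)).fit()
    elif method == "ols":
        fit = sm.OLS(y, X).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    name = species if species is not None else getattr(formed, "name", "") or ""
    window = (float(np.min(getattr(formed, "index", x))),
              float(np.max(getattr(formed, "index", x))))
    stderr = float(fit.bse[1]) if np.isfinite(fit.bse[1]) else 0.0
    return RateEstimate(species=str(name), rate=float(fit.params[1]),
                        stderr=stderr, window=window, method=method,
                        n_points=len(y))


def estimate_growth_rate(tc: TimeCourse, window=None,
                         dw_pg: float = DEFAULT_DW_PG,
                         method: str = "robust") -> RateEstimate:
    """Specific growth rate µ (h⁻¹) as the slope of biomass vs IVC.

    Under exponential growth B(t) = B₀e^{µt} the identity
    B(t) − B₀ = µ·∫B dt makes this slope exactly µ, estimated with the same
    regression machinery as the metabolite rates.
    """
    mask = tc.window_mask(window)
    ivc = integral_viable_mass(tc, window, dw_pg)
    biomass = tc.Xv[mask] * tc.V[mask] * gdw_per_mcell(dw_pg)
    formed = pd.Series(biomass - biomass[0], index=tc.t[mask], name="mu")
    est = estimate_rate(formed, ivc, method=method, species="mu")
    return est


def estimate_rates(tc: TimeCourse, species=None, window=None,
                   dw_pg: float = DEFAULT_DW_PG, k_d: float = 0.0,
                   method: str = "robust", growth_name: str = "mu",
                   gln: str = "Gln", nh4: str = "NH4") -> pd.DataFrame:
    """Estimate all specific rates (plus growth) for one time course.

    Returns a DataFrame indexed by species with columns rate, stderr, method.
    With ``k_d > 0`` the Gln/NH4 series are decomposition-corrected first.
    """
    species = list(tc.species) if species is None else list(species)
    ivc = integral_viable_mass(tc, window, dw_pg)
    corrected = {}
    if k_d > 0 and gln in tc.C.columns and nh4 in tc.C.columns:
        corrected = correct_gln_decomposition(tc, k_d, gln, nh4, window)
    rows = {}
    for sp in species:
        formed = corrected.get(sp, None)
        if formed is None:
            formed = formed_quantity(tc, sp, window)
        est = estimate_rate(formed, ivc, method=method, species=sp)
        rows[sp] = {"rate": est.rate, "stderr": est.stderr, "method": method}
    mu = estimate_growth_rate(tc, window, dw_pg, method)
    rows[growth_name] = {"rate": mu.rate, "stderr": mu.stderr, "method": method}
    return pd.DataFrame.from_dict(rows, orient="index")


def dataset_statistics(ds: FluxDataset) -> pd.DataFrame:
    """Per-species mean, sample SD and CV(%) of a flux dataset.

    CV = 100·SD/|mean|; a zero mean yields CV = inf (undefined flag).
    """
    if ds.n_experiments < 2:
        raise ValueError("statistics need at least 2 experiments")
    mean = ds.data.mean(axis=0)
    sd = ds.data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        cv = 100.0 * sd.to_numpy() / np.abs(mean.to_numpy())
    cv = np.where(mean.to_numpy() == 0, np.inf, cv)
    return pd.DataFrame({"mean": mean, "sd": sd, "cv_pct": cv},
                        index=ds.species)
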