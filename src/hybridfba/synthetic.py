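"""Synthetic fixtures with known ground truth.

Three generators cover everything the package needs to be exercised without
external data: small metabolic networks with enumerable solution sets and
hand-computable yields, exchange-flux datasets whose variation lives on a
known low-dimensional latent subspace of the flux cone, and fed-batch time
courses with exponential growth, known specific rates and optional abiotic
glutamine decay.  Every generator is a pure function of (spec, seed).

The default dataset fixture mirrors the dimensions of a typical CHO
process-data campaign — 21 experiments by 27 measured exchange rates — so
that bookkeeping such as the "(27 − NPC)" degrees-of-freedom reduction of
the hybrid LP can be checked with the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from ._lp import solve_lp
from .fluxpca import FluxDataset
from .gem_io import GEMModel
from .rates import DEFAULT_DW_PG, TimeCourse, gdw_per_mcell

__all__ = ["SyntheticSpec", "make_toy_gem", "simulate_flux_dataset",
           "simulate_timecourse", "chebyshev_center"]

#: ground-truth specific rates for the default time-course fixture
#: (mmol/gDW/h; growth in 1/h), magnitudes typical of exponential-phase CHO
DEFAULT_RATE_TRUTH = {
    "mu": 2.82e-2, "Glc": -3.84e-1, "Lac": 2.56e-1,
    "Gln": -7.37e-2, "NH4": 5.92e-2,
}
DEFAULT_C0 = {"Glc": 45.0, "Lac": 2.0, "Gln": 8.0, "NH4": 1.0}


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults define the package's study fixture."""

    seed: int = 1
    n_experiments: int = 21
    latent_dim: int = 4
    noise_sd: float = 0.05          # relative (multiplicative) rate noise
    toy_topology: str = "cho-mini-27"
    signal_cv: float = 0.17         # target relative SD of the latent signal
    latent_decay: float = 0.95      # geometric decay of latent amplitudes
    growth_species: str = "mu"      # exchange species carrying the growth rate
    growth_cv: float = 0.10         # relative 1-sigma latent swing of growth
    growth_noise_sd: float = 0.01   # relative noise on the growth column
    growth_side: float = 0.03       # relative side-loading SD of the growth dir
    rate_truth: dict = field(default_factory=lambda: dict(DEFAULT_RATE_TRUTH))
    gln_kd: float = 0.0             # abiotic Gln decay constant, 1/h

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.gln_kd < 0:
            raise ValueError("gln_kd must be >= 0")


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

#: amino-acid-like side reactions of the 27-species model:
#: AAj -> a·PYR + b·NH4 (fixed coefficients, part of the model definition)
_AA_COEFS = [
    (1.2, 0.4), (0.8, 0.2), (1.5, 0.6), (0.6, 0.1), (1.0, 0.5),
    (0.9, 0.3), (1.3, 0.2), (0.7, 0.4), (1.1, 0.1), (0.5, 0.3),
    (1.4, 0.5), (0.8, 0.6), (1.0, 0.2), (0.6, 0.4), (1.2, 0.1),
    (0.9, 0.5), (0.7, 0.2), (1.1, 0.3), (0.5, 0.1), (1.3, 0.4),
]


def make_toy_gem(topology: str) -> GEMModel:
    """Construct a small metabolic model with known analytic structure.

    ``linear``
        A → M1 → M2 → biomass(+CO2, W); the flux distribution is unique once
        any one exchange rate is fixed.
    ``branched``
        A → M with a free split between byproduct secretion (M → B) and
        biomass (M → X + ½CO2); maximising biomass drives the split to its
        bound.
    ``cho-mini``
        7 reactions: glycolysis (Glc → 2 PYR), reversible lactate exchange,
        reversible pyruvate exchange, TCA proxy (PYR → 3 CO2), glutamine
        transport and glutaminolysis (GLN → PYR + NH4), and a biomass
        reaction 3 PYR + 0.2 GLN → mu.  With glucose uptake bounded by b and
        glutamine by q the maximal growth rate is (2b + q)/3.2.
    ``cho-mini-27``
        cho-mini extended with 20 irreversible amino-acid-like uptake
        reactions AAj → a·PYR + b·NH4, giving 27 reactions and 27 exchange
        species in total.
    """
    if topology == "linear":
        rxns = ["r_upt", "r_conv", "r_bio"]
        mets = ["M1", "M2"]
        ext = ["A", "mu", "CO2", "W"]
        S_int = np.array([[1.0, -1.0, 0.0],
                          [0.0, 1.0, -1.0]])
        S_ext = np.array([[-1.0, 0.0, 0.0],    # A consumed
                          [0.0, 0.0, 1.0],     # biomass
                          [0.0, 0.0, 0.5],     # CO2
                          [0.0, 0.0, 0.3]])    # W
        lb = np.zeros(3)
        ub = np.full(3, 10.0)
        return GEMModel(rxns, mets, ext, S_int, S_ext, lb, ub,
                        subsystem=["Transport", "Core", "Biomass"],
                        biomass_rxn="r_bio")

    if topology == "branched":
        rxns = ["r_upt", "r_byp", "r_bio"]
        mets = ["M"]
        ext = ["A", "B", "mu", "CO2"]
        S_int = np.array([[1.0, -1.0, -1.0]])
        S_ext = np.array([[-1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0],
                          [0.0, 0.0, 0.5]])
        lb = np.zeros(3)
        ub = np.full(3, 10.0)
        return GEMModel(rxns, mets, ext, S_int, S_ext, lb, ub,
                        subsystem=["Transport", "Overflow", "Biomass"],
                        biomass_rxn="r_bio")

    if topology in ("cho-mini", "cho-mini-27"):
        rxns = ["glyc", "ldh", "pyr_t", "tca", "gln_t", "glnase", "biomass"]
        mets = ["PYR", "GLN"]
        core_ext = ["Glc", "Lac", "Pyr", "CO2", "Gln", "NH4", "mu"]
        subsys = ["Glycolysis", "Glycolysis", "Transport", "TCA",
                  "Transport", "Glutaminolysis", "Biomass"]
        #                 glyc  ldh  pyr_t tca  gln_t glnase biomass
        S_int = np.array([
            [2.0, -1.0, -1.0, -1.0, 0.0, 1.0, -3.0],   # PYR
            [0.0, 0.0, 0.0, 0.0, 1.0, -1.0, -0.2],     # GLN
        ])
        S_ext = np.array([
            [-1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],      # Glc
            [0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],       # Lac
            [0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0],       # Pyr
            [0.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0],       # CO2
            [0.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0],      # Gln
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0],       # NH4
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0],       # mu
        ])
        lb = np.array([0.0, -10.0, -10.0, 0.0, 0.0, 0.0, 0.0])
        ub = np.full(7, 10.0)
        if topology == "cho-mini":
            return GEMModel(rxns, mets, core_ext, S_int, S_ext, lb, ub,
                            subsystem=subsys, biomass_rxn="biomass")

        n_aa = len(_AA_COEFS)
        aa_names = [f"AA{j+1:02d}" for j in range(n_aa)]
        rxns = rxns + [f"cat_{a}" for a in aa_names]
        subsys = subsys + ["AminoAcid"] * n_aa
        S_int = np.hstack([S_int, np.zeros((2, n_aa))])
        S_ext = np.hstack([S_ext, np.zeros((7, n_aa))])
        aa_rows = np.zeros((n_aa, 7 + n_aa))
        for j, (a, b) in enumerate(_AA_COEFS):
            S_int[0, 7 + j] = a           # PYR produced
            S_ext[5, 7 + j] = b           # NH4 produced
            aa_rows[j, 7 + j] = -1.0      # AAj consumed
        S_ext = np.vstack([S_ext, aa_rows])
        lb = np.concatenate([lb, np.zeros(n_aa)])
        ub = np.concatenate([ub, np.full(n_aa, 10.0)])
        return GEMModel(rxns, mets, core_ext + aa_names, S_int, S_ext, lb, ub,
                        subsystem=subsys, biomass_rxn="biomass")

    raise ValueError(f"unknown topology {topology!r}")


# ---------------------------------------------------------------------------
# flux datasets with known latent structure
# ---------------------------------------------------------------------------

def chebyshev_center(model: GEMModel) -> np.ndarray:
    """A strictly interior point of {S_int v = 0, lb ≤ v ≤ ub}.

    Maximises the uniform slack t with lb + t ≤ v ≤ ub − t; the returned
    point keeps every flux away from its bounds so it can serve as the base
    of latent perturbations.
    """
    n = model.n_reactions
    # variables x = [v, t]
    A_eq = np.hstack([model.S_int, np.zeros((model.S_int.shape[0], 1))])
    rows, rhs = [], []
    for j in range(n):
        e = np.zeros(n + 1)
        e[j], e[n] = -1.0, 1.0
        rows.append(e.copy())
        rhs.append(-model.lb[j])
        e[j] = 1.0
        rows.append(e)
        rhs.append(model.ub[j])
    c = np.zeros(n + 1)
    c[n] = 1.0
    res = solve_lp(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                   A_ub=np.array(rows), b_ub=np.array(rhs),
                   bounds=[(None, None)] * n + [(0, None)], sense="max")
    if res.status != 0 or res.x[n] <= 0:
        raise RuntimeError("model has no strictly interior flux distribution")
    return res.x[:n]


def simulate_flux_dataset(model: GEMModel, spec: SyntheticSpec,
                          base_scale: float = 0.08):
    """Draw an exchange-flux dataset whose variation is rank-``latent_dim``.

    A strictly interior base flux ``v0`` (a scaled Chebyshev centre of the
    flux polytope) anchors the dataset.  ``latent_dim`` flux-space directions
    are built inside the null space of ``S_int`` so that every sampled point
    satisfies the balances by construction; their exchange-space loadings are
    shaped to give each species a latent signal of relative SD ``signal_cv``
    with geometrically decaying per-component amplitudes.  Samples violating
    a flux bound are redrawn (latent coordinates are standard normal clipped
    at ±3); multiplicative Gaussian noise of SD ``noise_sd`` is added to the
    exchange rates afterwards.

    Returns ``(FluxDataset, truth)`` where ``truth`` records the base rates,
    flux directions, exchange loadings and latent coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    v0 = base_scale * chebyshev_center(model)
    r0 = model.S_ext @ v0

    d = spec.latent_dim
    g_idx = (model.species_index(spec.growth_species)
             if spec.growth_species in model.exchange_species else None)

    # Latent structure: d−1 "metabolic variation" directions that leave the
    # growth flux untouched (they live in the null space of S_int extended
    # with the biomass-flux selector), plus one weaker "productivity"
    # direction — a uniform scaling of the whole base flux state — that is
    # the only component moving growth.  This mirrors the empirical pattern
    # that exponential-phase growth varies far less than the metabolite
    # exchange rates and makes the growth-relevant component identifiable.
    S_con = model.S_int
    if g_idx is not None and model.biomass_rxn is not None:
        e_bio = np.zeros((1, model.n_reactions))
        e_bio[0, model.reaction_index(model.biomass_rxn)] = 1.0
        S_con = np.vstack([model.S_int, e_bio]) if model.S_int.size else e_bio
    N = null_space(S_con) if S_con.size else np.eye(model.n_reactions)
    n_generic = d - 1 if g_idx is not None else d
    if N.shape[1] < n_generic:
        raise ValueError(f"latent_dim={spec.latent_dim} exceeds the null-space "
                         f"dimension {N.shape[1]}")
    E = model.S_ext @ N                       # achievable exchange directions
    if np.any(r0 == 0):
        raise RuntimeError("base flux state has a zero exchange rate; "
                           "relative loading scaling is undefined")

    decay = spec.latent_decay ** np.arange(max(n_generic, 1))
    if g_idx is None:
        # orthonormal columns scaled by the decay profile: in autoscaled
        # space the per-component variance shares are ~decay²/Σdecay²
        Q, _ = np.linalg.qr(rng.standard_normal((len(r0), n_generic)))
        target = (spec.signal_cv * np.abs(r0)[:, None] * np.sqrt(len(r0))
                  * Q * decay / np.linalg.norm(decay))
        Z, *_ = np.linalg.lstsq(E, target, rcond=None)
        D = N @ Z
    else:
        # Construct the loadings to be orthogonal in the *autoscaled* metric
        # so the PCA recovers the components without rotation.  sd_hat is the
        # per-species SD the design aims at; the scaled productivity vector
        # p_tilde is fixed by the mechanism (a uniform scaling of v0), and
        # the generic components are drawn from the achievable biomass-free
        # subspace orthogonal to it.  Vectors in that subspace have an
        # exactly zero growth coordinate, so only the productivity component
        # moves the growth rate.
        sig_tot = np.sqrt(spec.signal_cv**2 + spec.growth_side**2
                          + spec.noise_sd**2)
        sd_hat = sig_tot * np.abs(r0)
        sd_hat[g_idx] = (np.sqrt(spec.growth_cv**2 + spec.growth_noise_sd**2)
                         * abs(r0[g_idx]))
        from scipy.linalg import orth

        # growth direction: the most parsimonious flux re-allocation that
        # changes growth — minimise the (scaled) exchange loadings of all
        # other species subject to the prescribed growth swing, inside
        # null(S_int).  Its side-loadings are then only what stoichiometry
        # strictly requires, keeping the growth component well separated
        # from the metabolic-variation components.
        N_f = null_space(model.S_int) if model.S_int.size else np.eye(model.n_reactions)
        A_ex = model.S_ext @ N_f
        W = np.delete(A_ex / sd_hat[:, None], g_idx, axis=0)
        a_mu = A_ex[g_idx]
        g_swing = spec.growth_cv * abs(r0[g_idx])
        H = 2.0 * W.T @ W + 1e-12 * np.eye(W.shape[1])
        kkt = np.block([[H, a_mu[:, None]], [a_mu[None, :], np.zeros((1, 1))]])
        sol = np.linalg.lstsq(kkt, np.concatenate([np.zeros(W.shape[1]),
                                                   [g_swing]]), rcond=None)[0]
        d_growth = N_f @ sol[:W.shape[1]]
        if spec.growth_side > 0:
            # blend in a uniform-productivity component so the growth
            # direction carries a controlled side-loading on every species,
            # then rescale to the prescribed growth swing
            blended = d_growth + (spec.growth_side / spec.growth_cv) * \
                (g_swing / abs(r0[g_idx])) * v0
        else:
            blended = d_growth
        mu_swing = (model.S_ext @ blended)[g_idx]
        d_growth = blended * (g_swing / mu_swing)

        B = orth(E / sd_hat[:, None])         # scaled achievable subspace
        p_tilde = (model.S_ext @ d_growth) / sd_hat
        c_coord = B.T @ p_tilde
        Y = rng.standard_normal((B.shape[1], n_generic))
        if c_coord @ c_coord > 0:
            Y -= np.outer(c_coord, c_coord @ Y) / (c_coord @ c_coord)
        Qy, _ = np.linalg.qr(Y)
        G_tilde = B @ Qy[:, :n_generic]       # unit, mutually ⊥, ⊥ p_tilde
        # amplitudes: total generic energy matches signal_cv, split by decay
        a_total = np.linalg.norm(spec.signal_cv * np.abs(r0) / sd_hat)
        amps = a_total * decay / np.linalg.norm(decay)
        # balance per-species energies by alternating projections: without
        # this the χ²-like spread of row energies depresses the explained
        # variance captured by the latent components
        row_target = spec.signal_cv * np.abs(r0) / sd_hat
        row_target[g_idx] = 0.0
        M = G_tilde * amps
        for _ in range(50):
            norms = np.linalg.norm(M, axis=1)
            M = M * np.divide(row_target, norms, out=np.ones_like(norms),
                              where=norms > 0)[:, None]
            Ym = B.T @ M
            if c_coord @ c_coord > 0:
                Ym -= np.outer(c_coord, c_coord @ Ym) / (c_coord @ c_coord)
            M = B @ Ym
            U, _, Vt = np.linalg.svd(M, full_matrices=False)
            M = (U @ Vt) * amps               # nearest orthogonal-column frame
        L = M * sd_hat[:, None]               # back to rate units
        Z, *_ = np.linalg.lstsq(E, L, rcond=None)
        D = np.hstack([N @ Z, d_growth[:, None]])
    loadings = model.S_ext @ D                # achieved exchange loadings

    n = spec.n_experiments
    if n <= d:
        raise ValueError("need more experiments than latent dimensions")
    # sample-orthogonal latent design: QR of a centred Gaussian matrix,
    # rescaled to exactly zero mean, unit sample variance and zero sample
    # correlation — at n = 21 this avoids the ~1/√n spurious correlation
    # an iid draw would inject between components
    T_raw = rng.standard_normal((n, d))
    T_raw -= T_raw.mean(axis=0)
    Qt, _ = np.linalg.qr(T_raw)
    latents = Qt[:, :d] * np.sqrt(n - 1)
    pert = latents @ D.T
    # if a perturbation would leave the flux box, shrink all amplitudes by a
    # common factor (keeps the design orthogonal; recorded via the loadings)
    with np.errstate(divide="ignore", invalid="ignore"):
        room = np.where(pert > 0, (model.ub - v0) / pert,
                        np.where(pert < 0, (model.lb - v0) / pert, np.inf))
    scale = min(1.0, 0.95 * np.min(room))
    if scale <= 0:
        raise RuntimeError("base flux state has no room for perturbations")
    D = scale * D
    loadings = scale * loadings
    samples = v0 + scale * pert
    # feasibility certificate: bounds hold and the balances are exact
    if model.S_int.size:
        assert np.max(np.abs(samples @ model.S_int.T)) < 1e-9

    R = samples @ model.S_ext.T
    noise = np.full(R.shape[1], spec.noise_sd)
    if g_idx is not None:
        # growth is estimated from the whole cell-density profile and is far
        # more precise than the per-metabolite rates
        noise[g_idx] = spec.growth_noise_sd
    R_noisy = R * (1.0 + noise * rng.standard_normal(R.shape))
    data = pd.DataFrame(R_noisy, columns=model.exchange_species,
                        index=[f"exp{i+1:02d}" for i in range(n)])
    truth = {"v0": v0, "base_rates": pd.Series(r0, index=model.exchange_species),
             "directions": D, "loadings": pd.DataFrame(
                 loadings, index=model.exchange_species,
                 columns=[f"latent{j+1}" for j in range(d)]),
             "latents": latents, "noise_free_rates": pd.DataFrame(
                 R, columns=model.exchange_species, index=data.index)}
    if g_idx is not None:
        # growth of the most productive state the generating process supports
        # (latent coordinates are clipped at ±3)
        truth["max_supported_growth"] = float(
            r0[g_idx] + 3.0 * np.abs(loadings[g_idx]).sum())
        truth["base_growth"] = float(r0[g_idx])
    return FluxDataset(data), truth


# ---------------------------------------------------------------------------
# fed-batch time courses
# ---------------------------------------------------------------------------

def simulate_timecourse(rate_truth=None, spec: SyntheticSpec | None = None,
                        x0: float = 1.0, v0_ml: float = 1000.0,
                        c0: dict | None = None, t_end: float = 72.0,
                        dt_sample: float = 6.0, noise_cv: float = 0.0,
                        bolus: dict | None = None, bolus_interval: float = 24.0,
                        dw_pg: float = DEFAULT_DW_PG,
                        growth_name: str = "mu", gln: str = "Gln",
                        nh4: str = "NH4"):
    """Simulate a fed-batch exponential-growth phase with known rates.

    Growth is exactly exponential at the true µ; concentrations follow
    d(C·V)/dt = q·B(t) (+ boluses, − first-order abiotic Gln decay with
    equimolar NH4 production when ``spec.gln_kd > 0``).  The ODEs are
    integrated by RK4 on a 0.01 h grid and sampled every ``dt_sample`` hours.
    ``bolus`` maps species to mmol added at every ``bolus_interval``.
    Optional multiplicative measurement noise (``noise_cv``) applies to the
    sampled concentrations.  If a concentration would go negative the
    horizon is shortened and the truncation recorded in the truth dict.

    Returns ``(TimeCourse, truth)``.
    """
    spec = spec if spec is not None else SyntheticSpec()
    truth_rates = dict(spec.rate_truth if rate_truth is None else rate_truth)
    if growth_name not in truth_rates:
        raise ValueError(f"rate_truth must include the growth rate {growth_name!r}")
    mu = float(truth_rates[growth_name])
    species = [s for s in truth_rates if s != growth_name]
    q = np.array([truth_rates[s] for s in species])
    c0 = dict(DEFAULT_C0) if c0 is None else dict(c0)
    missing = set(species) - set(c0)
    if missing:
        raise ValueError(f"initial concentrations missing for {sorted(missing)}")
    kd = spec.gln_kd
    i_gln = species.index(gln) if gln in species else None
    i_nh4 = species.index(nh4) if nh4 in species else None

    rng = np.random.default_rng(spec.seed)
    dt = 0.01
    n_fine = int(round(t_end / dt))
    B0 = x0 * v0_ml * gdw_per_mcell(dw_pg)            # gDW

    A = np.array([c0[s] for s in species]) * v0_ml / 1000.0   # mmol
    feeds = []
    t_samples = [0.0]
    rows = [A.copy()]
    truncated_at = None

    def deriv(t, A_):
        dA = q * (B0 * np.exp(mu * t))
        if kd > 0 and i_gln is not None:
            loss = kd * A_[i_gln]
            dA[i_gln] -= loss
            if i_nh4 is not None:
                dA = dA.copy()
                dA[i_nh4] += loss
        return dA

    for step in range(n_fine):
        t = step * dt
        k1 = deriv(t, A)
        k2 = deriv(t + dt / 2, A + dt / 2 * k1)
        k3 = deriv(t + dt / 2, A + dt / 2 * k2)
        k4 = deriv(t + dt, A + dt * k3)
        A = A + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_next = (step + 1) * dt
        if bolus and np.isclose(t_next % bolus_interval, 0.0, atol=dt / 2) \
                and t_next < t_end:
            for sp, mmol in bolus.items():
                A[species.index(sp)] += mmol
                feeds.append({"time": t_next, "species": sp, "mmol": mmol})
        if np.any(A < 0):
            truncated_at = t_next
            break
        if np.isclose(t_next % dt_sample, 0.0, atol=dt / 2):
            t_samples.append(t_next)
            rows.append(A.copy())

    t_arr = np.array(t_samples)
    amounts = np.array(rows)
    C = amounts * 1000.0 / v0_ml                     # back to mM (V constant)
    if noise_cv > 0:
        C = C * (1.0 + noise_cv * rng.standard_normal(C.shape))
    Xv = x0 * np.exp(mu * t_arr)
    feeds_df = (pd.DataFrame(feeds) if feeds
                else pd.DataFrame(columns=["time", "species", "mmol"]))
    if len(feeds_df):
        feeds_df = feeds_df[feeds_df["time"] <= t_arr[-1]]
    tc = TimeCourse(t=t_arr, Xv=Xv, V=np.full_like(t_arr, v0_ml),
                    C=pd.DataFrame(C, columns=species), feeds=feeds_df)
    truth = {"mu": mu, "rates": pd.Series(truth_rates), "kd": kd,
             "dw_pg": dw_pg, "truncated_at": truncated_at}
    return tc, truth
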