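import numpy as np
import pandas as pd
import pytest

import hybridfba as h
from hybridfba.hybridcore import (Scenario, build_problem, calibrate,
                                  check_degeneracy, exchange_objective, fva,
                                  minmax_interval, pca_band_slack,
                                  shadow_prices, solve, standard_scenarios,
                                  subsystem_activity, biomass_sensitivity,
                                  CalibrationError)
from helpers import vertex_optimum, vertex_flux_ranges


def hand_yield(b, q):
    """cho-mini maximal growth with Glc uptake <= b, Gln uptake <= q and
    lactate/pyruvate uptake closed: pyruvate- or glutamine-limited."""
    return min((2 * b + q) / 3.2, 5 * q)


def bounded_cho(cho_mini, b=1.0, q=0.5):
    return Scenario("hand", [], fixed={
        "Glc": (-b, 0.0), "Gln": (-q, 0.0),
        "Lac": (0.0, 10.0), "Pyr": (0.0, 10.0)})


class TestBuildProblem:
    def test_npc_zero_is_plain_fba(self, cho_mini):
        prob = build_problem(cho_mini, objective="biomass")
        c, A_eq, b_eq, A_ub, b_ub, bounds, labels = prob.arrays()
        assert prob.n_vars == cho_mini.n_reactions
        assert A_ub is None and labels == []
        assert A_eq.shape == cho_mini.S_int.shape

    def test_rf_zero_collapses_band_to_equality(self, cho27, fitted_pca):
        prob = build_problem(cho27, pca=fitted_pca, npc=2, rf=0.0,
                             objective="biomass")
        _, _, _, A_ub, b_ub, _, labels = prob.arrays()
        for i in range(0, 2 * len(fitted_pca.species), 2):
            up, lo = b_ub[i], -b_ub[i + 1]
            assert up == pytest.approx(lo)     # zero-width band

    def test_constraint_blocks_match_hand_assembly(self, cho27, fitted_pca):
        npc = 2
        prob = build_problem(cho27, pca=fitted_pca, npc=npc, rf=1.5,
                             objective="biomass")
        _, _, _, A_ub, b_ub, _, labels = prob.arrays()
        sig = fitted_pca.sigma.to_numpy()
        mu = fitted_pca.mu.to_numpy()
        coeff = fitted_pca.coeff.to_numpy()[:, :npc]
        for i, sp in enumerate(fitted_pca.species):
            hand = np.concatenate([cho27.S_ext[cho27.species_index(sp)],
                                   -sig[i] * coeff[i]])
            np.testing.assert_allclose(A_ub[2 * i], hand)
            np.testing.assert_allclose(A_ub[2 * i + 1], -hand)
            assert b_ub[2 * i] == pytest.approx(mu[i] + 1.5 * sig[i])
            assert b_ub[2 * i + 1] == pytest.approx(-(mu[i] - 1.5 * sig[i]))

    def test_npc_beyond_available_components_rejected(self, cho27, fitted_pca):
        with pytest.raises(ValueError, match="exceeds"):
            build_problem(cho27, pca=fitted_pca, npc=100, objective="biomass")

    def test_misaligned_species_rejected(self, cho_mini, fitted_pca):
        # the 27-species PCA names species absent from the 7-species model
        with pytest.raises(ValueError, match="AA01"):
            build_problem(cho_mini, pca=fitted_pca, npc=2, objective="biomass")


class TestSolve:
    @pytest.mark.parametrize("b,q", [(1.0, 0.5), (1.0, 0.1), (0.5, 2.0)])
    def test_hand_computed_yield(self, cho_mini, b, q):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini, b, q),
                             objective="biomass")
        sol = solve(prob, "max")
        assert sol.status == "optimal"
        assert sol.J == pytest.approx(hand_yield(b, q), abs=1e-9)

    def test_matches_vertex_enumeration(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini),
                             objective="biomass")
        sol = solve(prob, "max")
        j_vertex, _ = vertex_optimum(prob)
        assert sol.J == pytest.approx(j_vertex, abs=1e-9)

    def test_all_exchanges_closed_gives_zero(self, cho_mini):
        sc = Scenario("closed", [], fixed={s: (0.0, 0.0)
                                           for s in cho_mini.exchange_species})
        sol = solve(build_problem(cho_mini, scenario=sc, objective="biomass"))
        assert sol.J == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sol.v, 0.0, atol=1e-9)

    def test_huge_rf_recovers_standard_fba(self, cho27, fitted_pca,
                                           fixture_stats):
        sc = standard_scenarios(fixture_stats["mean"])[0]
        kw = dict(scenario=sc, r_mean=fixture_stats["mean"],
                  sigma=fixture_stats["sd"], objective="biomass")
        fba = solve(build_problem(cho27, **kw), "max")
        hyb = solve(build_problem(cho27, pca=fitted_pca, npc=4, rf=1e6,
                                  score_bound_mult=1e9, **kw), "max")
        assert hyb.J == pytest.approx(fba.J, abs=1e-6)

    def test_infeasible_problem_diagnosed(self, cho_mini):
        # no carbon or nitrogen source but growth demanded
        sc = Scenario("bad", [], fixed={"Glc": (0.0, 0.0), "Gln": (0.0, 0.0),
                                        "Lac": (0.0, 10.0), "Pyr": (0.0, 10.0),
                                        "mu": (1.0, 2.0)})
        sol = solve(build_problem(cho_mini, scenario=sc, objective="biomass"))
        assert sol.status == "infeasible"
        assert "exchange bounds" in sol.message


class TestShadowPrices:
    def test_binding_substrate_bound_prices_growth(self, cho_mini):
        # glutamine-limited optimum: mu* = 5q, so relaxing the Gln uptake
        # bound by one unit must raise growth by 5
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini, 1.0, 0.1),
                             objective="biomass")
        sol = solve(prob, "max")
        mult = sol.multipliers.set_index(["group", "name", "side"])["price"]
        assert mult[("exchange", "Gln", "lower")] == pytest.approx(5.0, abs=1e-8)

    def test_nonbinding_constraint_has_zero_price(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini, 1.0, 0.1),
                             objective="biomass")
        sol = solve(prob, "max")
        mult = sol.multipliers.set_index(["group", "name", "side"])["price"]
        # glucose is not limiting in the glutamine-limited regime
        assert mult[("exchange", "Glc", "lower")] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("b,q", [(1.0, 0.1), (1.0, 0.5)])
    def test_prices_match_finite_differences(self, cho_mini, b, q):
        delta = 1e-5
        base = bounded_cho(cho_mini, b, q)
        sol = solve(build_problem(cho_mini, scenario=base, objective="biomass"))
        mult = sol.multipliers.set_index(["group", "name", "side"])["price"]
        for sp, bound in [("Glc", b), ("Gln", q)]:
            relaxed = Scenario("d", [], fixed={**base.fixed,
                                               sp: (-(dict(Glc=b, Gln=q)[sp] + delta), 0.0)})
            sol2 = solve(build_problem(cho_mini, scenario=relaxed,
                                       objective="biomass"))
            fd = (sol2.J - sol.J) / delta
            assert mult[("exchange", sp, "lower")] == pytest.approx(fd, abs=1e-6)

    def test_ranking_and_degeneracy_flag(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini),
                             objective="biomass")
        sol = solve(prob, "max")
        table = shadow_prices(sol)
        prices = table["price"].abs().to_numpy()
        assert all(prices[:-1] >= prices[1:])
        check_degeneracy(prob, sol)
        if sol.degenerate:
            with pytest.warns(UserWarning, match="degenerate"):
                shadow_prices(sol)


class TestMinMaxAndNesting:
    def test_fully_determined_problem_has_point_interval(self, linear_model):
        sc = Scenario("fix", [], fixed={"A": (-1.0, -1.0)})
        prob = build_problem(linear_model, scenario=sc, objective="r_bio")
        mm = minmax_interval(prob)
        assert mm.j_min == pytest.approx(mm.j_max, abs=1e-9)
        assert mm.half_interval == pytest.approx(1.0, abs=1e-9)

    def test_hybrid_interval_nested_in_fba_interval(self, cho27, fitted_pca,
                                                    fixture_stats):
        for sc in standard_scenarios(fixture_stats["mean"]):
            kw = dict(scenario=sc, r_mean=fixture_stats["mean"],
                      sigma=fixture_stats["sd"], objective="biomass")
            fba = minmax_interval(build_problem(cho27, **kw))
            hyb = minmax_interval(build_problem(cho27, pca=fitted_pca, npc=4,
                                                rf=1.0, **kw))
            assert hyb.j_min >= fba.j_min - 1e-9, sc.name
            assert hyb.j_max <= fba.j_max + 1e-9, sc.name

    def test_wider_k_never_shrinks_fba_interval(self, cho27, fixture_stats):
        non_growth = [s for s in cho27.exchange_species if s != "mu"]
        widths = []
        for k in (1, 2, 3, 4, 6):
            sc = Scenario(f"k{k}", non_growth, float(k))
            mm = minmax_interval(build_problem(
                cho27, scenario=sc, r_mean=fixture_stats["mean"],
                sigma=fixture_stats["sd"], objective="biomass"))
            widths.append((mm.j_min, mm.j_max))
        for (lo1, hi1), (lo2, hi2) in zip(widths, widths[1:]):
            assert lo2 <= lo1 + 1e-9
            assert hi2 >= hi1 - 1e-9

    def test_rf_sweep_monotone_and_convergent(self, cho27, fitted_pca,
                                              fixture_stats):
        sc = standard_scenarios(fixture_stats["mean"])[4]
        kw = dict(scenario=sc, r_mean=fixture_stats["mean"],
                  sigma=fixture_stats["sd"], objective="biomass")
        fba = solve(build_problem(cho27, **kw), "max").J
        prev = -np.inf
        for rf in (0.25, 0.5, 1, 2, 4, 16, 64, 1e3):
            j = solve(build_problem(cho27, pca=fitted_pca, npc=4, rf=rf,
                                    score_bound_mult=1e6, **kw), "max").J
            assert j >= prev - 1e-9
            prev = j
        assert prev == pytest.approx(fba, abs=1e-6)


class TestCalibrate:
    def test_recovers_generating_latent_dimension(self, cho27, fitted_pca,
                                                  fixture_stats, default_fixture):
        _, truth, _ = default_fixture
        scens = standard_scenarios(fixture_stats["mean"])
        cal = calibrate(cho27, fitted_pca, scens[4], range(0, 9),
                        [0.25, 0.5, 1.0, 2.0], truth["max_supported_growth"],
                        fixture_stats["mean"], fixture_stats["sd"],
                        scenarios=scens, rf_small=0.25)
        assert cal.npc == 4
        assert cal.rf in (0.25, 0.5, 1.0, 2.0)
        assert {"stage", "npc", "rf", "prediction", "feasible"} <= set(cal.table)

    def test_rf_feasibility_boundary(self, cho27, fitted_pca, fixture_stats):
        # pin eight exchange rates 0.3 sigma away from their band centres:
        # with 4 scores the 8 exact-match conditions of RF = 0 are
        # overdetermined, while RF >= 0.5 absorbs the offsets
        mean, sd = fixture_stats["mean"], fixture_stats["sd"]
        pinned = [f"AA{i:02d}" for i in range(1, 9)]
        sc = Scenario("pinned", [], fixed={
            sp: (mean[sp] + 0.3 * sd[sp], mean[sp] + 0.3 * sd[sp])
            for sp in pinned})
        ref = mean["mu"]
        cal = calibrate(cho27, fitted_pca, sc, [4], [0.0, 0.5, 1.0], ref,
                        fixture_stats["mean"], fixture_stats["sd"],
                        rf_small=0.5)
        assert cal.rf == 0.5
        table = cal.table[cal.table.stage == "rf"]
        assert not table[table.rf == 0.0].feasible.any()

    def test_tie_breaks_toward_smaller_npc(self, cho27, fitted_pca,
                                           fixture_stats):
        sc = standard_scenarios(fixture_stats["mean"])[4]
        fba_pred = solve(build_problem(cho27, scenario=sc,
                                       r_mean=fixture_stats["mean"],
                                       sigma=fixture_stats["sd"],
                                       objective="biomass"), "max").J
        cal = calibrate(cho27, fitted_pca, sc, [0, 1, 2], [0.5], fba_pred,
                        fixture_stats["mean"], fixture_stats["sd"])
        assert cal.npc == 0

    def test_empty_grid_rejected(self, cho27, fitted_pca, fixture_stats):
        with pytest.raises(ValueError):
            calibrate(cho27, fitted_pca, Scenario("s", []), [], [1.0], 0.0,
                      fixture_stats["mean"], fixture_stats["sd"])


class TestFVA:
    def test_stoichiometrically_fixed_reaction_has_point_range(self, linear_model):
        sc = Scenario("fix", [], fixed={"A": (-1.0, -1.0)})
        prob = build_problem(linear_model, scenario=sc, objective="r_bio")
        ranges = fva(prob, tol=0.0)
        np.testing.assert_allclose(ranges["v_min"], ranges["v_max"], atol=1e-9)

    def test_optimal_face_contains_solver_flux(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini),
                             objective="biomass")
        sol = solve(prob, "max")
        ranges = fva(prob, j_opt=sol.J, tol=0.0)
        for r in cho_mini.reaction_ids:
            assert ranges.loc[r, "v_min"] - 1e-8 <= sol.v[r] <= ranges.loc[r, "v_max"] + 1e-8

    def test_ranges_match_vertex_oracle(self, branched_model):
        sc = Scenario("b", [], fixed={"A": (-2.0, 0.0)})
        prob = build_problem(branched_model, scenario=sc, objective="r_bio")
        sol = solve(prob, "max")
        ranges = fva(prob, j_opt=sol.J, tol=0.05)
        # oracle: add the objective band to the polytope and enumerate
        from dataclasses import replace
        import helpers
        c, A_eq, b_eq, G, hvec = helpers.problem_polytope(prob)
        band = np.vstack([c, -c])
        lo, hi = 0.95 * sol.J, 1.05 * sol.J
        G2 = np.vstack([G, band])
        h2 = np.concatenate([hvec, [hi, -lo]])
        V = helpers.enumerate_vertices(A_eq, b_eq, G2, h2, prob.n_vars)
        np.testing.assert_allclose(ranges["v_min"], V.min(axis=0), atol=1e-9)
        np.testing.assert_allclose(ranges["v_max"], V.max(axis=0), atol=1e-9)

    def test_negative_objective_band_ordered_by_value(self, cho_mini):
        # minimise byproduct secretion at pinned growth: negative optimum
        sc = Scenario("opt", [], fixed={"Glc": (-1.0, 0.0), "Gln": (-0.5, 0.0),
                                        "mu": (0.4, 0.42)})
        c_v = exchange_objective(cho_mini, {"Lac": 1.0, "NH4": 1.0, "Pyr": 1.0})
        prob = build_problem(cho_mini, scenario=sc, objective=c_v)
        sol = solve(prob, "min")
        assert sol.J < 0
        ranges = fva(prob, j_opt=sol.J, tol=0.05, sense="min")
        assert (ranges["v_min"] <= ranges["v_max"] + 1e-12).all()


class TestStructuralAccounting:
    def test_eq7_band_contract_at_optima(self, cho27, fitted_pca, fixture_stats):
        for sc in standard_scenarios(fixture_stats["mean"])[:4]:
            for rf in (0.5, 1.0):
                prob = build_problem(cho27, pca=fitted_pca, npc=4, rf=rf,
                                     scenario=sc, r_mean=fixture_stats["mean"],
                                     sigma=fixture_stats["sd"], objective="biomass")
                sol = solve(prob, "max")
                eps = pca_band_slack(prob, sol)
                ratio = (eps.abs() / fitted_pca.sigma).max()
                assert ratio <= rf + 1e-7

    @pytest.mark.parametrize("npc", [1, 4, 6])
    def test_freedom_reduction_is_species_minus_npc(self, cho27, fitted_pca,
                                                    npc):
        prob = build_problem(cho27, pca=fitted_pca, npc=npc, objective="biomass")
        _, _, _, A_ub, _, _, labels = prob.arrays()
        n_bands = sum(1 for g, _, side in labels if g == "pca" and side == "upper")
        n_scores = prob.n_vars - cho27.n_reactions
        assert n_bands == 27
        assert n_bands - n_scores == 27 - npc


class TestSubsystemActivity:
    def test_zero_flux_zero_activity(self, cho_mini):
        act = subsystem_activity(np.zeros(7), cho_mini)
        assert (act["activity"] == 0).all()

    def test_homogeneity(self, cho_mini):
        v = np.arange(1.0, 8.0)
        a1 = subsystem_activity(v, cho_mini)["activity"]
        a2 = subsystem_activity(2 * v, cho_mini)["activity"]
        np.testing.assert_allclose(a2, 2 * a1)

    def test_hand_summed_activities_and_delta(self, cho_mini):
        v = np.array([1.0, -0.5, 0.2, 0.3, 0.4, 0.1, 0.25])
        act = subsystem_activity(v, cho_mini, reference_flux_vector=np.zeros(7))
        assert act.loc["Glycolysis", "activity"] == pytest.approx(1.5)
        assert act.loc["Transport", "activity"] == pytest.approx(0.6)
        np.testing.assert_allclose(act["delta"], act["activity"])

    def test_unannotated_reactions_grouped(self, cho_mini):
        m = cho_mini.copy()
        m.subsystem = [""] * m.n_reactions
        act = subsystem_activity(np.ones(7), m)
        assert list(act.index) == ["unassigned"]


class TestBiomassSensitivity:
    def test_fixed_seed_reproducible(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini),
                             objective="biomass")
        s1 = biomass_sensitivity(prob, 0.1, n_draws=10, seed=3)
        s2 = biomass_sensitivity(prob, 0.1, n_draws=10, seed=3)
        np.testing.assert_array_equal(s1.J_values, s2.J_values)

    def test_vanishing_perturbation_gives_vanishing_spread(self, cho_mini):
        prob = build_problem(cho_mini, scenario=bounded_cho(cho_mini),
                             objective="biomass")
        small = biomass_sensitivity(prob, 1e-6, n_draws=8, seed=1)
        assert small.J_sd < 1e-5
        assert small.flux_sd.max() < 1e-4

    def test_growth_less_affected_than_overflow_fluxes(self, cho_mini):
        # growth pinned to a narrow band: composition uncertainty must be
        # absorbed by the low-magnitude overflow fluxes, not the objective
        sc = Scenario("pinned", [], fixed={"Glc": (-1.0, 0.0),
                                           "Gln": (-0.5, 0.0),
                                           "mu": (0.40, 0.42)})
        prob = build_problem(cho_mini, scenario=sc, objective="biomass")
        summ = biomass_sensitivity(prob, 0.1, n_draws=30, seed=7)
        rel_J = summ.J_sd / abs(np.mean(summ.J_values))
        assert rel_J < 0.05
        assert summ.flux_sd.drop("biomass").max() > 10 * summ.J_sd
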