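"""Scenario application, msMSY grid search and baseline comparison."""

import numpy as np
import pytest

import trophomsy as T
from conftest import eq3_rhs_manual


def brute_force_msy(model, params, prices, fine_step=0.01, grid_max=5.0, years=200):
    """Independent maximizer: equilibrium catch at each fine factor found by
    root-finding on an independently coded right-hand side, not by the scan
    or the integrator."""
    from scipy.optimize import fsolve

    P = params
    live = [i for i, k in enumerate(P.kinds) if k != "detritus"]
    best_x, best_c = None, -np.inf
    scope_F = P.base_F[:, [bool(s) for s in P.fleet_scope]].sum(axis=1)
    guess = [P.B0[i] for i in live]
    x = fine_step
    while x <= grid_max + 1e-9:
        def rhs(b_live, x=x):
            B = P.B0.copy()
            for k, i in enumerate(live):
                B[i] = np.maximum(b_live[k], 1e-12)
            return eq3_rhs_manual(model, P, B, effort_factor=x)[live]

        sol, info, ier, _ = fsolve(rhs, guess, full_output=True)
        if ier == 1 and (np.asarray(sol) > 0).all():
            B = P.B0.copy()
            for k, i in enumerate(live):
                B[i] = sol[k]
            catch = float((scope_F * x * B)[live].sum())
            if catch > best_c + 1e-12:
                best_c, best_x = catch, x
            guess = sol
        x = round(x + fine_step, 10)
    return best_x


class TestApplyScenario:
    def test_pp_scenario_touches_only_producers(self, web1):
        model, _, P = web1
        spec = T.ScenarioSpec(name="pp", producer_multiplier=0.7,
                              scope_species=T.SCOPE_SPECIES)
        p2, forcing = T.apply_scenario(model, P, spec)
        np.testing.assert_array_equal(p2.K, P.K)
        assert not forcing.forced_biomass
        assert set(forcing.producer_multiplier) == {"phytoplankton"}
        assert forcing.producer_multiplier["phytoplankton"](100.0) == 0.7

    def test_mammal_scenarios_force_and_override(self, web1):
        model, _, P = web1
        for spec in T.standard_scenarios(T.SCOPE_SPECIES):
            if not spec.name.startswith("mammals"):
                continue
            p2, forcing = T.apply_scenario(model, P, spec)
            i_seal = P.index("seals")
            assert forcing.forced_biomass["seals"](50.0) == pytest.approx(
                5.76 * P.B0[i_seal])
            expected_porp = 2.09 if spec.name.endswith("with_drift") else 1.46
            assert forcing.forced_biomass["porpoises"](50.0) == pytest.approx(
                expected_porp * P.B0[P.index("porpoises")])
            assert (p2.K[:, i_seal] == 2.0).all()
            # only the seal column changes
            mask = np.ones(P.K.shape[1], bool)
            mask[i_seal] = False
            np.testing.assert_array_equal(p2.K[:, mask], P.K[:, mask])

    def test_unknown_group_rejected(self, web1):
        model, _, P = web1
        spec = T.ScenarioSpec(name="bad", forced_biomass_multipliers={"krill": 2.0},
                              scope_species=T.SCOPE_SPECIES)
        with pytest.raises(KeyError, match="krill"):
            T.apply_scenario(model, P, spec)


class TestMsyScan:
    def test_toy_scan_matches_brute_force(self, one_stock_toy):
        model = one_stock_toy
        P = T.derive_dynamic_params(model)
        prices = T.PriceTable({"fish": 1000.0})
        spec = T.ScenarioSpec(name="toy", scope_species=("fish",))
        res = T.msy_scan(model, P, spec, prices, grid_step=0.1, grid_max=5.0)
        oracle = brute_force_msy(model, P, prices, fine_step=0.01)
        assert abs(res.msMSYt_factor - oracle) <= 0.1 + 1e-9

    def test_equal_prices_equal_objectives(self, one_stock_toy):
        model = one_stock_toy
        P = T.derive_dynamic_params(model)
        prices = T.PriceTable({"fish": 777.0})
        spec = T.ScenarioSpec(name="toy", scope_species=("fish",))
        res = T.msy_scan(model, P, spec, prices, grid_step=0.5, grid_max=4.0)
        assert res.msMSYt_factor == res.msMSYeuro_factor

    def test_flat_objective_tie_breaks_to_smallest(self, web1):
        model, prices, P = web1
        from dataclasses import replace
        # zero catchability on the scope species: objective identically zero
        base_F = P.base_F.copy()
        for s in T.SCOPE_SPECIES:
            base_F[P.index(s), :] = 0.0
        flat = replace(P, base_F=base_F)
        spec = T.ScenarioSpec(name="flat", scope_species=T.SCOPE_SPECIES)
        res = T.msy_scan(model, flat, spec, prices, grid_step=0.5, grid_max=2.0,
                         years=30)
        assert res.msMSYt_factor == 0.5
        assert res.msMSYeuro_factor == 0.5

    def test_grid_factors_are_members(self, one_stock_toy):
        model = one_stock_toy
        P = T.derive_dynamic_params(model)
        prices = T.PriceTable({"fish": 1000.0})
        spec = T.ScenarioSpec(name="toy", scope_species=("fish",))
        res = T.msy_scan(model, P, spec, prices, grid_step=0.5, grid_max=3.0,
                         years=100)
        np.testing.assert_allclose(res.table["factor"],
                                   [0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        assert res.msMSYt_factor in set(res.table["factor"])


class TestCompareToBaseline:
    def test_identical_scenario_all_hundred(self, one_stock_toy):
        model = one_stock_toy
        P = T.derive_dynamic_params(model)
        prices = T.PriceTable({"fish": 1000.0})
        spec = T.ScenarioSpec(name="baseline", scope_species=("fish",))
        res = T.msy_scan(model, P, spec, prices, grid_step=1.0, grid_max=3.0,
                         years=100)
        from dataclasses import replace
        twin = replace(res, scenario="twin")
        report = T.compare_to_baseline(res, [twin])
        row = report.table.set_index("scenario").loc["twin"]
        assert row["effort_rel_baseline"] == pytest.approx(1.0)
        for col in ("SSB_fish_pct", "C_fish_pct", "rev_fish_pct"):
            assert row[col] == pytest.approx(100.0)

    def test_relative_catch_percentage(self):
        import pandas as pd
        from dataclasses import replace
        cols = {"factor": [1.0], "converged": [True], "C_fish": [100.0],
                "F_fish": [0.5], "B_fish": [10.0], "rev_fish": [1.0],
                "total_C": [100.0], "total_revenue": [1.0]}
        base = T.MsyScanResult("baseline", ("fish",), pd.DataFrame(cols), 1.0, 1.0)
        scen = replace(base, scenario="scen",
                       table=pd.DataFrame({**cols, "C_fish": [78.0],
                                           "total_C": [78.0]}))
        report = T.compare_to_baseline(base, [scen])
        assert report.table.set_index("scenario").loc["scen", "C_fish_pct"] == \
            pytest.approx(78.0)

    def test_species_mismatch_rejected(self, one_stock_toy):
        import pandas as pd
        cols = pd.DataFrame({"factor": [1.0], "converged": [True]})
        a = T.MsyScanResult("a", ("fish",), cols, 1.0, 1.0)
        b = T.MsyScanResult("b", ("crab",), cols, 1.0, 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            T.compare_to_baseline(a, [b])


class TestDirectionalScenarios:
    def test_mammal_scenario_cod_down_shrimp_up(self, web1):
        """Seal predation on cod relieves brown shrimp from its key
        predator: forcing seals up must depress cod and lift shrimp."""
        model, prices, P = web1
        spec = T.ScenarioSpec(
            name="seals3x", forced_biomass_multipliers={"seals": 3.0},
            vulnerability_overrides={"seals": 2.0},
            scope_species=T.SCOPE_SPECIES)
        p2, forcing = T.apply_scenario(model, P, spec)
        eq = T.equilibrium_summary(T.simulate(model, p2, forcing, years=200))
        base = T.equilibrium_summary(T.simulate(model, P, years=200))
        assert eq["B"][P.index("cod_adult")] < base["B"][P.index("cod_adult")]
        assert eq["B"][P.index("brown_shrimp")] > base["B"][P.index("brown_shrimp")]

    def test_objective_divergence_direction(self, web1):
        """With a robust cheap stock and a sensitive expensive one, the
        tonnage-maximizing effort is at least the revenue-maximizing one."""
        model, prices, P = web1
        spec = T.ScenarioSpec(name="baseline", scope_species=T.SCOPE_SPECIES)
        res = T.msy_scan(model, P, spec, prices, grid_step=0.25, grid_max=5.0)
        assert res.msMSYt_factor >= res.msMSYeuro_factor
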