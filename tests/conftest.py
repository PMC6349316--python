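import numpy as np
import pytest

import trophomsy as T


def make_chain2():
    """Two-group chain with hand-checkable balance arithmetic."""
    names = ("phyto", "zoo")
    groups = (
        T.FunctionalGroup(name="phyto", kind="producer", B=100.0, PB=10.0, EE=None),
        T.FunctionalGroup(name="zoo", kind="consumer", B=10.0, PB=5.0, QB=30.0,
                          U=0.2, EE=None),
    )
    DC = np.array([[0.0, 1.0], [0.0, 0.0]])
    diet = T.DietMatrix(names, DC, np.zeros(2))
    Y = np.array([[0.0], [10.0]])
    fleets = T.FleetTable(("trawl",), names, Y, (True,), np.ones_like(Y))
    return T.FoodWebModel(groups, diet, fleets)


@pytest.fixture
def chain2():
    return make_chain2()


@pytest.fixture
def chain2_balanced(chain2):
    return T.balance_model(chain2)


def make_one_stock_toy(F0=0.5):
    """Producer-consumer-fishery toy for yield-curve oracles."""
    names = ("algae", "fish", "detritus")
    groups = (
        T.FunctionalGroup(name="algae", kind="producer", B=50.0, PB=10.0, EE=None),
        T.FunctionalGroup(name="fish", kind="consumer", B=5.0, PB=1.0, QB=4.0,
                          U=0.2, EE=None),
        T.FunctionalGroup(name="detritus", kind="detritus", B=30.0, PB=0.0),
    )
    DC = np.zeros((3, 3))
    DC[0, 1] = 1.0
    diet = T.DietMatrix(names, DC, np.zeros(3))
    Y = np.zeros((3, 1))
    Y[1, 0] = F0 * 5.0
    fleets = T.FleetTable(("fleet",), names, Y, (True,), np.ones_like(Y))
    return T.balance_model(T.FoodWebModel(groups, diet, fleets))


@pytest.fixture(scope="session")
def one_stock_toy():
    return make_one_stock_toy()


@pytest.fixture(scope="session")
def web1():
    """Seed-1 synthetic shelf-sea web: (model, prices, params)."""
    return T.generate_web(T.WebRecipe(seed=1))


@pytest.fixture(scope="session")
def web_battery():
    """Five-seed battery of synthetic webs."""
    return [T.generate_web(T.WebRecipe(seed=s)) for s in range(1, 6)]


def eq1_residuals(model):
    """Independent term-by-term evaluation of the mass balance, per group.

    Deliberately written as explicit loops over the defining sum, not via
    the solver's vectorized path."""
    out = {}
    Y = model.fleets.total_catch()
    for i, g in enumerate(model.groups):
        if g.kind == "detritus":
            continue
        predation = 0.0
        for j, pred in enumerate(model.groups):
            if pred.QB is not None:
                predation += pred.B * pred.QB * model.diet.DC[i, j]
        lhs = g.B * g.PB * g.EE
        rhs = predation + Y[i] + g.E + g.BA
        out[g.name] = (lhs - rhs) / max(abs(lhs), 1.0)
    return out


def eq3_rhs_manual(model, params, B, effort_factor=1.0, producer_multiplier=1.0):
    """Independent evaluation of the biomass derivatives: literal sums over
    the growth, predation-loss, other-mortality, fishing and migration terms,
    with the arena and producer-saturation forms inlined."""
    P = params
    n = len(P.names)
    dB = np.zeros(n)
    scope_mult = np.array([effort_factor if s else 1.0 for s in P.fleet_scope])
    for i in range(n):
        if P.kinds[i] == "detritus":
            inflow = 0.0
            for j in range(n):
                intake_j = sum(
                    P.Q0[k, j] * (B[k] / P.B0[k])
                    * (1.0 if P.K[k, j] == 1.0 else
                       P.K[k, j] * (B[j] / P.B0[j]) / (P.K[k, j] - 1.0 + B[j] / P.B0[j]))
                    for k in range(n)) + P.Q0_import[j] * B[j] / P.B0[j]
                inflow += P.U[j] * intake_j + P.M0[j] * B[j]
            losses = sum(
                P.Q0[i, j] * (B[i] / P.B0[i])
                * (1.0 if P.K[i, j] == 1.0 else
                   P.K[i, j] * (B[j] / P.B0[j]) / (P.K[i, j] - 1.0 + B[j] / P.B0[j]))
                for j in range(n))
            dB[i] = inflow + P.det_import[i] - losses - P.det_export_rate[i] * B[i]
            continue
        intake = sum(
            P.Q0[k, i] * (B[k] / P.B0[k])
            * (1.0 if P.K[k, i] == 1.0 else
               P.K[k, i] * (B[i] / P.B0[i]) / (P.K[k, i] - 1.0 + B[i] / P.B0[i]))
            for k in range(n)) + P.Q0_import[i] * B[i] / P.B0[i]
        losses = sum(
            P.Q0[i, j] * (B[i] / P.B0[i])
            * (1.0 if P.K[i, j] == 1.0 else
               P.K[i, j] * (B[j] / P.B0[j]) / (P.K[i, j] - 1.0 + B[j] / P.B0[j]))
            for j in range(n))
        F = float(P.base_F[i] @ scope_mult)
        if P.kinds[i] == "producer":
            x = B[i] / P.B0[i]
            s = P.prod_sat
            growth = producer_multiplier * P.PB0[i] * P.B0[i] * s * x / (1 + (s - 1) * x)
        else:
            growth = P.g[i] * intake
        dB[i] = growth - losses - (P.M0[i] + F + P.migration[i]) * B[i]
    for lk in P.stage_links:
        ia, ij = P.names.index(lk.adult), P.names.index(lk.juvenile)
        t_in = lk.recruitment_fraction * P.PB0[ia] * B[ia]
        t_out = lk.graduation_rate * B[ij]
        dB[ij] += t_in - t_out
        dB[ia] += t_out - t_in
    return dB
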