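"""Seeded generator of small balanced food webs.

The generated webs emulate the trophic skeleton of a temperate shelf sea such
as the southern North Sea: a producer -> zooplankton/benthos -> shrimp ->
fish -> marine-mammal chain in which cod is the key shrimp predator and
seals and porpoises prey on cod, exploited by three scope fleets (demersal
trawlers on cod, beam trawlers on plaice and sole, shrimp trawlers on brown
shrimp) plus a non-scope gillnet fleet with small bycatch of mammals and
other fish.  Plaice is priced at 16% of sole.

Construction is demand-driven: biomasses of the apex groups are drawn, and
each lower group's biomass is then set so that its ecotrophic efficiency
lands on a drawn target — every web therefore balances by construction, and
the balanced state is a fixed point of the dynamics.  Cod is split into a
juvenile and an adult pool linked by recruitment and graduation flows chosen
to cancel exactly at the base state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .dynamics import DynamicParams, derive_dynamic_params
from .fisheries import PriceTable
from .foodweb import (CONSUMER, DETRITUS, PRODUCER, DietMatrix, FleetTable,
                      FoodWebModel, FunctionalGroup, StageLink,
                      UnbalancedModelError, balance_model)

__all__ = ["WebRecipe", "generate_web", "generate_stage_link",
           "SCOPE_SPECIES", "CHAIN_ROSTER", "FLEET_ROSTER"]

CHAIN_ROSTER = (
    "phytoplankton", "zooplankton", "benthos", "detritus", "brown_shrimp",
    "cod_juv", "cod_adult", "plaice", "sole", "other_fish", "seals", "porpoises",
)
FLEET_ROSTER = ("DEM", "BT", "SHR", "GNS")
SCOPE_SPECIES = ("cod_adult", "plaice", "sole", "brown_shrimp")

# Parameter ranges (log-uniform for biomass draws, uniform otherwise).
# PB declines with trophic level; QB is a multiple of PB; EE targets keep
# every group's ecotrophic efficiency well inside [0.05, 0.95].
DEFAULT_RANGES: dict = {
    "PB": {
        "phytoplankton": (15.0, 25.0), "zooplankton": (6.0, 10.0),
        "benthos": (2.0, 4.0), "brown_shrimp": (2.0, 3.5),
        "cod_juv": (0.8, 1.2), "cod_adult": (0.45, 0.65),
        "plaice": (0.5, 0.7), "sole": (0.45, 0.65),
        "other_fish": (0.7, 1.1), "seals": (0.06, 0.1),
        "porpoises": (0.06, 0.1), "filler": (1.0, 2.0),
    },
    "QB_factor": {"default": (3.0, 4.0), "seals": (10.0, 20.0), "porpoises": (10.0, 20.0)},
    "U": {"default": (0.2, 0.3), "seals": (0.15, 0.2), "porpoises": (0.15, 0.2)},
    "B_apex": {"seals": (0.02, 0.08), "porpoises": (0.02, 0.06)},
    "B_detritus": (20.0, 60.0),
    "EE_target": {
        "phytoplankton": (0.5, 0.8), "zooplankton": (0.6, 0.85),
        "benthos": (0.55, 0.85), "brown_shrimp": (0.75, 0.92),
        "cod_juv": (0.6, 0.85), "cod_adult": (0.8, 0.92),
        "plaice": (0.7, 0.9), "sole": (0.7, 0.9),
        "other_fish": (0.5, 0.8), "filler": (0.4, 0.7),
    },
    "catch_fraction": {   # share of production taken by the fishery
        "cod_adult": (0.25, 0.4), "plaice": (0.25, 0.35), "sole": (0.2, 0.3),
        "brown_shrimp": (0.25, 0.4), "other_fish": (0.08, 0.15),
        "seals": (0.06, 0.12), "porpoises": (0.06, 0.12),
    },
    "recruitment_fraction": (0.2, 0.4),
    "price": {"sole": (9000.0, 12000.0), "cod_adult": (1200.0, 1800.0),
              "brown_shrimp": (2500.0, 3500.0)},
    "plaice_to_sole_price": 0.16,
    "diet_jitter": (0.85, 1.2),
}

# predator -> {prey: weight, "import": share}; normalized after jitter.
# Cod's shrimp weight dominates by enough margin to survive any jitter.
_DIET_TEMPLATE: dict[str, dict[str, float]] = {
    "zooplankton": {"phytoplankton": 0.85, "detritus": 0.15},
    "benthos": {"phytoplankton": 0.3, "detritus": 0.7},
    "brown_shrimp": {"benthos": 0.4, "zooplankton": 0.3, "detritus": 0.3},
    "cod_juv": {"zooplankton": 0.5, "benthos": 0.3, "brown_shrimp": 0.2},
    "cod_adult": {"brown_shrimp": 0.45, "other_fish": 0.2, "benthos": 0.2,
                  "cod_juv": 0.15},
    "plaice": {"benthos": 0.85, "detritus": 0.1, "zooplankton": 0.05},
    "sole": {"benthos": 0.9, "detritus": 0.1},
    "other_fish": {"zooplankton": 0.4, "benthos": 0.3, "brown_shrimp": 0.1,
                   "cod_juv": 0.1, "detritus": 0.05, "import": 0.05},
    "seals": {"cod_adult": 0.3, "other_fish": 0.35, "plaice": 0.1, "sole": 0.05,
              "cod_juv": 0.05, "import": 0.15},
    "porpoises": {"cod_adult": 0.2, "other_fish": 0.45, "cod_juv": 0.1,
                  "import": 0.25},
}

# Topological order for demand-driven biomass derivation: every group's
# predators appear before it.
_DERIVATION_ORDER = (
    "cod_adult", "other_fish", "cod_juv", "plaice", "sole",
    "brown_shrimp", "benthos", "zooplankton", "phytoplankton",
)

_FLEET_OF = {"cod_adult": "DEM", "plaice": "BT", "sole": "BT",
             "brown_shrimp": "SHR", "other_fish": "GNS",
             "seals": "GNS", "porpoises": "GNS"}


@dataclass(frozen=True)
class WebRecipe:
    """Deterministic recipe for one synthetic web."""

    seed: int
    n_extra_groups: int = 0
    ranges: Mapping = field(default_factory=lambda: DEFAULT_RANGES)

    def __post_init__(self):
        if not 0 <= self.n_extra_groups <= 10:
            raise ValueError("n_extra_groups must lie in [0, 10]")


def _loguniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _attempt(rng: np.random.Generator, recipe: WebRecipe):
    R = recipe.ranges
    fillers = [f"filler_{k+1}" for k in range(recipe.n_extra_groups)]
    names = list(CHAIN_ROSTER) + fillers
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    kind = {nm: CONSUMER for nm in names}
    kind["phytoplankton"] = PRODUCER
    kind["detritus"] = DETRITUS

    # Rates
    PB, QB, U = {}, {}, {}
    for nm in names:
        if nm == "detritus":
            continue
        key = "filler" if nm in fillers else nm
        PB[nm] = rng.uniform(*R["PB"][key])
        if kind[nm] == CONSUMER:
            qf = R["QB_factor"].get(nm, R["QB_factor"]["default"])
            QB[nm] = PB[nm] * rng.uniform(*qf)
            U[nm] = rng.uniform(*R["U"].get(nm, R["U"]["default"]))

    # Diet matrix
    template = {k: dict(v) for k, v in _DIET_TEMPLATE.items()}
    for f in fillers:
        template[f] = {"benthos": 0.4, "zooplankton": 0.4, "detritus": 0.2}
        template["other_fish"][f] = 0.05
    DC = np.zeros((n, n))
    imp = np.zeros(n)
    jit = R["diet_jitter"]
    for pred, weights in template.items():
        w = {p: v * rng.uniform(*jit) for p, v in weights.items()}
        total = sum(w.values())
        for p, v in w.items():
            if p == "import":
                imp[idx[pred]] = v / total
            else:
                DC[idx[p], idx[pred]] = v / total

    # Biomasses: apex drawn, the rest derived from predation demand so that
    # EE hits its target exactly; fishery takes catch_fraction of production.
    B = {nm: _loguniform(rng, *R["B_apex"][nm]) for nm in ("seals", "porpoises")}
    B["detritus"] = _loguniform(rng, *R["B_detritus"])
    ee_target, catch_frac = {}, {}
    for nm in names:
        key = "filler" if nm in fillers else nm
        if key in R["EE_target"]:
            ee_target[nm] = rng.uniform(*R["EE_target"][key])
        if key in R["catch_fraction"]:
            catch_frac[nm] = rng.uniform(*R["catch_fraction"][key])

    order = list(_DERIVATION_ORDER)
    order[order.index("sole") + 1:order.index("sole") + 1] = fillers
    for nm in order:
        i = idx[nm]
        demand = sum(B[p] * QB[p] * DC[i, idx[p]] for p in B if p in QB)
        ee, y = ee_target[nm], catch_frac.get(nm, 0.0)
        if ee - y <= 0.02:
            return None
        B[nm] = demand / ((ee - y) * PB[nm])
        if not 1e-5 < B[nm] < 1e4:
            return None

    # Catches
    Y = np.zeros((n, len(FLEET_ROSTER)))
    for nm, frac in catch_frac.items():
        Y[idx[nm], FLEET_ROSTER.index(_FLEET_OF[nm])] = frac * B[nm] * PB[nm]

    groups = []
    for nm in names:
        k = kind[nm]
        groups.append(FunctionalGroup(
            name=nm, kind=k, B=B[nm],
            PB=0.0 if k == DETRITUS else PB[nm],
            QB=QB.get(nm), EE=None if k != DETRITUS else None,
            U=U.get(nm),
            stage_of="cod_adult" if nm == "cod_juv" else None,
        ))
    diet = DietMatrix(tuple(names), DC, imp)
    scope = tuple(f != "GNS" for f in FLEET_ROSTER)
    fleets = FleetTable(FLEET_ROSTER, tuple(names), Y, scope, np.ones_like(Y))
    model = FoodWebModel(tuple(groups), diet, fleets)
    model = balance_model(model)

    # Generator contract on solved efficiencies
    for g in model.groups:
        if g.kind != DETRITUS and not 0.05 <= g.EE <= 0.95:
            return None

    # Stage link with transfers that cancel exactly at the base state
    r = rng.uniform(*R["recruitment_fraction"])
    p_adult = model.group("cod_adult").B * model.group("cod_adult").PB
    grad = r * p_adult / model.group("cod_juv").B
    model = replace(model, stage_links=(StageLink("cod_adult", "cod_juv", r, grad),))

    # Prices: plaice pegged at 16% of sole
    price = {nm: rng.uniform(*rng_pair) for nm, rng_pair in R["price"].items()}
    price["plaice"] = R["plaice_to_sole_price"] * price["sole"]
    prices = PriceTable(price)

    # Baseline vulnerabilities: bottom-up (K = 1) for the mammal predators,
    # mixed control (K = 2) on every other link.
    K = np.full((n, n), 2.0)
    for nm in ("seals", "porpoises"):
        K[:, idx[nm]] = 1.0
    params = derive_dynamic_params(model, K)
    return model, prices, params


def generate_web(recipe: WebRecipe) -> tuple[FoodWebModel, PriceTable, DynamicParams]:
    """Generate a balanced web; identical recipes give identical output.

    Draws are retried (up to 100 perturbed attempts) if a draw combination
    produces an unbalanceable web or an efficiency outside [0.05, 0.95].
    """
    rng = np.random.default_rng(recipe.seed)
    for _ in range(100):
        try:
            out = _attempt(rng, recipe)
        except UnbalancedModelError:
            out = None
        if out is not None:
            return out
    raise UnbalancedModelError(
        f"could not generate a balanceable web from seed {recipe.seed} "
        "within 100 attempts")


def generate_stage_link(
    model: FoodWebModel,
    adult: str,
    juvenile: str,
    recruitment_fraction: float,
    graduation_rate: float,
) -> FoodWebModel:
    """Attach a juvenile/adult linkage to a balanced model.

    Recruitment moves ``recruitment_fraction`` of the adult pool's production
    into the juvenile pool; graduation returns juvenile biomass to the adult
    pool at ``graduation_rate``.  Any net base-state transfer is booked
    through the migration terms (immigration for the receiving pool) and the
    efficiencies of the two pools are re-solved, so the static balance — and
    with it the dynamic fixed point — is preserved.  Transfers that cannot be
    absorbed (an efficiency pushed outside [0, 1]) raise
    :class:`UnbalancedModelError`.
    """
    if not model.balanced:
        raise ValueError("model must be balanced first")
    link = StageLink(adult, juvenile, recruitment_fraction, graduation_rate)
    a, j = model.group(adult), model.group(juvenile)
    t_in = recruitment_fraction * a.B * a.PB
    t_out = graduation_rate * j.B
    net = t_in - t_out      # net flow adult -> juvenile at base state
    if abs(net) < 1e-12 * max(t_in, 1.0):
        return replace(model, stage_links=model.stage_links + (link,))

    groups = list(model.groups)
    ia, ij = model.index(adult), model.index(juvenile)
    groups[ij] = replace(j, E=j.E - net, EE=None)
    groups[ia] = replace(a, E=a.E + net, EE=None)
    rebased = replace(model, groups=tuple(groups), balanced=False,
                      stage_links=model.stage_links + (link,))
    return balance_model(rebased)
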