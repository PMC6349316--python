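"""Multispecies-MSY effort scans and ecosystem-change scenarios.

The msMSY search scales the effort of all scope fleets together over a grid
of common factors, runs each setting to equilibrium (200 simulated years by
default), reads off catch/biomass/F in the next-to-last year, and picks the
factor maximizing combined scope-species catch in tonnes (msMSYt) or
landings revenue in euros (msMSY-EUR).  Scenarios modify the system before
scanning: a producer-production multiplier (e.g. primary production at 70%),
forced biomass for marine-mammal groups (held at a multiple of their
baseline for the whole run), and per-predator vulnerability overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (DynamicParams, ForcingSet, TimeFunction,
                       equilibrium_summary, simulate)
from .fisheries import EffortRegime, PriceTable, revenue
from .foodweb import FoodWebModel

__all__ = [
    "ScenarioSpec",
    "MsyScanResult",
    "ComparisonReport",
    "apply_scenario",
    "msy_scan",
    "compare_to_baseline",
    "BASELINE",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One ecosystem-change scenario.

    ``forced_biomass_multipliers`` pin groups to a multiple of their baseline
    biomass for the whole run; ``vulnerability_overrides`` set the
    vulnerability K of every prey link into the named predator (applied in
    this scenario only); ``scope_species`` are the stocks whose combined
    catch/revenue forms the msMSY objective.
    """

    name: str
    producer_multiplier: float = 1.0
    forced_biomass_multipliers: Mapping[str, float] = field(default_factory=dict)
    vulnerability_overrides: Mapping[str, float] = field(default_factory=dict)
    scope_species: tuple[str, ...] = ()

    def __post_init__(self):
        if self.producer_multiplier <= 0:
            raise ValueError("producer multiplier must be positive")
        if any(v <= 0 for v in self.forced_biomass_multipliers.values()):
            raise ValueError("forced-biomass multipliers must be positive")
        if any(v < 1 for v in self.vulnerability_overrides.values()):
            raise ValueError("vulnerability overrides must be >= 1")


BASELINE = ScenarioSpec(name="baseline")

# Default magnitudes of the ecosystem-change scenarios: primary production
# at 70%, grey seals held at 5.76x their reference biomass, harbour
# porpoises at 2.09x (continued southward drift) or 1.46x (drift stopped),
# with the seal vulnerability raised from 1 to 2 in the mammal scenarios.
PP_MULTIPLIER = 0.7
SEAL_MULTIPLIER = 5.76
PORPOISE_MULTIPLIER_DRIFT = 2.09
PORPOISE_MULTIPLIER_NO_DRIFT = 1.46
SEAL_VULNERABILITY = 2.0


def standard_scenarios(
    scope_species: tuple[str, ...],
    seal_group: str = "seals",
    porpoise_group: str = "porpoises",
) -> list[ScenarioSpec]:
    """The four study scenarios: baseline, reduced primary production, and
    the two marine-mammal carrying-capacity scenarios."""
    return [
        ScenarioSpec(name="baseline", scope_species=scope_species),
        ScenarioSpec(name="pp70", producer_multiplier=PP_MULTIPLIER,
                     scope_species=scope_species),
        ScenarioSpec(
            name="mammals_with_drift",
            forced_biomass_multipliers={seal_group: SEAL_MULTIPLIER,
                                        porpoise_group: PORPOISE_MULTIPLIER_DRIFT},
            vulnerability_overrides={seal_group: SEAL_VULNERABILITY},
            scope_species=scope_species),
        ScenarioSpec(
            name="mammals_without_drift",
            forced_biomass_multipliers={seal_group: SEAL_MULTIPLIER,
                                        porpoise_group: PORPOISE_MULTIPLIER_NO_DRIFT},
            vulnerability_overrides={seal_group: SEAL_VULNERABILITY},
            scope_species=scope_species),
    ]


def apply_scenario(
    model: FoodWebModel,
    params: DynamicParams,
    spec: ScenarioSpec,
) -> tuple[DynamicParams, ForcingSet]:
    """Translate a scenario into modified rates and a forcing set.

    Producer forcing and biomass forcing cover the entire simulation horizon;
    vulnerability overrides rewrite the K column of the named predators.
    Unknown group names raise ``KeyError``.
    """
    if not model.balanced:
        raise ValueError("model must be balanced first")
    names = params.names
    for nm in list(spec.forced_biomass_multipliers) + list(spec.vulnerability_overrides):
        if nm not in names:
            raise KeyError(f"scenario {spec.name!r} references unknown group {nm!r}")

    K = params.K.copy()
    for pred, v in spec.vulnerability_overrides.items():
        K[:, params.index(pred)] = float(v)
    new_params = params.with_K(K)

    producers = {nm: TimeFunction(spec.producer_multiplier)
                 for nm, k in zip(names, params.kinds) if k == "producer"}
    forced = {nm: TimeFunction(m * params.B0[params.index(nm)])
              for nm, m in spec.forced_biomass_multipliers.items()}
    return new_params, ForcingSet(producer_multiplier=producers, forced_biomass=forced)


@dataclass(frozen=True)
class MsyScanResult:
    """Equilibrium grid of one msMSY scan.

    ``table`` has one row per common effort factor with per-species B (SSB
    for stage-linked species), C, F and revenue plus the summed objectives;
    non-equilibrated factors are flagged and excluded from the argmax.
    """

    scenario: str
    scope_species: tuple[str, ...]
    table: pd.DataFrame
    msMSYt_factor: float
    msMSYeuro_factor: float

    def row(self, factor: float) -> pd.Series:
        match = self.table[np.isclose(self.table["factor"], factor)]
        if match.empty:
            raise KeyError(f"factor {factor} not in scan grid")
        return match.iloc[0]


def _ssb_map(model: FoodWebModel) -> dict[str, str]:
    """Species -> biomass-reporting pool: the adult pool for stage-linked
    species, the species itself otherwise."""
    out: dict[str, str] = {}
    for lk in model.stage_links:
        out[lk.adult] = lk.adult
        out[lk.juvenile] = lk.adult
    return out


def msy_scan(
    model: FoodWebModel,
    params: DynamicParams,
    scenario: ScenarioSpec,
    prices: PriceTable,
    grid_step: float = 0.5,
    grid_max: float = 5.0,
    years: float = 200.0,
    steps_per_year: int = 12,
    convergence_tol: float = 0.01,
) -> MsyScanResult:
    """Grid search for the common effort factor maximizing scope catch.

    For each factor x in {step, 2*step, ..., <= max} all scope fleets run at
    x times baseline effort for ``years`` years; the next-to-last-year
    equilibrium is recorded.  A factor whose final two annual-mean biomasses
    differ by more than ``convergence_tol`` for any scope species is flagged
    non-equilibrated and excluded from the argmax.  Ties pick the smallest
    factor.
    """
    if grid_step <= 0 or grid_max < grid_step:
        raise ValueError("grid_step must be positive and grid_max >= grid_step")
    sp_names = scenario.scope_species
    if not sp_names:
        raise ValueError("scenario must define scope_species")
    run_params, forcing = apply_scenario(model, params, scenario)
    # Forced groups never enter the objective
    objective_species = tuple(s for s in sp_names
                              if s not in scenario.forced_biomass_multipliers)
    ssb_of = _ssb_map(model)
    spy = steps_per_year

    nfac = int(np.floor(grid_max / grid_step + 1e-9))
    factors = [round((k + 1) * grid_step, 10) for k in range(nfac)]

    rows = []
    for x in factors:
        regime = EffortRegime(common_factor=x)
        mult = regime.multipliers(run_params)
        eff = {f: TimeFunction(m) for f, m in zip(run_params.fleet_names, mult)}
        fset = ForcingSet(producer_multiplier=forcing.producer_multiplier,
                          forced_biomass=forcing.forced_biomass,
                          effort_multiplier=eff)
        traj = simulate(model, run_params, fset, years=years, steps_per_year=spy)
        summ = equilibrium_summary(traj)

        # convergence screen: final two annual means per scope species
        total = int(round(traj.times[-1]))
        last = traj.B[(total - 1) * spy: total * spy].mean(axis=0)
        prev = summ["B"]
        converged = True
        for s in objective_species:
            pools = {s, ssb_of.get(s, s)}
            for pool in pools:
                i = run_params.index(pool)
                if prev[i] > 0 and abs(last[i] - prev[i]) / prev[i] > convergence_tol:
                    converged = False

        row: dict = {"factor": x, "converged": converged}
        names = run_params.names
        total_C = 0.0
        for s in objective_species:
            i = run_params.index(s)
            row[f"C_{s}"] = summ["C"][i]
            row[f"F_{s}"] = summ["F"][i]
            pool = ssb_of.get(s, s)
            row[f"B_{s}"] = summ["B"][run_params.index(pool)]
            total_C += summ["C"][i]
        total_rev, per_rev = revenue(summ["C_by_fleet"], run_params.landed_fraction,
                                     prices, names, objective_species)
        for s, v in per_rev.items():
            row[f"rev_{s}"] = v
        row["total_C"] = total_C
        row["total_revenue"] = total_rev
        rows.append(row)

    table = pd.DataFrame(rows)

    def argmax(col: str) -> float:
        ok = table[table["converged"]]
        if ok.empty:
            raise RuntimeError(f"no equilibrated run in scan {scenario.name!r}")
        best = ok[col].max()
        # smallest factor among (near-)ties
        tied = ok[np.isclose(ok[col], best, rtol=1e-12, atol=0.0) | (ok[col] == best)]
        return float(tied["factor"].min())

    return MsyScanResult(
        scenario=scenario.name,
        scope_species=objective_species,
        table=table,
        msMSYt_factor=argmax("total_C"),
        msMSYeuro_factor=argmax("total_revenue"),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Scenario-vs-baseline comparison at the respective msMSY factors.

    Percentages are scenario value at its own msMSY divided by the baseline
    value at the baseline msMSY; F is reported absolute."""

    species: tuple[str, ...]
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_to_baseline(
    baseline: MsyScanResult,
    scenarios: Sequence[MsyScanResult],
    objective: str = "tonnes",
) -> ComparisonReport:
    """Build the relative comparison table (effort, F, SSB%, C%, revenue%).

    ``objective`` selects which msMSY factor anchors the comparison
    ("tonnes" or "euros").  All results must share the species set.
    """
    attr = "msMSYt_factor" if objective == "tonnes" else "msMSYeuro_factor"
    species = baseline.scope_species
    for res in scenarios:
        if res.scope_species != species:
            raise ValueError(
                f"species mismatch: {res.scenario!r} has {res.scope_species}, "
                f"baseline has {species}")
    base_row = baseline.row(getattr(baseline, attr))

    rows = []
    for res in [baseline, *scenarios]:
        row = res.row(getattr(res, attr))
        out: dict = {
            "scenario": res.scenario,
            "effort_rel_baseline": getattr(res, attr) / getattr(baseline, attr),
        }
        for s in species:
            out[f"F_{s}"] = row[f"F_{s}"]
        for s in species:
            out[f"SSB_{s}_pct"] = 100.0 * row[f"B_{s}"] / base_row[f"B_{s}"]
        for s in species:
            out[f"C_{s}_pct"] = 100.0 * row[f"C_{s}"] / base_row[f"C_{s}"]
        for s in species:
            out[f"rev_{s}_pct"] = 100.0 * row[f"rev_{s}"] / base_row[f"rev_{s}"]
        rows.append(out)
    return ComparisonReport(species=species, table=pd.DataFrame(rows))
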