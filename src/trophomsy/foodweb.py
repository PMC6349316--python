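"""Static mass-balance food-web model (Ecopath-style snapshot).

A food web is a set of functional groups (producers, consumers, detritus)
linked by a diet-composition matrix and exploited by fishing fleets.  At
steady state every group's production is partitioned among predation losses,
fishery catches, net migration, biomass accumulation and "other" mortality:

    B_i * PB_i * EE_i = sum_j B_j * QB_j * DC[i, j] + Y_i + E_i + BA_i

where ``B`` is biomass (t km^-2), ``PB`` production/biomass (yr^-1), ``QB``
consumption/biomass (yr^-1), ``DC[i, j]`` the proportion of prey *i* in the
diet of predator *j*, ``Y`` the total catch, ``E`` net migration (emigration
positive), ``BA`` biomass accumulation and ``EE`` the ecotrophic efficiency
(the fraction of production used within or exported from the system).

Exactly one of {B, PB, EE} may be left unknown per non-detritus group;
:func:`balance_model` fills the gaps and validates the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "DietMatrix",
    "FleetTable",
    "StageLink",
    "FoodWebModel",
    "UnbalancedModelError",
    "SchemaError",
    "balance_model",
    "energy_budget",
    "detritus_ledger",
    "read_foodweb",
    "write_foodweb",
]

RESIDUAL_TOL = 1e-9

PRODUCER = "producer"
CONSUMER = "consumer"
DETRITUS = "detritus"
_KINDS = (PRODUCER, CONSUMER, DETRITUS)


class UnbalancedModelError(ValueError):
    """Raised when balancing produces an infeasible parameter (EE outside
    [0, 1], non-positive biomass, or a singular unknown-biomass system)."""


class SchemaError(ValueError):
    """Raised when input tables violate the documented CSV schema."""


@dataclass(frozen=True)
class FunctionalGroup:
    """One compartment of the food web.

    ``None`` marks an unknown parameter to be filled by :func:`balance_model`.
    ``stage_of`` links a juvenile pool to its adult pool by name.
    """

    name: str
    kind: str = CONSUMER
    B: float | None = None
    PB: float | None = None
    QB: float | None = None
    EE: float | None = None
    U: float | None = None
    BA: float = 0.0
    E: float = 0.0
    stage_of: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"group {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CONSUMER:
            if self.QB is None:
                raise SchemaError(f"consumer {self.name!r} needs QB")
            u = 0.0 if self.U is None else self.U
            if not 0.0 <= u < 1.0:
                raise SchemaError(f"consumer {self.name!r}: U must lie in [0, 1)")
        else:
            if self.QB is not None:
                raise SchemaError(f"{self.kind} {self.name!r} must not have QB")
            if self.U is not None:
                raise SchemaError(f"{self.kind} {self.name!r} must not have U")
        if self.kind == DETRITUS and self.PB not in (None, 0.0):
            raise SchemaError(f"detritus {self.name!r} must have PB = 0")

    @property
    def unknowns(self) -> tuple[str, ...]:
        return tuple(f for f in ("B", "PB", "EE") if getattr(self, f) is None)

    @property
    def unassimilated(self) -> float:
        return 0.0 if self.U is None else self.U


@dataclass(frozen=True)
class DietMatrix:
    """Prey-by-predator diet proportions.

    ``DC[i, j]`` is the share of prey ``names[i]`` in the diet of predator
    ``names[j]``; ``import_share[j]`` is the share of predator *j*'s diet taken
    outside the system.  Consumer columns sum to one including the import
    share; producer and detritus columns are all zero.
    """

    names: tuple[str, ...]
    DC: np.ndarray
    import_share: np.ndarray

    def __post_init__(self) -> None:
        dc = np.asarray(self.DC, dtype=float)
        imp = np.asarray(self.import_share, dtype=float)
        n = len(self.names)
        if dc.shape != (n, n) or imp.shape != (n,):
            raise SchemaError("diet matrix shape mismatch")
        if (dc < 0).any() or (imp < 0).any():
            raise SchemaError("diet proportions must be non-negative")
        object.__setattr__(self, "DC", dc)
        object.__setattr__(self, "import_share", imp)

    def validate_columns(self, groups: list[FunctionalGroup]) -> None:
        for j, g in enumerate(groups):
            total = self.DC[:, j].sum() + self.import_share[j]
            if g.kind == CONSUMER:
                if abs(total - 1.0) > 1e-9:
                    raise SchemaError(
                        f"diet column of predator {g.name!r} sums to {total:.6g}, not 1"
                    )
            elif total > 1e-12:
                raise SchemaError(f"{g.kind} {g.name!r} must have an all-zero diet column")


@dataclass(frozen=True)
class FleetTable:
    """Baseline catches per group and fleet (t km^-2 yr^-1).

    ``scope[f]`` marks fleet *f* as subject to the common effort multiplier
    of an msMSY scan; ``landed_fraction`` gives the landed share of each
    group-by-fleet catch (the remainder is discarded to detritus).
    """

    fleets: tuple[str, ...]
    group_names: tuple[str, ...]
    Y: np.ndarray                   # group x fleet
    scope: tuple[bool, ...]
    landed_fraction: np.ndarray     # group x fleet

    def __post_init__(self) -> None:
        y = np.asarray(self.Y, dtype=float)
        lf = np.asarray(self.landed_fraction, dtype=float)
        shape = (len(self.group_names), len(self.fleets))
        if y.shape != shape or lf.shape != shape:
            raise SchemaError("fleet table shape mismatch")
        if (y < 0).any():
            raise SchemaError("catches must be non-negative")
        if (lf < 0).any() or (lf > 1).any():
            raise SchemaError("landed fractions must lie in [0, 1]")
        if len(self.fleets) and not any(self.scope):
            raise SchemaError("at least one fleet must be in scope")
        object.__setattr__(self, "Y", y)
        object.__setattr__(self, "landed_fraction", lf)

    @classmethod
    def empty(cls, group_names: tuple[str, ...]) -> "FleetTable":
        n = len(group_names)
        return cls((), group_names, np.zeros((n, 0)), (), np.zeros((n, 0)))

    def total_catch(self) -> np.ndarray:
        """Per-group catch summed over fleets (the Y_i of the balance)."""
        return self.Y.sum(axis=1)

    def discards(self) -> np.ndarray:
        """Per-group unlanded catch, routed to detritus."""
        return (self.Y * (1.0 - self.landed_fraction)).sum(axis=1)


@dataclass(frozen=True)
class StageLink:
    """Two-pool juvenile/adult linkage.

    A fraction ``recruitment_fraction`` of the adult pool's production flows
    into the juvenile pool; juveniles graduate to the adult pool at rate
    ``graduation_rate`` (yr^-1) applied to juvenile biomass.
    """

    adult: str
    juvenile: str
    recruitment_fraction: float
    graduation_rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.recruitment_fraction <= 1.0:
            raise ValueError("recruitment_fraction must lie in (0, 1]")
        if self.graduation_rate <= 0:
            raise ValueError("graduation_rate must be positive")


@dataclass(frozen=True)
class FoodWebModel:
    groups: tuple[FunctionalGroup, ...]
    diet: DietMatrix
    fleets: FleetTable
    stage_links: tuple[StageLink, ...] = ()
    balanced: bool = False
    detritus_export: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate group names: {dup}")
        if tuple(names) != self.diet.names:
            raise SchemaError("diet matrix names do not match group order")
        if tuple(names) != self.fleets.group_names:
            raise SchemaError("fleet table names do not match group order")
        for link in self.stage_links:
            for nm in (link.adult, link.juvenile):
                if nm not in names:
                    raise SchemaError(f"stage link references unknown group {nm!r}")

    # -- convenience ------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no group named {name!r}") from None

    def group(self, name: str) -> FunctionalGroup:
        return self.groups[self.index(name)]

    def kinds(self) -> np.ndarray:
        return np.array([g.kind for g in self.groups])

    def array(self, attr: str, default: float = np.nan) -> np.ndarray:
        out = np.empty(len(self.groups))
        for i, g in enumerate(self.groups):
            v = getattr(g, attr)
            out[i] = default if v is None else v
        return out


def energy_budget(group: FunctionalGroup) -> float:
    """Respiration implied by the consumer energy budget Q = P + R + U.

    Returns ``R = B*QB - B*PB - U*B*QB`` (t km^-2 yr^-1) and raises if the
    budget is infeasible (``U + PB/QB >= 1`` would make respiration negative).
    """
    if group.kind != CONSUMER:
        raise ValueError(f"{group.name!r} is not a consumer")
    for f in ("B", "PB", "QB"):
        if getattr(group, f) is None:
            raise ValueError(f"consumer {group.name!r}: {f} unknown")
    Q = group.B * group.QB
    R = Q - group.B * group.PB - group.unassimilated * Q
    if R < -1e-12 * max(Q, 1.0):
        raise UnbalancedModelError(
            f"infeasible energy budget for {group.name!r}: "
            f"U + PB/QB = {group.unassimilated + group.PB / group.QB:.4g} >= 1"
        )
    return max(R, 0.0)


def _demand_constant(model: FoodWebModel) -> np.ndarray:
    """Y + E + BA per group (the non-predation demand side of the balance)."""
    Y = model.fleets.total_catch()
    return Y + model.array("E", 0.0) + model.array("BA", 0.0)


def balance_model(model: FoodWebModel) -> FoodWebModel:
    """Solve the mass balance for every group's missing parameter.

    Unknown biomasses may be mutually coupled through predation and are solved
    as one linear system; unknown PB and EE then follow in closed form.  The
    returned model has ``balanced=True`` and a detritus inflow/outflow ledger.

    Raises :class:`UnbalancedModelError` when a solved EE falls outside
    [0, 1], a solved biomass is non-positive, or the coupled system is
    singular, and :class:`SchemaError` for structurally invalid inputs.
    """
    groups = list(model.groups)
    n = len(groups)
    model.diet.validate_columns(groups)

    for g in groups:
        if g.kind == DETRITUS:
            if g.B is None:
                raise SchemaError(f"detritus {g.name!r} needs a biomass")
            continue
        unk = g.unknowns
        if len(unk) > 1:
            raise SchemaError(
                f"group {g.name!r} must have at most one unknown among B/PB/EE, "
                f"has {len(unk)}: {unk}"
            )

    DC = model.diet.DC
    const = _demand_constant(model)
    kind = model.kinds()
    living = kind != DETRITUS

    B = model.array("B")
    PB = model.array("PB")
    QB = model.array("QB", 0.0)
    EE = model.array("EE")

    # Coupled linear solve for unknown biomasses:
    #   B_i*PB_i*EE_i - sum_{j unknown} B_j*QB_j*DC[i,j] = known demand_i
    unknown_b = [i for i in range(n) if living[i] and groups[i].B is None]
    if unknown_b:
        idx = {i: k for k, i in enumerate(unknown_b)}
        m = len(unknown_b)
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        for k, i in enumerate(unknown_b):
            A[k, k] += PB[i] * EE[i]
            for j in range(n):
                pred = QB[j] * DC[i, j]
                if pred == 0.0:
                    continue
                if j in idx:
                    A[k, idx[j]] -= pred
                else:
                    rhs[k] += B[j] * pred
            rhs[k] += const[i]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            raise UnbalancedModelError(
                "singular system for unknown biomasses of "
                + ", ".join(groups[i].name for i in unknown_b)
            ) from None
        for i in unknown_b:
            B[i] = sol[idx[i]]

    predation = DC @ (B * QB)  # per-prey consumption by all predators

    for i in range(n):
        if not living[i]:
            continue
        demand = predation[i] + const[i]
        if groups[i].PB is None:
            if B[i] * EE[i] <= 0:
                raise UnbalancedModelError(
                    f"cannot solve PB of {groups[i].name!r} with B*EE = 0"
                )
            PB[i] = demand / (B[i] * EE[i])
        elif groups[i].EE is None:
            prod = B[i] * PB[i]
            if prod <= 0:
                raise UnbalancedModelError(
                    f"cannot solve EE of {groups[i].name!r} with zero production"
                )
            EE[i] = demand / prod

    # Validation
    for i in range(n):
        if not living[i]:
            continue
        nm = groups[i].name
        if not B[i] > 0:
            raise UnbalancedModelError(f"unbalanced model: solved B of {nm!r} is {B[i]:.4g}")
        if not -1e-12 <= EE[i] <= 1.0 + 1e-12:
            raise UnbalancedModelError(f"unbalanced model: EE of {nm!r} is {EE[i]:.4g}")
        EE[i] = min(max(EE[i], 0.0), 1.0)
        resid = B[i] * PB[i] * EE[i] - (predation[i] + const[i])
        scale = max(abs(B[i] * PB[i]), 1.0)
        if abs(resid) > RESIDUAL_TOL * scale:
            raise UnbalancedModelError(f"balance residual {resid:.3g} for {nm!r}")

    new_groups = tuple(
        replace(g, B=float(B[i]), PB=float(PB[i]) if living[i] else g.PB,
                EE=float(EE[i]) if living[i] else g.EE)
        for i, g in enumerate(groups)
    )
    balanced = replace(model, groups=new_groups, balanced=True)
    ledger = {d: detritus_ledger(balanced, d)["export"]
              for d in balanced.names if balanced.group(d).kind == DETRITUS}
    balanced = replace(balanced, detritus_export=ledger)
    for g in balanced.groups:
        if g.kind == CONSUMER:
            energy_budget(g)  # raises if U + PB/QB >= 1
    return balanced


def detritus_ledger(model: FoodWebModel, detritus: str) -> dict[str, float]:
    """Inflow/outflow bookkeeping for one detritus pool.

    Inflows: unassimilated consumption of all consumers, non-predation deaths
    ``B*PB*(1-EE)`` of all living groups, and fishery discards.  Outflow:
    consumption of the pool by detritivores.  The residual is booked as
    export (or, if negative, as a constant external import).  Multiple
    detritus pools share the inflow proportionally to their consumption;
    with a single pool (the usual case) it receives everything.
    """
    names = model.names
    d = model.index(detritus)
    kind = model.kinds()
    det_idx = [i for i in range(len(names)) if kind[i] == DETRITUS]
    B = model.array("B")
    QB = model.array("QB", 0.0)
    PB = model.array("PB", 0.0)
    EE = model.array("EE", 0.0)
    U = np.array([g.unassimilated for g in model.groups])

    unassim = float((U * B * QB).sum())
    deaths = float((B * PB * (1.0 - EE))[kind != DETRITUS].sum())
    discards = float(model.fleets.discards().sum())
    share = 1.0 / len(det_idx) if len(det_idx) > 1 else 1.0
    inflow = (unassim + deaths + discards) * share
    outflow = float((model.diet.DC[d, :] * B * QB).sum())
    return {
        "inflow": inflow,
        "outflow": outflow,
        "export": inflow - outflow,
    }


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_GROUP_COLS = ["name", "kind", "B", "PB", "QB", "EE", "U", "BA", "E", "stage_of"]


def write_foodweb(model: FoodWebModel, out_dir) -> dict[str, str]:
    """Write groups.csv, diet.csv, fleets.csv and fleet_meta.csv to *out_dir*.

    Unknown parameters are written as empty cells; the diet matrix carries a
    final ``import`` row.  Returns the mapping of table name to file path.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f"{k}.csv")
             for k in ("groups", "diet", "fleets", "fleet_meta")}

    rows = []
    for g in model.groups:
        rows.append({
            "name": g.name, "kind": g.kind, "B": g.B, "PB": g.PB, "QB": g.QB,
            "EE": g.EE, "U": g.U, "BA": g.BA, "E": g.E, "stage_of": g.stage_of,
        })
    pd.DataFrame(rows, columns=_GROUP_COLS).to_csv(paths["groups"], index=False)

    diet = pd.DataFrame(model.diet.DC, index=list(model.names), columns=list(model.names))
    diet.loc["import"] = model.diet.import_share
    diet.to_csv(paths["diet"], index_label="prey")

    ft = model.fleets
    pd.DataFrame(ft.Y, index=list(ft.group_names), columns=list(ft.fleets)).to_csv(
        paths["fleets"], index_label="group")
    meta = pd.DataFrame({
        "fleet": list(ft.fleets),
        "scope": [int(s) for s in ft.scope],
        "landed_fraction": [float(ft.landed_fraction[:, j].min()) for j in range(len(ft.fleets))],
    })
    meta.to_csv(paths["fleet_meta"], index=False)
    return paths


def read_foodweb(groups_csv, diet_csv, fleets_csv=None, fleet_meta_csv=None) -> FoodWebModel:
    """Read a model from the CSV schema written by :func:`write_foodweb`."""
    gdf = pd.read_csv(groups_csv)
    missing = set(_GROUP_COLS[:2]) - set(gdf.columns)
    if missing:
        raise SchemaError(f"groups.csv missing columns: {sorted(missing)}")

    def cell(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return row[col]

    groups = []
    for _, row in gdf.iterrows():
        groups.append(FunctionalGroup(
            name=str(row["name"]), kind=str(row["kind"]),
            B=cell(row, "B"), PB=cell(row, "PB"), QB=cell(row, "QB"),
            EE=cell(row, "EE"), U=cell(row, "U"),
            BA=cell(row, "BA") or 0.0, E=cell(row, "E") or 0.0,
            stage_of=cell(row, "stage_of"),
        ))
    names = tuple(g.name for g in groups)
    if len(set(names)) != len(names):
        raise SchemaError("duplicate group names in groups.csv")

    ddf = pd.read_csv(diet_csv, index_col=0)
    expect = list(names) + ["import"]
    if list(ddf.index) != expect or list(ddf.columns) != list(names):
        raise SchemaError("diet.csv rows/columns do not match groups.csv "
                          "(rows must be the groups plus a final 'import' row)")
    diet = DietMatrix(names, ddf.loc[list(names)].to_numpy(float),
                      ddf.loc["import"].to_numpy(float))
    diet.validate_columns(groups)

    if fleets_csv is None:
        fleets = FleetTable.empty(names)
    else:
        fdf = pd.read_csv(fleets_csv, index_col=0)
        if list(fdf.index) != list(names):
            raise SchemaError("fleets.csv rows do not match groups.csv")
        fleet_names = tuple(fdf.columns)
        Y = fdf.to_numpy(float)
        if fleet_meta_csv is not None:
            mdf = pd.read_csv(fleet_meta_csv)
            meta = {r["fleet"]: r for _, r in mdf.iterrows()}
            scope = tuple(bool(meta[f]["scope"]) for f in fleet_names)
            lf = np.column_stack([
                np.full(len(names), float(meta[f]["landed_fraction"])) for f in fleet_names
            ]) if fleet_names else np.zeros((len(names), 0))
        else:
            scope = tuple(True for _ in fleet_names)
            lf = np.ones_like(Y)
        fleets = FleetTable(fleet_names, names, Y, scope, lf)

    return FoodWebModel(tuple(groups), diet, fleets)
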