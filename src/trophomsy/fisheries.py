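"""Fleet effort, fishing mortality and landings revenue.

Fishing mortality is linear in fleet effort: each fleet's baseline F on a
group is its baseline catch divided by baseline biomass (catchability is
implicit), and scaling a fleet's effort by *x* scales its F contribution by
*x*.  Scope fleets — those entering a multispecies-MSY scan — share a single
common effort factor, mirroring the relative-stability principle of keeping
effort ratios between fleets fixed.  Revenue counts landings only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dynamics import DynamicParams

__all__ = ["PriceTable", "EffortRegime", "fishing_mortality", "revenue", "read_prices"]


@dataclass(frozen=True)
class PriceTable:
    """Per-group landed price in EUR per tonne."""

    price: Mapping[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.price.items() if v < 0}
        if bad:
            raise ValueError(f"negative prices: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.price[name]

    def __contains__(self, name: str) -> bool:
        return name in self.price


def read_prices(path) -> PriceTable:
    """Read a ``group,price_eur_per_tonne`` CSV."""
    df = pd.read_csv(path)
    return PriceTable(dict(zip(df["group"], df["price_eur_per_tonne"].astype(float))))


@dataclass(frozen=True)
class EffortRegime:
    """Per-fleet effort multipliers under the common-factor constraint.

    All scope fleets move together by ``common_factor``; non-scope fleets
    stay at their baseline effort unless explicitly overridden."""

    common_factor: float = 1.0
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.common_factor <= 0:
            raise ValueError("effort factor must be positive")
        if any(v <= 0 for v in self.overrides.values()):
            raise ValueError("effort multipliers must be positive")

    def multiplier(self, fleet: str, in_scope: bool) -> float:
        if fleet in self.overrides:
            return self.overrides[fleet]
        return self.common_factor if in_scope else 1.0

    def multipliers(self, params: DynamicParams) -> np.ndarray:
        return np.array([
            self.multiplier(f, s) for f, s in zip(params.fleet_names, params.fleet_scope)
        ])


def fishing_mortality(
    base_F_by_fleet: Mapping[str, float] | np.ndarray,
    regime: EffortRegime,
    fleet_scope: Mapping[str, bool] | None = None,
) -> float:
    """Total F (yr^-1) on one group: sum over fleets of baseline F times the
    fleet's effort multiplier.  ``base_F_by_fleet`` maps fleet name to the
    group's baseline F from that fleet; with an array input every fleet is
    treated as in scope unless ``fleet_scope`` says otherwise."""
    if isinstance(base_F_by_fleet, Mapping):
        items = base_F_by_fleet.items()
    else:
        items = ((f"fleet{i}", v) for i, v in enumerate(np.asarray(base_F_by_fleet)))
    total = 0.0
    for fleet, f0 in items:
        in_scope = True if fleet_scope is None else bool(fleet_scope.get(fleet, True))
        total += float(f0) * regime.multiplier(fleet, in_scope)
    return total


def revenue(
    catch_by_group_fleet: np.ndarray,
    landed_fraction: np.ndarray,
    prices: PriceTable,
    group_names: tuple[str, ...],
    scope_species: tuple[str, ...] | None = None,
) -> tuple[float, dict[str, float]]:
    """Landings revenue in EUR: per group ``sum_f C_gf * landed_gf * price_g``.

    Returns the total over ``scope_species`` (all groups with a price if not
    given) and the per-group breakdown.  A scope species without a price is
    an error; catches must be non-negative.
    """
    C = np.asarray(catch_by_group_fleet, dtype=float)
    if (C < -1e-12).any():
        raise ValueError("catches must be non-negative")
    lf = np.asarray(landed_fraction, dtype=float)
    scope = tuple(scope_species) if scope_species is not None else \
        tuple(g for g in group_names if g in prices)
    per_group: dict[str, float] = {}
    for g in scope:
        if g not in prices:
            raise KeyError(f"no price for scope species {g!r}")
        i = group_names.index(g)
        landed = float((C[i] * lf[i]).sum()) if C.ndim == 2 else float(C[i] * lf[i])
        per_group[g] = landed * prices[g]
    return sum(per_group.values()), per_group
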