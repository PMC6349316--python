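"""Time-dynamic trophic simulation (Ecosim-style).

Biomass dynamics follow, per functional group *i*,

    dB_i/dt = g_i * sum_prey Q(prey -> i)  -  sum_pred Q(i -> pred)
              - (M0_i + F_i(t)) * B_i  +  I_i  -  e_i * B_i

with ``g`` the net growth efficiency (PB/QB), ``M0`` the other-mortality
rate, ``F`` fishing mortality driven by fleet effort, and consumption ``Q``
given by a foraging-arena functional response controlled by a vulnerability
multiplier ``K``: ``K = 1`` is pure bottom-up control (predator abundance
cannot raise predation mortality), larger ``K`` lets predation mortality
rise up to ``K``-fold above its baseline as predators become abundant.
Producers replace the consumption-gain term with a saturating production
function that can be scaled by a forcing multiplier.

The balanced static snapshot is, by construction, a fixed point of these
dynamics at baseline effort (when BA = 0), which anchors every simulation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .foodweb import CONSUMER, DETRITUS, PRODUCER, FoodWebModel

__all__ = [
    "DynamicParams",
    "ForcingSet",
    "Trajectory",
    "TimeFunction",
    "derive_dynamic_params",
    "arena_consumption",
    "producer_production",
    "simulate",
    "equilibrium_summary",
]

BIOMASS_FLOOR_FRACTION = 1e-10


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Time functions (constants or breakpoint series, linear interpolation)
# ---------------------------------------------------------------------------

class TimeFunction:
    """Piecewise-linear function of time in years; constant outside its knots."""

    def __init__(self, value: float | Sequence[tuple[float, float]]):
        if np.isscalar(value):
            self._t = [0.0]
            self._v = [float(value)]
        else:
            pts = sorted((float(t), float(v)) for t, v in value)
            if not pts:
                raise ValueError("empty breakpoint series")
            self._t = [p[0] for p in pts]
            self._v = [p[1] for p in pts]

    def __call__(self, t: float) -> float:
        ts, vs = self._t, self._v
        if t <= ts[0]:
            return vs[0]
        if t >= ts[-1]:
            return vs[-1]
        k = bisect.bisect_right(ts, t)
        w = (t - ts[k - 1]) / (ts[k] - ts[k - 1])
        return vs[k - 1] * (1.0 - w) + vs[k] * w

    def __eq__(self, other):
        return isinstance(other, TimeFunction) and self._t == other._t and self._v == other._v


def _as_tf(v) -> TimeFunction:
    return v if isinstance(v, TimeFunction) else TimeFunction(v)


@dataclass(frozen=True)
class ForcingSet:
    """External forcings: producer production multipliers, forced biomass
    trajectories (absolute t km^-2), and per-fleet effort multipliers.
    Groups/fleets not listed default to multiplier 1 / unforced."""

    producer_multiplier: Mapping[str, TimeFunction] = field(default_factory=dict)
    forced_biomass: Mapping[str, TimeFunction] = field(default_factory=dict)
    effort_multiplier: Mapping[str, TimeFunction] = field(default_factory=dict)

    def __post_init__(self):
        for attr in ("producer_multiplier", "forced_biomass", "effort_multiplier"):
            object.__setattr__(self, attr,
                               {k: _as_tf(v) for k, v in getattr(self, attr).items()})


@dataclass(frozen=True)
class DynamicParams:
    """Rates derived from a balanced snapshot that drive the simulation.

    ``Q0[i, j]`` is the baseline consumption flow prey *i* -> predator *j*;
    ``K[i, j]`` the vulnerability multiplier of that link; ``g`` net growth
    efficiency per group (consumers); ``M0`` other-mortality (yr^-1);
    ``base_F`` group-by-fleet baseline fishing mortality; ``prod_sat`` the
    producer saturation factor *s* (production saturates at s/(s-1) times
    baseline as producer biomass grows)."""

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    B0: np.ndarray
    g: np.ndarray
    M0: np.ndarray
    Q0: np.ndarray
    K: np.ndarray
    Q0_import: np.ndarray
    PB0: np.ndarray
    U: np.ndarray
    base_F: np.ndarray          # group x fleet
    fleet_names: tuple[str, ...]
    fleet_scope: tuple[bool, ...]
    landed_fraction: np.ndarray
    migration: np.ndarray       # net migration rate e (yr^-1), emigration > 0
    det_export_rate: np.ndarray  # per-group, nonzero for detritus pools
    det_import: np.ndarray       # constant inflow for detritus pools
    stage_links: tuple = ()
    prod_sat: float = 2.0

    def with_K(self, K: np.ndarray) -> "DynamicParams":
        return replace(self, K=np.asarray(K, dtype=float))

    def index(self, name: str) -> int:
        return self.names.index(name)


def derive_dynamic_params(
    model: FoodWebModel,
    K: np.ndarray | float = 2.0,
    prod_sat: float = 2.0,
) -> DynamicParams:
    """Extract simulation rates from a balanced model.

    ``K`` may be a scalar (applied to every trophic link) or a full
    prey-by-predator matrix.  Raises if the model is not balanced.
    """
    if not model.balanced:
        raise ValueError("model must be balanced first")
    n = len(model.groups)
    B0 = model.array("B")
    PB = model.array("PB", 0.0)
    QB = model.array("QB", 0.0)
    EE = model.array("EE", 0.0)
    U = np.array([g.unassimilated for g in model.groups])
    kinds = tuple(g.kind for g in model.groups)
    living = np.array([k != DETRITUS for k in kinds])

    g_eff = np.zeros(n)
    cons = np.array([k == CONSUMER for k in kinds])
    g_eff[cons] = PB[cons] / QB[cons]

    Q0 = model.diet.DC * (B0 * QB)[None, :]
    Q0_import = model.diet.import_share * B0 * QB
    M0 = np.where(living, PB * (1.0 - EE), 0.0)

    K_mat = np.full((n, n), float(K)) if np.isscalar(K) else np.asarray(K, dtype=float)
    if K_mat.shape != (n, n):
        raise ValueError("K matrix shape mismatch")
    if (K_mat[Q0 > 0] < 1.0).any():
        raise ValueError("vulnerability K must be >= 1 on every active link")

    ft = model.fleets
    with np.errstate(divide="ignore", invalid="ignore"):
        base_F = np.where(B0[:, None] > 0, ft.Y / B0[:, None], 0.0)

    staged = {lk.adult for lk in model.stage_links} | {lk.juvenile for lk in model.stage_links}
    migration = np.array([
        0.0 if g.name in staged else g.E / B0[i] for i, g in enumerate(model.groups)
    ])

    det_export_rate = np.zeros(n)
    det_import = np.zeros(n)
    for i, gk in enumerate(kinds):
        if gk == DETRITUS:
            exp = model.detritus_export.get(model.groups[i].name, 0.0)
            if exp >= 0:
                det_export_rate[i] = exp / B0[i]
            else:
                det_import[i] = -exp

    return DynamicParams(
        names=model.names, kinds=kinds, B0=B0, g=g_eff, M0=M0, Q0=Q0,
        K=K_mat, Q0_import=Q0_import, PB0=PB, U=U,
        base_F=base_F, fleet_names=ft.fleets, fleet_scope=ft.scope,
        landed_fraction=ft.landed_fraction, migration=migration,
        det_export_rate=det_export_rate, det_import=det_import,
        stage_links=model.stage_links, prod_sat=prod_sat,
    )


def arena_consumption(prey_B, pred_B, prey_B0, pred_B0, Q0, K=1.0):
    """Foraging-arena consumption flow (t km^-2 yr^-1).

    ``Q = Q0 * (prey_B/prey_B0) * K*p / (K - 1 + p)`` with relative predator
    abundance ``p = pred_B/pred_B0``.  At the base state Q equals Q0.  With
    ``K = 1`` consumption is independent of predator biomass (pure bottom-up
    control); for ``K > 1`` predation mortality rises with predator abundance
    but saturates at ``K`` times its baseline.
    """
    K = np.asarray(K, dtype=float)
    if (K < 1.0).any() if K.ndim else K < 1.0:
        raise ValueError("vulnerability K must be >= 1")
    p = np.asarray(pred_B, dtype=float) / pred_B0
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = np.where(K == 1.0, 1.0, K * p / (K - 1.0 + p))
    return Q0 * (np.asarray(prey_B, dtype=float) / prey_B0) * bracket


def producer_production(B, B0, PB0, multiplier=1.0, s=2.0):
    """Saturating primary production (t km^-2 yr^-1).

    ``P = multiplier * PB0 * B0 * s*x / (1 + (s-1)*x)`` with ``x = B/B0``;
    equals ``multiplier * PB0 * B0`` at base biomass and saturates at
    ``s/(s-1)`` times that as the stock grows.  ``s`` must exceed 1.
    """
    if s <= 1.0:
        raise ValueError("producer saturation factor s must be > 1")
    x = np.asarray(B, dtype=float) / B0
    return multiplier * PB0 * B0 * (s * x) / (1.0 + (s - 1.0) * x)


@dataclass(frozen=True)
class Trajectory:
    """Simulated state sampled at every integration step.

    ``B`` is biomass (t km^-2); ``Q`` annualized consumption flows
    (prey x predator); ``C`` annualized catch rates per fleet and ``F`` the
    total fishing mortality.  All arrays share the leading time axis."""

    times: np.ndarray           # (T,)
    names: tuple[str, ...]
    fleet_names: tuple[str, ...]
    B: np.ndarray               # (T, n)
    Q: np.ndarray               # (T, n, n)
    C: np.ndarray               # (T, n, nf)
    F: np.ndarray               # (T, n)
    steps_per_year: int = 12

    def years(self) -> float:
        return float(self.times[-1])


def _rhs(state, t, P: DynamicParams, forcing: ForcingSet,
         prod_idx, forced_idx, forced_funcs, effort_funcs, stage_idx):
    """Time derivative of the biomass vector, plus diagnostic flows."""
    n = len(P.names)
    B = np.maximum(state, BIOMASS_FLOOR_FRACTION * P.B0)

    rel = B / P.B0
    # Arena consumption on every link: prey scaling x predator saturation
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = np.where(P.K == 1.0, 1.0,
                           P.K * rel[None, :] / (P.K - 1.0 + rel[None, :]))
    Q = P.Q0 * rel[:, None] * bracket
    Q_imp = P.Q0_import * rel   # imported diet scales with predator biomass

    intake = Q.sum(axis=0) + Q_imp
    losses = Q.sum(axis=1)

    # Fishing mortality: linear in per-fleet effort multipliers
    mult = np.array([f(t) for f in effort_funcs])
    F = P.base_F @ mult
    C = P.base_F * mult[None, :] * B[:, None]

    dB = P.g * intake - losses - (P.M0 + F + P.migration) * B

    # Producers: saturating production replaces the consumption-gain term
    for i in prod_idx:
        m = forcing.producer_multiplier.get(P.names[i])
        m_val = m(t) if m is not None else 1.0
        dB[i] = (producer_production(B[i], P.B0[i], P.PB0[i], m_val, P.prod_sat)
                 - losses[i] - (P.M0[i] + F[i] + P.migration[i]) * B[i])

    # Detritus: ledger flows (unassimilated intake + other-mortality deaths
    # + discards) in, detritivore consumption + linear export out
    disc_rate = (P.base_F * mult[None, :] * (1.0 - P.landed_fraction)) @ np.ones(len(mult))
    for i, k in enumerate(P.kinds):
        if k == DETRITUS:
            inflow = (P.U * intake).sum() + (P.M0 * B).sum() + (disc_rate * B).sum() \
                + P.det_import[i]
            dB[i] = inflow - losses[i] - P.det_export_rate[i] * B[i]

    # Stage transfers: recruitment (a fraction of adult production, at the
    # baseline production rate per unit adult biomass, hence linear in adult
    # biomass) in, graduation out; mass-conserving between the two pools
    for (ia, ij, r, grad) in stage_idx:
        t_in = r * P.PB0[ia] * B[ia]
        t_out = grad * B[ij]
        dB[ij] += t_in - t_out
        dB[ia] += t_out - t_in

    # Forced groups are pinned: no free dynamics
    for i in forced_idx:
        dB[i] = 0.0

    return dB, Q, C, F


def simulate(
    model: FoodWebModel,
    params: DynamicParams,
    forcing: ForcingSet | None = None,
    years: float = 200.0,
    steps_per_year: int = 12,
) -> Trajectory:
    """Integrate the dynamics with fixed-step RK4 from the base state.

    Groups with a forced-biomass time function are reset to the forced value
    at every step while still consuming prey and suffering recorded catch.
    A biomass floor of ``1e-10 * B0`` is enforced throughout.
    """
    if not model.balanced:
        raise ValueError("model must be balanced first")
    forcing = forcing or ForcingSet()
    P = params
    n = len(P.names)
    for nm in list(forcing.forced_biomass) + list(forcing.producer_multiplier):
        if nm not in P.names:
            raise KeyError(f"forcing references unknown group {nm!r}")

    prod_idx = [i for i, k in enumerate(P.kinds) if k == PRODUCER]
    forced_funcs = {P.index(nm): f for nm, f in forcing.forced_biomass.items()}
    forced_idx = sorted(forced_funcs)
    effort_funcs = [forcing.effort_multiplier.get(f, TimeFunction(1.0))
                    for f in P.fleet_names]
    stage_idx = [(P.index(lk.adult), P.index(lk.juvenile),
                  lk.recruitment_fraction, lk.graduation_rate)
                 for lk in P.stage_links]

    nsteps = int(round(years * steps_per_year))
    dt = 1.0 / steps_per_year
    floor = BIOMASS_FLOOR_FRACTION * P.B0

    times = np.empty(nsteps + 1)
    Bt = np.empty((nsteps + 1, n))
    Qt = np.empty((nsteps + 1, n, n))
    Ct = np.empty((nsteps + 1, n, len(P.fleet_names)))
    Ft = np.empty((nsteps + 1, n))

    B = P.B0.copy()
    for i in forced_idx:
        B[i] = forced_funcs[i](0.0)
    for step in range(nsteps + 1):
        t = step * dt
        dB, Q, C, F = _rhs(B, t, P, forcing, prod_idx, forced_idx,
                           forced_funcs, effort_funcs, stage_idx)
        times[step] = t
        Bt[step] = B
        Qt[step] = Q
        Ct[step] = C
        Ft[step] = F
        if step == nsteps:
            break
        k1 = dB
        k2 = _rhs(B + 0.5 * dt * k1, t + 0.5 * dt, P, forcing, prod_idx,
                  forced_idx, forced_funcs, effort_funcs, stage_idx)[0]
        k3 = _rhs(B + 0.5 * dt * k2, t + 0.5 * dt, P, forcing, prod_idx,
                  forced_idx, forced_funcs, effort_funcs, stage_idx)[0]
        k4 = _rhs(B + dt * k3, t + dt, P, forcing, prod_idx,
                  forced_idx, forced_funcs, effort_funcs, stage_idx)[0]
        B = B + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(B).all():
            bad = P.names[int(np.argmax(~np.isfinite(B)))]
            raise IntegrationError(f"non-finite biomass for {bad!r} at t = {t + dt:.3f} yr")
        B = np.maximum(B, floor)
        for i in forced_idx:            # hard reset to the forced trajectory
            B[i] = forced_funcs[i]((step + 1) * dt)

    return Trajectory(times=times, names=P.names, fleet_names=P.fleet_names,
                      B=Bt, Q=Qt, C=Ct, F=Ft, steps_per_year=steps_per_year)


def equilibrium_summary(traj: Trajectory) -> dict:
    """Annual-mean state over the next-to-last simulated year.

    For a ``years``-long run this is simulated year ``years - 1`` (1-based),
    i.e. the mean over the window ``[years - 2, years - 1)``.  Requires at
    least two simulated years.
    """
    spy = traj.steps_per_year
    total_years = int(round(traj.times[-1]))
    if total_years < 2:
        raise ValueError("trajectory must span at least 2 years")
    lo = (total_years - 2) * spy
    hi = (total_years - 1) * spy
    sl = slice(lo, hi)
    B = traj.B[sl].mean(axis=0)
    C = traj.C[sl].mean(axis=0)
    F = traj.F[sl].mean(axis=0)
    return {
        "names": traj.names,
        "fleet_names": traj.fleet_names,
        "B": B,
        "C": C.sum(axis=1),
        "C_by_fleet": C,
        "F": F,
        "C_fleet_totals": C.sum(axis=0),
    }
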