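"""Simulation loop: advance the nine stocks period by period to the horizon.

Within a period every equation reads start-of-period stocks; all stocks are
then updated simultaneously from their flows.  Guard clamps (stock floors,
the zero-population rule on the per-capita health stock) are logged as
structured events, never silent — extinction of a group is exactly the event
"population stock clamped to 0".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import dynamics
from .response_functions import RandomStream
from .state import (
    ClampEvent,
    ControllerSet,
    GroupState,
    ParameterSet,
    PeriodRecord,
    ScenarioSet,
    SimulationTrace,
)

__all__ = ["Storyline", "SiteLags", "ModelState", "step", "run"]


@dataclass
class SiteLags:
    """Previous-period conflict risk and intensity per site (the t-1 terms
    of the conflict equations; initial values come from the storyline)."""

    o_cr: float = 0.0
    o_ci: float = 0.0
    d_cr: float = 0.0
    d_ci: float = 0.0


@dataclass
class Storyline:
    """A complete input bundle: parameters, scenario series, controllers,
    initial stocks and lagged values, and the random seed."""

    name: str
    params: ParameterSet
    scenarios: ScenarioSet
    controllers: ControllerSet
    origin: GroupState
    immigrants: GroupState
    natives: GroupState
    lags: SiteLags = field(default_factory=SiteLags)
    seed: int = 0

    def validate(self) -> None:
        self.params.validate()
        self.scenarios.validate(self.params.endtime_p)
        self.controllers.validate(self.params.endtime_p)

    def copy(self) -> "Storyline":
        return Storyline(
            name=self.name,
            params=replace(self.params),
            scenarios=self.scenarios.copy(),
            controllers=self.controllers.copy(),
            origin=self.origin.copy(),
            immigrants=self.immigrants.copy(),
            natives=self.natives.copy(),
            lags=replace(self.lags),
            seed=self.seed,
        )


@dataclass
class ModelState:
    """All stocks plus conflict lags at the start of a period."""

    origin: GroupState
    immigrants: GroupState
    natives: GroupState
    lags: SiteLags


def _compute_period(
    t: int, state: ModelState, storyline: Storyline, stream: RandomStream
) -> tuple[PeriodRecord, dynamics.ConflictOutcome, dynamics.ConflictOutcome]:
    scen = storyline.scenarios
    params = storyline.params
    fb = params.functions
    ctrl = storyline.controllers

    o_conf = dynamics.origin_conflict(
        state.origin, state.lags.o_cr, state.lags.o_ci, scen, t, fb, ctrl, stream
    )
    d_conf = dynamics.destination_conflict(
        state.immigrants, state.natives, state.lags.d_cr, state.lags.d_ci,
        scen, t, fb, ctrl, stream,
    )
    migration = dynamics.migration_step(
        state.origin, state.immigrants, state.natives,
        o_conf.intensity, d_conf.intensity, scen, t, fb, ctrl,
    )
    o_vals = dynamics.origin_flows(
        state.origin, o_conf, migration, scen, t, params, stream
    )
    d_vals = dynamics.destination_flows(
        state.immigrants, state.natives, d_conf, migration, scen, t, params, stream
    )

    values: dict[str, float] = {
        "t": float(t),
        "o_pop_s": state.origin.pop_s,
        "o_hppc_s": state.origin.hppc_s,
        "o_ep_s": state.origin.ep_s,
        "di_pop_s": state.immigrants.pop_s,
        "di_hppc_s": state.immigrants.hppc_s,
        "di_ep_s": state.immigrants.ep_s,
        "dn_pop_s": state.natives.pop_s,
        "dn_hppc_s": state.natives.hppc_s,
        "dn_ep_s": state.natives.ep_s,
        "o_cr_a": o_conf.risk,
        "o_ci_a": o_conf.intensity,
        "d_cr_a": d_conf.risk,
        "d_ci_a": d_conf.intensity,
        "o_nm_a": migration.o_nm_a,
        "d_nm_a": migration.d_nm_a,
        "od_nm_a": migration.od_nm_a,
        "od_imhppc_a": migration.od_imhppc_a,
    }
    values.update(o_vals)
    values.update(d_vals)

    for name, v in values.items():
        if not math.isfinite(v):
            raise ArithmeticError(f"non-finite value for {name} at period {t}: {v!r}")
    return PeriodRecord(values), o_conf, d_conf


_STOCK_UPDATES = (
    # (group attr, stock attr, flow record name, is per-capita health stock)
    ("origin", "pop_s", "o_pop_f"),
    ("origin", "hppc_s", "o_hppc_f"),
    ("origin", "ep_s", "o_ep_f"),
    ("immigrants", "pop_s", "di_pop_f"),
    ("immigrants", "hppc_s", "di_hppc_f"),
    ("immigrants", "ep_s", "di_ep_f"),
    ("natives", "pop_s", "dn_pop_f"),
    ("natives", "hppc_s", "dn_hppc_f"),
    ("natives", "ep_s", "dn_ep_f"),
)


def _advance(
    t: int, state: ModelState, record: PeriodRecord, events: list[ClampEvent]
) -> ModelState:
    """Simultaneous stock update: stock(t+1) = clamp(stock(t) + flow(t));
    an emptied group's per-capita health stock is reset to 0."""
    new_groups: dict[str, dict[str, float]] = {"origin": {}, "immigrants": {}, "natives": {}}
    for group, attr, flow_name in _STOCK_UPDATES:
        raw = getattr(getattr(state, group), attr) + record[flow_name]
        clamped = max(raw, 0.0)
        if clamped != raw:
            events.append(ClampEvent(t + 1, f"{group}.{attr}", raw, clamped))
        new_groups[group][attr] = clamped
    # zero-population rule on the per-capita health stock
    for group in new_groups:
        g = new_groups[group]
        if g["pop_s"] == 0.0 and g["hppc_s"] != 0.0:
            events.append(ClampEvent(t + 1, f"{group}.hppc_s", g["hppc_s"], 0.0))
            g["hppc_s"] = 0.0
    lags = SiteLags(
        o_cr=record["o_cr_a"], o_ci=record["o_ci_a"],
        d_cr=record["d_cr_a"], d_ci=record["d_ci_a"],
    )
    return ModelState(
        origin=GroupState(**new_groups["origin"]),
        immigrants=GroupState(**new_groups["immigrants"]),
        natives=GroupState(**new_groups["natives"]),
        lags=lags,
    )


def step(
    state: ModelState,
    t: int,
    storyline: Storyline,
    stream: RandomStream,
    events: list[ClampEvent] | None = None,
) -> tuple[ModelState, PeriodRecord]:
    """Compute period ``t`` and advance the stocks to ``t + 1``."""
    if events is None:
        events = []
    record, _, _ = _compute_period(t, state, storyline, stream)
    new_state = _advance(t, state, record, events)
    return new_state, record


def run(storyline: Storyline, seed: int | None = None) -> SimulationTrace:
    """Simulate the storyline over its full horizon.

    Returns a trace with ``endtime_p + 1`` period records (t = 0..endtime);
    the final period's auxiliaries and flows are recorded but its flows are
    not applied.  Deterministic given the seed.
    """
    storyline.validate()
    if seed is None:
        seed = storyline.seed
    stream = RandomStream(seed)
    state = ModelState(
        origin=storyline.origin.copy(),
        immigrants=storyline.immigrants.copy(),
        natives=storyline.natives.copy(),
        lags=replace(storyline.lags),
    )
    records: list[PeriodRecord] = []
    events: list[ClampEvent] = []
    for t in range(storyline.params.endtime_p + 1):
        record, _, _ = _compute_period(t, state, storyline, stream)
        records.append(record)
        if t < storyline.params.endtime_p:
            state = _advance(t, state, record, events)
    return SimulationTrace(records=records, storyline=storyline, seed=seed, clamp_events=events)
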