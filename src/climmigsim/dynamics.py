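"""Pure per-period computations: conflict, migration, services, and flows.

Each function reads start-of-period stocks and the period's scenario values
and returns auxiliaries/flows; nothing here mutates state.  The engine calls
them in fixed order (conflict -> migration -> origin blocks -> destination
blocks) and applies all stock updates simultaneously at period end.

Site blocks share the same skeleton: a *need for provision* arises when a
problem stock tops its threshold and is discounted by access barriers; an
*effective* service quality/capacity is the scenario base minus conflict and
climate damage; provision is the lesser of need and capacity, split across
groups under shortage; provided service times quality reduces the problem
flow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .response_functions import FunctionBank, RandomStream
from .state import (
    ControllerSet,
    GroupState,
    ParameterSet,
    ScenarioSet,
    clamp_state,
    per_capita,
)

__all__ = [
    "ConflictOutcome",
    "MigrationOutcome",
    "conflict_step",
    "origin_conflict",
    "destination_conflict",
    "migration_step",
    "effective_service",
    "need_for_provision",
    "allocate_capacity",
    "mixing_adjustment",
    "origin_flows",
    "destination_flows",
]


# ---------------------------------------------------------------------------
# Conflict


@dataclass(frozen=True)
class ConflictOutcome:
    """Conflict risk (a probability), realised intensity, and the uniform
    threshold drawn against the risk (None when the intensity was taken from
    an override series and no draw was consumed)."""

    risk: float
    intensity: float
    drawn_threshold: float | None


def conflict_step(
    risk_sum: float,
    intensity_sum: float,
    override: float | None,
    stream: RandomStream,
    substream: str,
) -> ConflictOutcome:
    """Resolve one site's conflict for the period.

    The computed risk (clamped into [0, 1]) is compared with a uniform draw;
    conflict breaks out — intensity ``intensity_sum`` — only if the risk
    strictly tops the drawn threshold.  With an override, the intensity
    follows the override series and the draw is skipped entirely.
    """
    risk = clamp_state(risk_sum, "risk")
    if override is not None:
        return ConflictOutcome(risk=risk, intensity=float(override), drawn_threshold=None)
    threshold = stream.uniform(substream)
    intensity = intensity_sum if risk > threshold else 0.0
    return ConflictOutcome(risk=risk, intensity=intensity, drawn_threshold=threshold)


def origin_conflict(
    origin: GroupState,
    lag_risk: float,
    lag_intensity: float,
    scen: ScenarioSet,
    t: int,
    fb: FunctionBank,
    controllers: ControllerSet,
    stream: RandomStream,
) -> ConflictOutcome:
    eicc = scen.at("o_eicc_x", t)
    risk = (
        fb.r(1, origin.pop_s)
        + fb.r(2, lag_risk)
        + fb.rf(1, eicc)
        + fb.rf(2, lag_intensity)
        + fb.rf(3, origin.hppc_s)
        + scen.at("o_cr_tx", t)
    )
    intensity = (
        fb.r(3, origin.pop_s)
        + fb.rf(4, eicc)
        + fb.rf(5, lag_intensity)
        + fb.rf(6, origin.hppc_s)
        + scen.at("o_ci_tx", t)
    )
    override = controllers.value("o_ci_a", t) if controllers.overridden("o_ci_a") else None
    return conflict_step(risk, intensity, override, stream, "origin_conflict")


def destination_conflict(
    di: GroupState,
    dn: GroupState,
    lag_risk: float,
    lag_intensity: float,
    scen: ScenarioSet,
    t: int,
    fb: FunctionBank,
    controllers: ControllerSet,
    stream: RandomStream,
) -> ConflictOutcome:
    eicc = scen.at("d_eicc_x", t)
    risk = (
        fb.r(4, di.pop_s)
        + fb.r(5, dn.pop_s)
        + fb.r(6, lag_risk)
        + fb.rf(7, eicc)
        + fb.rf(8, lag_intensity)
        + fb.rf(9, di.hppc_s)
        + fb.rf(10, dn.hppc_s)
        + scen.at("d_cr_tx", t)
    )
    intensity = (
        fb.r(7, di.pop_s)
        + fb.r(8, dn.pop_s)
        + fb.rf(11, eicc)
        + fb.rf(12, lag_intensity)
        + fb.rf(13, di.hppc_s)
        + fb.rf(14, dn.hppc_s)
        + scen.at("d_ci_tx", t)
    )
    override = controllers.value("d_ci_a", t) if controllers.overridden("d_ci_a") else None
    return conflict_step(risk, intensity, override, stream, "destination_conflict")


# ---------------------------------------------------------------------------
# Migration


@dataclass(frozen=True)
class MigrationOutcome:
    """Movers this period and their health on arrival, plus the origin-push
    and destination-pull components of the mover count."""

    od_nm_a: float
    od_imhppc_a: float
    o_nm_a: float
    d_nm_a: float


def migration_step(
    origin: GroupState,
    di: GroupState,
    dn: GroupState,
    o_ci: float,
    d_ci: float,
    scen: ScenarioSet,
    t: int,
    fb: FunctionBank,
    controllers: ControllerSet,
) -> MigrationOutcome:
    """Mover count = origin push + destination pull + pair TNE, floored at 0
    and capped at the origin population; arrival health = origin health
    times the selection ratio (healthier or sicker than average movers)."""
    ratio = scen.at("od_nmhppc_x", t)
    if ratio < 0:
        raise ValueError("selection ratio od_nmhppc_x must be >= 0")
    o_nm = (
        fb.r(9, origin.pop_s)
        + fb.rf(15, origin.hppc_s)
        + fb.rf(16, origin.ep_s)
        + fb.rf(17, o_ci)
        + fb.rf(18, scen.at("o_eicc_x", t))
        + scen.at("o_nm_tx", t)
    )
    d_nm = (
        fb.r(10, di.pop_s)
        + fb.r(11, dn.pop_s)
        - fb.r(12, di.hppc_s)
        - fb.r(13, dn.hppc_s)
        - fb.r(14, di.ep_s)
        - fb.r(15, dn.ep_s)
        - fb.r(16, d_ci)
        - fb.r(17, scen.at("d_eicc_x", t))
        + scen.at("d_nm_tx", t)
    )
    if controllers.overridden("od_nm_a"):
        movers = controllers.value("od_nm_a", t)
    else:
        movers = o_nm + d_nm + scen.at("od_nm_tx", t)
    movers = min(max(movers, 0.0), origin.pop_s)
    if controllers.overridden("od_imhppc_a"):
        arrival_hppc = controllers.value("od_imhppc_a", t)
    else:
        arrival_hppc = origin.hppc_s * ratio
    return MigrationOutcome(
        od_nm_a=movers, od_imhppc_a=arrival_hppc, o_nm_a=o_nm, d_nm_a=d_nm
    )


# ---------------------------------------------------------------------------
# Service building blocks


def need_for_provision(
    stock: float,
    threshold: float,
    barrier: float,
    pop: float = 1.0,
    per_population: bool = True,
) -> float:
    """Service need for provision: the excess of the problem stock over the
    need threshold, discounted by the access barrier, scaled by population
    (health care and destination environmental services) or population-free
    (origin environmental services)."""
    if not 0.0 <= barrier <= 1.0:
        raise ValueError(f"barrier must lie in [0, 1], got {barrier}")
    need = max(stock - threshold, 0.0) * (1.0 - barrier)
    return need * pop if per_population else need


def effective_service(
    base_quality: float,
    base_capacity: float,
    conflict_intensity: float,
    eicc: float,
    quality_damage: tuple,
    capacity_damage: tuple,
) -> tuple[float, float]:
    """Quality and capacity after conflict and climate damage: base scenario
    values minus the damage responses, quality clamped into [0, 1] and
    capacity floored at 0."""
    q_ci, q_ei = quality_damage
    c_ci, c_ei = capacity_damage
    quality = clamp_state(base_quality - q_ci(conflict_intensity) - q_ei(eicc), "quality")
    capacity = max(base_capacity - c_ci(conflict_intensity) - c_ei(eicc), 0.0)
    return quality, capacity


def allocate_capacity(
    needs: tuple[float, float],
    capacity: float,
    mode: int,
    shares: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Split service capacity across groups.

    With sufficient capacity every group receives its need.  Under shortage,
    mode 1 divides the capacity by the groups' shares of the total need;
    mode 2 uses fixed scenario shares, capped at each group's need so that
    provision always addresses need.
    """
    total = sum(needs)
    if capacity < 0 or any(n < 0 for n in needs):
        raise ValueError("needs and capacity must be non-negative")
    if total <= capacity:
        return tuple(needs)
    if mode == 1:
        return tuple(n / total * capacity for n in needs)
    if mode == 2:
        if shares is None:
            raise ValueError("mode-2 allocation requires fixed shares")
        return tuple(min(s * capacity, n) for s, n in zip(shares, needs))
    raise ValueError(f"unknown capacity split mode {mode!r}")


def mixing_adjustment(
    movers: float,
    pool_pop: float,
    pool_hppc: float,
    mover_hppc: float,
    direction: str,
) -> float:
    """Health-mixing term on a per-capita flow when movers leave or join a
    pool.

    On departure the pool's average health problems rise if the leavers were
    healthier than the pool (positive term); on arrival the pool's level is
    pulled toward the arrivals' level.  An emptied pool contributes 0 under
    the zero-population rule.
    """
    if direction == "departure":
        movers = min(movers, pool_pop)
        remaining = pool_pop - movers
        if remaining == 0.0:
            return 0.0
        return movers / remaining * (pool_hppc - mover_hppc)
    if direction == "arrival":
        merged = pool_pop + movers
        if merged == 0.0:
            return 0.0
        return movers / merged * (mover_hppc - pool_hppc)
    raise ValueError(f"unknown mixing direction {direction!r}")


# ---------------------------------------------------------------------------
# Origin flows (health care, environmental services, population)


def origin_flows(
    origin: GroupState,
    conflict: ConflictOutcome,
    migration: MigrationOutcome,
    scen: ScenarioSet,
    t: int,
    params: ParameterSet,
    stream: RandomStream,
) -> dict[str, float]:
    """Origin-site auxiliaries and the three origin flows for period t."""
    fb = params.functions
    eicc = scen.at("o_eicc_x", t)
    ci = conflict.intensity
    movers = migration.od_nm_a

    # health care block
    o_tnhcfp = need_for_provision(
        origin.hppc_s, params.hchppc_p, scen.at("o_hcb_x", t), origin.pop_s
    )
    o_hcq, o_hcc = effective_service(
        scen.at("o_hcq_x", t), scen.at("o_hcc_x", t), ci, eicc,
        quality_damage=(lambda x: fb.r(18, x), lambda x: fb.r(19, x)),
        capacity_damage=(lambda x: fb.r(20, x), lambda x: fb.r(21, x)),
    )
    o_phchppc = per_capita(min(o_tnhcfp, o_hcc), origin.pop_s) * o_hcq

    # emigration mixing on the origin's per-capita health stock
    o_emhppc = mixing_adjustment(
        movers, origin.pop_s, origin.hppc_s, migration.od_imhppc_a, "departure"
    )

    chance = stream.normal("origin_hp_chance", params.vhppc_p)
    o_hppc_f = (
        params.wthppc_p
        + fb.r(22, origin.ep_s)
        + fb.r(23, ci)
        + fb.r(24, eicc)
        + o_emhppc
        + chance
        - params.shhppc_p
        - o_phchppc
        + scen.at("o_hppc_tx", t)
    )

    # environmental services block (origin need is population-free)
    o_tnesfp = need_for_provision(
        origin.ep_s, params.esep_p, scen.at("o_esb_x", t), per_population=False
    )
    o_esq, o_esc = effective_service(
        scen.at("o_esq_x", t), scen.at("o_esc_x", t), ci, eicc,
        quality_damage=(lambda x: fb.r(25, x), lambda x: fb.r(26, x)),
        capacity_damage=(lambda x: fb.r(27, x), lambda x: fb.r(28, x)),
    )
    o_tpesep = min(o_tnesfp, o_esc) * o_esq

    o_ep_f = (
        params.o_ieppc_p * (origin.pop_s - movers)
        + fb.rf(19, ci)
        + fb.rf(20, eicc)
        - o_tpesep
        - params.o_decrep_p * origin.ep_s
        + scen.at("o_ep_tx", t)
    )

    o_pop_f = (
        origin.pop_s
        * (params.o_netbr_p - fb.r(29, origin.hppc_s) + scen.at("o_popgr_tx", t))
        - movers
    )

    return {
        "o_tnhcfp_a": o_tnhcfp, "o_hcq_a": o_hcq, "o_hcc_a": o_hcc,
        "o_phchppc_a": o_phchppc, "o_emhppc_a": o_emhppc,
        "o_tnesfp_a": o_tnesfp, "o_esq_a": o_esq, "o_esc_a": o_esc,
        "o_tpesep_a": o_tpesep,
        "o_hppc_f": o_hppc_f, "o_ep_f": o_ep_f, "o_pop_f": o_pop_f,
    }


# ---------------------------------------------------------------------------
# Destination flows (two groups sharing site capacities)


def destination_flows(
    di: GroupState,
    dn: GroupState,
    conflict: ConflictOutcome,
    migration: MigrationOutcome,
    scen: ScenarioSet,
    t: int,
    params: ParameterSet,
    stream: RandomStream,
) -> dict[str, float]:
    """Destination auxiliaries and the six destination flows for period t.

    Immigrants and natives each have their own needs, barriers and
    qualities but share the site's health-care and environmental-service
    capacities; under shortage the capacity is split per the scenario's
    division mode.
    """
    fb = params.functions
    eicc = scen.at("d_eicc_x", t)
    ci = conflict.intensity
    movers = migration.od_nm_a

    # --- health care block
    di_tnhcfp = need_for_provision(
        di.hppc_s, params.hchppc_p, scen.at("di_hcb_x", t), di.pop_s
    )
    dn_tnhcfp = need_for_provision(
        dn.hppc_s, params.hchppc_p, scen.at("dn_hcb_x", t), dn.pop_s
    )
    d_tnhcfp = di_tnhcfp + dn_tnhcfp

    di_hcq, _ = effective_service(
        scen.at("di_hcq_x", t), 0.0, ci, eicc,
        quality_damage=(lambda x: fb.r(30, x), lambda x: fb.r(31, x)),
        capacity_damage=(lambda x: 0.0, lambda x: 0.0),
    )
    dn_hcq, _ = effective_service(
        scen.at("dn_hcq_x", t), 0.0, ci, eicc,
        quality_damage=(lambda x: fb.r(32, x), lambda x: fb.r(33, x)),
        capacity_damage=(lambda x: 0.0, lambda x: 0.0),
    )
    d_hcc = max(scen.at("d_hcc_x", t) - fb.r(34, ci) - fb.r(35, eicc), 0.0)

    hc_mode = int(scen.at("d_divhcc_x", t))
    di_phc, dn_phc = allocate_capacity(
        (di_tnhcfp, dn_tnhcfp), d_hcc, hc_mode,
        shares=(scen.at("di_hccsha_x", t), scen.at("dn_hccsha_x", t)),
    )
    di_phcpc = per_capita(di_phc, di.pop_s)
    dn_phcpc = per_capita(dn_phc, dn.pop_s)
    di_phchppc = di_phcpc * di_hcq
    dn_phchppc = dn_phcpc * dn_hcq

    # arrivals mix into the immigrant group within the period
    di_imhppc = mixing_adjustment(
        movers, di.pop_s, di.hppc_s, migration.od_imhppc_a, "arrival"
    )

    di_chance = stream.normal("immigrant_hp_chance", params.vhppc_p)
    dn_chance = stream.normal("native_hp_chance", params.vhppc_p)

    di_hppc_f = (
        params.wthppc_p
        - params.shhppc_p
        + fb.r(36, di.ep_s)
        + fb.r(37, eicc)
        + fb.r(38, ci)
        + di_chance
        + params.di_dnhppc_p * dn.hppc_s
        - di_phchppc
        + di_imhppc
        + scen.at("di_hppcf_tx", t)
    )
    dn_hppc_f = (
        params.wthppc_p
        - params.shhppc_p
        + fb.r(39, dn.ep_s)
        + fb.r(40, eicc)
        + fb.r(41, ci)
        + dn_chance
        + params.dn_dihppc_p * di.hppc_s
        - dn_phchppc
        + scen.at("dn_hppcf_tx", t)
    )

    # --- environmental services block
    di_tnesfp = need_for_provision(
        di.ep_s, params.esep_p, scen.at("di_esb_x", t), di.pop_s
    )
    dn_tnesfp = need_for_provision(
        dn.ep_s, params.esep_p, scen.at("dn_esb_x", t), dn.pop_s
    )
    d_tnesfp = di_tnesfp + dn_tnesfp

    di_esq, _ = effective_service(
        scen.at("di_esq_x", t), 0.0, ci, eicc,
        quality_damage=(lambda x: fb.r(42, x), lambda x: fb.r(43, x)),
        capacity_damage=(lambda x: 0.0, lambda x: 0.0),
    )
    dn_esq, _ = effective_service(
        scen.at("dn_esq_x", t), 0.0, ci, eicc,
        quality_damage=(lambda x: fb.r(44, x), lambda x: fb.r(45, x)),
        capacity_damage=(lambda x: 0.0, lambda x: 0.0),
    )
    d_esc = max(scen.at("d_esc_x", t) - fb.r(46, ci) - fb.r(47, eicc), 0.0)

    es_mode = int(scen.at("d_divesc_x", t))
    di_tpes, dn_tpes = allocate_capacity(
        (di_tnesfp, dn_tnesfp), d_esc, es_mode,
        shares=(scen.at("di_escsha_x", t), scen.at("dn_escsha_x", t)),
    )
    di_pesep = di_tpes * di_esq
    dn_pesep = dn_tpes * dn_esq

    di_ep_f = (
        params.d_ieppc_p * (di.pop_s + movers)
        + params.di_dnep_p * dn.ep_s
        - params.dn_diep_p * di.ep_s
        + fb.rf(21, ci)
        + fb.rf(22, eicc)
        - di_pesep
        - params.d_decrep_p * di.ep_s
        + scen.at("di_ep_tx", t)
    )
    dn_ep_f = (
        params.d_ieppc_p * dn.pop_s
        + params.dn_diep_p * di.ep_s
        - params.di_dnep_p * dn.ep_s
        + fb.rf(23, ci)
        + fb.rf(24, eicc)
        - dn_pesep
        - params.d_decrep_p * dn.ep_s
        + scen.at("dn_ep_tx", t)
    )

    # --- population flows (arrivals join the immigrant group this period)
    di_pop_f = (
        di.pop_s
        * (params.di_netbr_p - fb.r(48, di.hppc_s) + scen.at("di_popgr_tx", t))
        + movers
    )
    dn_pop_f = dn.pop_s * (
        params.dn_netbr_p - fb.r(49, dn.hppc_s) + scen.at("dn_popgr_tx", t)
    )

    return {
        "di_tnhcfp_a": di_tnhcfp, "dn_tnhcfp_a": dn_tnhcfp, "d_tnhcfp_a": d_tnhcfp,
        "di_hcq_a": di_hcq, "dn_hcq_a": dn_hcq, "d_hcc_a": d_hcc,
        "di_phcpc_a": di_phcpc, "dn_phcpc_a": dn_phcpc,
        "di_phchppc_a": di_phchppc, "dn_phchppc_a": dn_phchppc,
        "di_imhppc_a": di_imhppc,
        "di_tnesfp_a": di_tnesfp, "dn_tnesfp_a": dn_tnesfp, "d_tnesfp_a": d_tnesfp,
        "di_esq_a": di_esq, "dn_esq_a": dn_esq, "d_esc_a": d_esc,
        "di_tpes_a": di_tpes, "dn_tpes_a": dn_tpes,
        "di_pesep_a": di_pesep, "dn_pesep_a": dn_pesep,
        "di_hppc_f": di_hppc_f, "dn_hppc_f": dn_hppc_f,
        "di_ep_f": di_ep_f, "dn_ep_f": dn_ep_f,
        "di_pop_f": di_pop_f, "dn_pop_f": dn_pop_f,
    }
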