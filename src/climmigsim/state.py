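"""Model state: stocks, parameters, scenario series, controllers, records.

Naming follows the field convention ``X_Y_Z``: ``X`` is ``o`` (origin), ``d``
(destination site), ``di`` (destination immigrants), ``dn`` (destination
natives), ``od`` (origin-destination pair); ``Z`` is ``s`` for stocks, ``f``
flows, ``a`` auxiliaries, ``p`` parameters, ``x`` exogenous scenario series
and ``tx`` total-non-climate-exogenous (TNE) effect series.

This module also owns the model's universal guard rules: probabilities,
qualities and barriers live in [0, 1]; stocks are non-negative; any
per-capita quantity of an empty population is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .response_functions import FunctionBank

__all__ = [
    "GroupState",
    "ParameterSet",
    "ScenarioSet",
    "Controller",
    "ControllerSet",
    "PeriodRecord",
    "SimulationTrace",
    "ClampEvent",
    "clamp_state",
    "per_capita",
]


# ---------------------------------------------------------------------------
# Guard rules


_CLAMP_KINDS = {
    "risk": (0.0, 1.0),
    "quality": (0.0, 1.0),
    "barrier": (0.0, 1.0),
    "stock": (0.0, None),
}


def clamp_state(raw: float, kind: str) -> float:
    """Clamp a computed value into its admissible range.

    Conflict risks, qualities and barriers are probabilities-like and are
    kept in [0, 1]; stocks are floored at 0 (the extinction mechanism).
    Values already inside their range pass through unchanged.
    """
    if kind not in _CLAMP_KINDS:
        raise ValueError(f"unknown clamp kind {kind!r}")
    if not math.isfinite(raw):
        raise ArithmeticError(f"non-finite value {raw!r} for {kind} clamp")
    lo, hi = _CLAMP_KINDS[kind]
    out = max(raw, lo)
    if hi is not None:
        out = min(out, hi)
    return out


def per_capita(total: float, pop: float) -> float:
    """``total / pop``, with the zero-population rule: 0 when ``pop == 0``."""
    if pop < 0:
        raise ValueError("population must be non-negative")
    if pop == 0.0:
        return 0.0
    return total / pop


@dataclass(frozen=True)
class ClampEvent:
    """A guard rule fired: the raw value was replaced by the clamped one."""

    t: int
    variable: str
    raw: float
    clamped: float


# ---------------------------------------------------------------------------
# Stocks


@dataclass
class GroupState:
    """Stocks of one population group: head count, health problems per
    capita, and the environmental-problem load the group faces."""

    pop_s: float
    hppc_s: float
    ep_s: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"GroupState.{f.name} must be finite and >= 0, got {v}")

    def copy(self) -> "GroupState":
        return replace(self)


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ParameterSet:
    """Scalar parameters plus the bank of response-function parameter sets.

    Rates are per period; thresholds are in the units of the stock they
    gate (health problems per capita for ``hchppc_p``, environmental
    problems for ``esep_p``).
    """

    endtime_p: int = 60
    hchppc_p: float = 48.0      # HP pc threshold above which HC is needed
    esep_p: float = 48.0        # EP threshold above which ES is needed
    wthppc_p: float = 2.0       # natural wear & tear on HP pc, per period
    shhppc_p: float = 0.0       # self-healing of HP pc, per period
    vhppc_p: float = 0.0        # variance of the HP pc chance shock
    o_netbr_p: float = 0.001    # net birth rates, per period
    di_netbr_p: float = 0.001
    dn_netbr_p: float = 0.001
    o_ieppc_p: float = 0.0      # EP created per person-period
    d_ieppc_p: float = 0.0
    o_decrep_p: float = 0.0     # EP decay rates, per period
    d_decrep_p: float = 0.0
    dn_dihppc_p: float = 0.0    # share of immigrant HP pc spilling to natives
    di_dnhppc_p: float = 0.0    # share of native HP pc spilling to immigrants
    dn_diep_p: float = 0.0      # share of immigrant EP spilling to natives
    di_dnep_p: float = 0.0      # share of native EP spilling to immigrants
    functions: FunctionBank = field(default_factory=FunctionBank.zeroed)

    _UNIT_RATES = (
        "vhppc_p", "o_decrep_p", "d_decrep_p",
        "dn_dihppc_p", "di_dnhppc_p", "dn_diep_p", "di_dnep_p",
    )

    def validate(self) -> None:
        if not (isinstance(self.endtime_p, int) and self.endtime_p > 0):
            raise ValueError("endtime_p must be a positive integer")
        for name in ("hchppc_p", "esep_p", "wthppc_p", "shhppc_p",
                     "o_ieppc_p", "d_ieppc_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in self._UNIT_RATES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Scenario series


#: scenario columns and their admissible ranges ("unit" = [0,1],
#: "nonneg" = [0, inf), "mode" = {1, 2}, "free" = unbounded TNE series).
SCENARIO_SPEC: dict[str, str] = {
    # climate impact intensity per site
    "o_eicc_x": "nonneg", "d_eicc_x": "nonneg",
    # barriers
    "o_hcb_x": "unit", "o_esb_x": "unit",
    "di_hcb_x": "unit", "dn_hcb_x": "unit",
    "di_esb_x": "unit", "dn_esb_x": "unit",
    # base qualities
    "o_hcq_x": "unit", "o_esq_x": "unit",
    "di_hcq_x": "unit", "dn_hcq_x": "unit",
    "di_esq_x": "unit", "dn_esq_x": "unit",
    # base capacities
    "o_hcc_x": "nonneg", "o_esc_x": "nonneg",
    "d_hcc_x": "nonneg", "d_esc_x": "nonneg",
    # shortage split modes and fixed shares
    "d_divhcc_x": "mode", "d_divesc_x": "mode",
    "di_hccsha_x": "unit", "dn_hccsha_x": "unit",
    "di_escsha_x": "unit", "dn_escsha_x": "unit",
    # emigrant-to-origin health selection ratio
    "od_nmhppc_x": "nonneg",
    # TNE effect series (unbounded)
    "o_cr_tx": "free", "o_ci_tx": "free", "d_cr_tx": "free", "d_ci_tx": "free",
    "o_nm_tx": "free", "d_nm_tx": "free", "od_nm_tx": "free",
    "o_hppc_tx": "free", "di_hppcf_tx": "free", "dn_hppcf_tx": "free",
    "o_ep_tx": "free", "di_ep_tx": "free", "dn_ep_tx": "free",
    "o_popgr_tx": "free", "di_popgr_tx": "free", "dn_popgr_tx": "free",
}


@dataclass
class ScenarioSet:
    """One exogenous series per scenario variable, indexed t = 0..endtime."""

    series: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def at(self, name: str, t: int) -> float:
        return float(self.series[name][t])

    @classmethod
    def constant(cls, endtime: int, **overrides) -> "ScenarioSet":
        """All-zero series of length ``endtime + 1`` (split modes default to
        1), with per-name overrides given as scalars or full arrays."""
        n = endtime + 1
        series: dict[str, np.ndarray] = {}
        for name, kind in SCENARIO_SPEC.items():
            default = 1.0 if kind == "mode" else 0.0
            series[name] = np.full(n, default, dtype=float)
        for name, value in overrides.items():
            if name not in SCENARIO_SPEC:
                raise KeyError(f"unknown scenario series {name!r}")
            arr = np.asarray(value, dtype=float)
            series[name] = np.full(n, float(arr)) if arr.ndim == 0 else arr.copy()
        return cls(series)

    def validate(self, endtime: int) -> None:
        n = endtime + 1
        missing = set(SCENARIO_SPEC) - set(self.series)
        if missing:
            raise ValueError(f"missing scenario series: {sorted(missing)}")
        for name, arr in self.series.items():
            kind = SCENARIO_SPEC.get(name)
            if kind is None:
                raise ValueError(f"unknown scenario series {name!r}")
            if len(arr) != n:
                raise ValueError(
                    f"scenario series {name!r} has length {len(arr)}, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"scenario series {name!r} contains non-finite values")
            if kind == "unit" and ((arr < 0).any() or (arr > 1).any()):
                raise ValueError(f"scenario series {name!r} must lie in [0, 1]")
            if kind == "nonneg" and (arr < 0).any():
                raise ValueError(f"scenario series {name!r} must be >= 0")
            if kind == "mode" and not np.isin(arr, (1.0, 2.0)).all():
                raise ValueError(f"scenario series {name!r} must contain only 1 or 2")

    def copy(self) -> "ScenarioSet":
        return ScenarioSet({k: v.copy() for k, v in self.series.items()})


# ---------------------------------------------------------------------------
# Controllers


#: variables a controller may override (computed value replaced by a series)
CONTROLLABLE = ("od_nm_a", "od_imhppc_a", "o_ci_a", "d_ci_a")


@dataclass
class Controller:
    """Switch for one computed variable: follow the model equation
    (``compute``) or an exogenous override series (``override``)."""

    mode: str = "compute"
    series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("compute", "override"):
            raise ValueError(f"controller mode must be compute|override, got {self.mode!r}")
        if self.mode == "override" and self.series is None:
            raise ValueError("override controller requires a series")


@dataclass
class ControllerSet:
    controllers: dict[str, Controller] = field(default_factory=dict)

    def overridden(self, name: str) -> bool:
        ctrl = self.controllers.get(name)
        return ctrl is not None and ctrl.mode == "override"

    def value(self, name: str, t: int) -> float:
        return float(self.controllers[name].series[t])

    def validate(self, endtime: int) -> None:
        for name, ctrl in self.controllers.items():
            if name not in CONTROLLABLE:
                raise ValueError(f"variable {name!r} is not controllable")
            if ctrl.mode == "override" and len(ctrl.series) != endtime + 1:
                raise ValueError(
                    f"override series for {name!r} has length {len(ctrl.series)}, "
                    f"expected {endtime + 1}"
                )

    def copy(self) -> "ControllerSet":
        return ControllerSet({
            k: Controller(c.mode, None if c.series is None else c.series.copy())
            for k, c in self.controllers.items()
        })


# ---------------------------------------------------------------------------
# Per-period record and trace


_AUX_FIELDS = (
    "o_cr_a", "o_ci_a", "d_cr_a", "d_ci_a",
    "o_nm_a", "d_nm_a", "od_nm_a", "od_imhppc_a",
    "o_tnhcfp_a", "o_hcq_a", "o_hcc_a", "o_phchppc_a", "o_emhppc_a",
    "o_tnesfp_a", "o_esq_a", "o_esc_a", "o_tpesep_a",
    "di_tnhcfp_a", "dn_tnhcfp_a", "d_tnhcfp_a",
    "di_hcq_a", "dn_hcq_a", "d_hcc_a",
    "di_phcpc_a", "dn_phcpc_a", "di_phchppc_a", "dn_phchppc_a", "di_imhppc_a",
    "di_tnesfp_a", "dn_tnesfp_a", "d_tnesfp_a",
    "di_esq_a", "dn_esq_a", "d_esc_a",
    "di_tpes_a", "dn_tpes_a", "di_pesep_a", "dn_pesep_a",
)
_FLOW_FIELDS = (
    "o_hppc_f", "o_ep_f", "o_pop_f",
    "di_hppc_f", "dn_hppc_f", "di_ep_f", "dn_ep_f", "di_pop_f", "dn_pop_f",
)
_STOCK_FIELDS = (
    "o_pop_s", "o_hppc_s", "o_ep_s",
    "di_pop_s", "di_hppc_s", "di_ep_s",
    "dn_pop_s", "dn_hppc_s", "dn_ep_s",
)

RECORD_FIELDS = ("t",) + _STOCK_FIELDS + _AUX_FIELDS + _FLOW_FIELDS


@dataclass
class PeriodRecord:
    """Everything computed in one period: start-of-period stocks, every
    auxiliary, and every flow.  Stocks recorded at period ``t`` are the
    values the period-``t`` equations read; ``stock(t+1) = stock(t) +
    flow(t)`` up to clamping."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(RECORD_FIELDS) - set(self.values)
        if missing:
            raise ValueError(f"period record missing fields: {sorted(missing)}")

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class SimulationTrace:
    """Ordered period records t = 0..endtime plus the clamp events fired."""

    records: list
    storyline: object
    seed: int
    clamp_events: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def series(self, name: str) -> np.ndarray:
        """The full time series of one recorded variable."""
        return np.array([rec[name] for rec in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([rec.values for rec in self.records])
        return df[list(RECORD_FIELDS)]

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
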