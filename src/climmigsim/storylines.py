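"""Built-in storylines S1-S4, their sensitivity variants, and config I/O.

The four storylines share one baseline host-area setting: perfect service
qualities, no barriers, HC/ES capacities 4200, 100 immigrants and 2000
natives with health problems per capita (HP pc) 48 and environmental
problems (EP) 47, need thresholds 48, death level 50, net birth rate 0.1%
per period, wear & tear 2, and a pro-health exogenous (TNE) HP pc impact of
-1 per group and period.  Conflict, climate impacts and EP couplings are
switched off; arrivals, arrival health and both conflict intensities follow
override series.

S1 has no arrivals and no spillovers.  S2 adds an arrival wave (10, 10, 10,
100, 125, 150, 175, 200 over periods 1-8, arrival HP pc 48 thrice then 55)
and intergroup HP pc spillovers (0, 1% or 2%).  S3 = S2 with 2% spillovers
plus an HC access barrier for immigrants (0.25 or 0.5); S4 = S2 with 2%
spillovers plus reduced HC quality for immigrants (0.75 or 0.5).  A free
"policy" base combines any barrier/quality pair at 2% spillovers for the
capacity-planning analysis.

A storyline serialises to a directory: ``header.yaml`` (parameters,
controllers, initial stocks, lags, seed, function bank) plus
``scenarios.csv`` (one column per exogenous series, one row per period).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SiteLags, Storyline
from .response_functions import FunctionBank, RiseFallFunction, RiseFunction
from .state import (
    CONTROLLABLE,
    SCENARIO_SPEC,
    Controller,
    ControllerSet,
    GroupState,
    ParameterSet,
    ScenarioSet,
)

__all__ = [
    "StorylineVariant",
    "build_storyline",
    "save_storyline",
    "load_storyline",
    "ARRIVALS",
    "ARRIVAL_HPPC",
]

ENDTIME = 60

#: arrival wave: 10/period over periods 1-3, 100 in period 4, rising by
#: 25/period over periods 5-8, zero afterwards (an extreme-weather pulse).
ARRIVALS = (10.0, 10.0, 10.0, 100.0, 125.0, 150.0, 175.0, 200.0)
#: arrival HP pc: as healthy as natives in periods 1-3, sicker afterwards.
ARRIVAL_HPPC = (48.0, 48.0, 48.0, 55.0, 55.0, 55.0, 55.0, 55.0)

BASE_CAPACITY = 4200.0


@dataclass(frozen=True)
class StorylineVariant:
    """One storyline plus its sensitivity knobs.

    ``base`` is S1..S4 or "policy".  ``spillover`` is the symmetric
    intergroup HP pc spillover share; ``barrier``/``quality`` apply to the
    immigrants' health-care access/quality; ``hc_capacity`` overrides the
    site HC capacity (used by the minimum-capacity search).
    """

    base: str = "S1"
    spillover: float = 0.0
    barrier: float = 0.0
    quality: float = 1.0
    hc_capacity: float | None = None

    def __post_init__(self) -> None:
        if self.base not in ("S1", "S2", "S3", "S4", "policy"):
            raise ValueError(f"unknown storyline base {self.base!r}")
        if not 0.0 <= self.barrier <= 1.0:
            raise ValueError("barrier must lie in [0, 1]")
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError("quality must lie in [0, 1]")
        if not 0.0 <= self.spillover <= 1.0:
            raise ValueError("spillover share must lie in [0, 1]")
        if self.base == "S1" and (self.spillover, self.barrier, self.quality) != (0.0, 0.0, 1.0):
            raise ValueError("S1 has no spillovers, no barriers, perfect quality")
        if self.base == "S2" and (self.barrier, self.quality) != (0.0, 1.0):
            raise ValueError("S2 varies the spillover share only")
        if self.base == "S3" and self.quality != 1.0:
            raise ValueError("S3 varies the immigrant HC barrier only")
        if self.base == "S4" and self.barrier != 0.0:
            raise ValueError("S4 varies the immigrant HC quality only")
        if self.hc_capacity is not None and self.hc_capacity < 0:
            raise ValueError("hc_capacity must be >= 0")

    @property
    def name(self) -> str:
        bits = [self.base]
        if self.spillover:
            bits.append(f"spill={self.spillover:g}")
        if self.barrier:
            bits.append(f"b={self.barrier:g}")
        if self.quality != 1.0:
            bits.append(f"q={self.quality:g}")
        if self.hc_capacity is not None:
            bits.append(f"hcc={self.hc_capacity:g}")
        return "[" + ", ".join(bits) + "]"


def _variant(spec: StorylineVariant | str, **kwargs) -> StorylineVariant:
    if isinstance(spec, StorylineVariant):
        return spec
    defaults = {
        "S1": {},
        "S2": {"spillover": 0.01},
        "S3": {"spillover": 0.02, "barrier": 0.25},
        "S4": {"spillover": 0.02, "quality": 0.75},
        "policy": {"spillover": 0.02},
    }[spec]
    defaults.update(kwargs)
    return StorylineVariant(base=spec, **defaults)


def build_storyline(spec: StorylineVariant | str = "S1", *, seed: int = 0, **kwargs) -> Storyline:
    """Materialise a storyline from its variant description.

    ``spec`` may be a :class:`StorylineVariant` or a base name ("S1".."S4",
    "policy"); keyword arguments adjust the variant knobs when a name is
    given (e.g. ``build_storyline("S3", barrier=0.5)``).
    """
    variant = _variant(spec, **kwargs)
    params = ParameterSet(
        endtime_p=ENDTIME,
        dn_dihppc_p=variant.spillover,
        di_dnhppc_p=variant.spillover,
        functions=FunctionBank.zeroed(),
    )

    n = ENDTIME + 1
    arrivals = np.zeros(n)
    arrival_hppc = np.zeros(n)
    if variant.base != "S1":
        # the wave said to arrive "in period k" is part of the period-(k-1)
        # flow, so it is already counted in the stocks reported at period k
        arrivals[0 : len(ARRIVALS)] = ARRIVALS
        arrival_hppc[0 : len(ARRIVAL_HPPC)] = ARRIVAL_HPPC

    hc_capacity = BASE_CAPACITY if variant.hc_capacity is None else variant.hc_capacity
    scenarios = ScenarioSet.constant(
        ENDTIME,
        # qualities 1 everywhere except the immigrants' HC quality knob
        o_hcq_x=1.0, o_esq_x=1.0,
        dn_hcq_x=1.0, dn_esq_x=1.0, di_esq_x=1.0,
        di_hcq_x=variant.quality,
        di_hcb_x=variant.barrier,
        o_hcc_x=BASE_CAPACITY, o_esc_x=BASE_CAPACITY,
        d_hcc_x=hc_capacity, d_esc_x=BASE_CAPACITY,
        od_nmhppc_x=1.0,
        # pro-health TNE impact on every group's HP pc flow
        o_hppc_tx=-1.0, di_hppcf_tx=-1.0, dn_hppcf_tx=-1.0,
        # unused mode-2 fixed shares, kept valid
        di_hccsha_x=0.5, dn_hccsha_x=0.5, di_escsha_x=0.5, dn_escsha_x=0.5,
    )

    controllers = ControllerSet({
        "od_nm_a": Controller("override", arrivals),
        "od_imhppc_a": Controller("override", arrival_hppc),
        "o_ci_a": Controller("override", np.zeros(n)),
        "d_ci_a": Controller("override", np.zeros(n)),
    })

    storyline = Storyline(
        name=variant.name,
        params=params,
        scenarios=scenarios,
        controllers=controllers,
        # the origin site is unreported downstream; it mirrors the natives
        origin=GroupState(pop_s=2000.0, hppc_s=48.0, ep_s=47.0),
        immigrants=GroupState(pop_s=100.0, hppc_s=48.0, ep_s=47.0),
        natives=GroupState(pop_s=2000.0, hppc_s=48.0, ep_s=47.0),
        lags=SiteLags(),
        seed=seed,
    )
    storyline.validate()
    return storyline


# ---------------------------------------------------------------------------
# Serialisation


def _fn_to_dict(fn) -> dict:
    return asdict(fn)


def save_storyline(storyline: Storyline, path: str | Path) -> None:
    """Write a storyline as ``header.yaml`` + ``scenarios.csv`` in ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    params = {
        f.name: getattr(storyline.params, f.name)
        for f in fields(storyline.params)
        if f.name != "functions"
    }
    fb = storyline.params.functions
    header = {
        "name": storyline.name,
        "seed": storyline.seed,
        "parameters": params,
        "functions": {
            "rise": [_fn_to_dict(fn) for fn in fb.rise],
            "risefall": [_fn_to_dict(fn) for fn in fb.risefall],
        },
        "initial_stocks": {
            "origin": asdict(storyline.origin),
            "immigrants": asdict(storyline.immigrants),
            "natives": asdict(storyline.natives),
        },
        "initial_lags": asdict(storyline.lags),
        "controllers": {
            name: ctrl.mode for name, ctrl in storyline.controllers.controllers.items()
        },
    }
    with open(path / "header.yaml", "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=False)

    table = {name: storyline.scenarios[name] for name in SCENARIO_SPEC}
    for name, ctrl in storyline.controllers.controllers.items():
        if ctrl.series is not None:
            table[f"ctrl__{name}"] = ctrl.series
    pd.DataFrame(table).to_csv(path / "scenarios.csv", index=False)


def load_storyline(path: str | Path) -> Storyline:
    """Read back a storyline directory; validates and raises on missing
    series, length mismatches, or out-of-range bounded values."""
    path = Path(path)
    with open(path / "header.yaml") as fh:
        header = yaml.safe_load(fh)

    fb = FunctionBank(
        rise=tuple(RiseFunction(**d) for d in header["functions"]["rise"]),
        risefall=tuple(RiseFallFunction(**d) for d in header["functions"]["risefall"]),
    )
    params = ParameterSet(functions=fb, **header["parameters"])

    df = pd.read_csv(path / "scenarios.csv")
    series = {
        name: df[name].to_numpy(dtype=float) for name in df.columns
        if not name.startswith("ctrl__")
    }
    controllers: dict[str, Controller] = {}
    for name, mode in header["controllers"].items():
        col = f"ctrl__{name}"
        ctrl_series = df[col].to_numpy(dtype=float) if col in df.columns else None
        controllers[name] = Controller(mode, ctrl_series)

    stocks = header["initial_stocks"]
    storyline = Storyline(
        name=header["name"],
        params=params,
        scenarios=ScenarioSet(series),
        controllers=ControllerSet(controllers),
        origin=GroupState(**stocks["origin"]),
        immigrants=GroupState(**stocks["immigrants"]),
        natives=GroupState(**stocks["natives"]),
        lags=SiteLags(**header["initial_lags"]),
        seed=header["seed"],
    )
    storyline.validate()
    return storyline
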