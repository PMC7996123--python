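"""Result-generation procedures built on top of the simulator.

Covers steady-state detection on simulated series, the minimum sufficient
health-care capacity (MSHC) search, the policy comparison table, parameter
sensitivity sweeps, an analytic steady-state cross-check, and the
sum-of-squared-errors fit score used when matching a simulated series to an
observed one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Storyline, run
from .state import SimulationTrace
from .storylines import StorylineVariant, build_storyline

__all__ = [
    "detect_steady",
    "first_equalization",
    "MshcResult",
    "find_mshc",
    "policy_table",
    "parameter_sweep",
    "steady_hp_oracle",
    "NoSteadyStateError",
    "fit_score",
]


def detect_steady(
    series,
    tolerance: float = 0.005,
    window: int = 3,
    decimals: int = 2,
) -> tuple[int, float] | None:
    """First time a series stops changing, on rounded values.

    The series is rounded to ``decimals`` places; steadiness is declared at
    the first index ``t`` whose next ``window`` successive differences all
    stay within ``tolerance``.  Returns ``(t, rounded value at t)``, or
    ``None`` if the series never settles inside the horizon.
    """
    arr = np.round(np.asarray(series, dtype=float), decimals)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must be finite")
    diffs = np.abs(np.diff(arr))
    for t in range(len(arr) - window):
        if np.all(diffs[t : t + window] <= tolerance):
            return t, float(arr[t])
    return None


def first_equalization(a, b, decimals: int = 2) -> int | None:
    """First period at which two series agree again (at ``decimals``
    rounding) after having diverged; the leading stretch where they have not
    yet diverged does not count."""
    ra = np.round(np.asarray(a, dtype=float), decimals)
    rb = np.round(np.asarray(b, dtype=float), decimals)
    if len(ra) != len(rb):
        raise ValueError("series lengths differ")
    equal = ra == rb
    unequal_idx = np.flatnonzero(~equal)
    if len(unequal_idx) == 0:
        return 0
    after = np.flatnonzero(equal & (np.arange(len(equal)) > unequal_idx[0]))
    return int(after[0]) if len(after) else None


# ---------------------------------------------------------------------------
# Minimum sufficient HC capacity


@dataclass(frozen=True)
class MshcResult:
    """Outcome of the minimum-capacity search for one (barrier, quality)
    policy: the capacity itself plus the summary of the run at that
    capacity."""

    barrier: float
    quality: float
    mshc: float
    immigrant_pop_end: float
    native_pop_end: float
    immigrant_steady_hp: float | None
    native_steady_hp: float | None
    steady_time: int | None


def _policy_storyline(barrier: float, quality: float, capacity: float | None,
                      spillover: float, seed: int) -> Storyline:
    variant = StorylineVariant(
        base="policy", spillover=spillover, barrier=barrier, quality=quality,
        hc_capacity=capacity,
    )
    return build_storyline(variant, seed=seed)


def _hc_sufficient(trace: SimulationTrace) -> bool:
    """True when the total HC need for provision never tops the effective
    HC capacity over periods 1..endtime."""
    need = trace.series("d_tnhcfp_a")[1:]
    cap = trace.series("d_hcc_a")[1:]
    return bool(np.all(need <= cap))


def find_mshc(
    barrier: float,
    quality: float,
    spillover: float = 0.02,
    upper: int = 20_000,
    seed: int = 0,
    max_upper: int = 1_280_000,
    base: Storyline | None = None,
) -> MshcResult:
    """Smallest integer HC capacity keeping provision sufficient throughout.

    Feasibility of a capacity ``c`` means the total need for provision never
    exceeds ``c`` in periods 1..endtime of the run *at that capacity*
    (capacity feeds back on need through health).  The search is an integer
    bisection between an infeasible lower and a feasible upper bound; the
    upper bound doubles until feasible.  By default the run is the policy
    storyline for ``(barrier, quality)`` at 2% spillovers; pass ``base`` to
    search over any other storyline (its HC capacity series is replaced).
    """

    def at_capacity(c: float) -> Storyline:
        if base is None:
            return _policy_storyline(barrier, quality, c, spillover, seed)
        sl = copy.deepcopy(base)
        sl.scenarios.series["d_hcc_x"] = np.full_like(sl.scenarios["d_hcc_x"], c)
        return sl

    def feasible(c: int) -> bool:
        return _hc_sufficient(run(at_capacity(float(c))))

    while not feasible(upper):
        upper *= 2
        if upper > max_upper:
            raise RuntimeError(
                f"no sufficient HC capacity found below {max_upper} for "
                f"policy (b={barrier}, q={quality})"
            )
    lo, hi = 0, upper
    if feasible(lo):
        hi = lo
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if feasible(mid):
                hi = mid
            else:
                lo = mid
    mshc = hi

    trace = run(at_capacity(float(mshc)))
    di_steady = detect_steady(trace.series("di_hppc_s"))
    dn_steady = detect_steady(trace.series("dn_hppc_s"))
    times = [s[0] for s in (di_steady, dn_steady) if s is not None]
    return MshcResult(
        barrier=barrier,
        quality=quality,
        mshc=float(mshc),
        immigrant_pop_end=float(trace.series("di_pop_s")[-1]),
        native_pop_end=float(trace.series("dn_pop_s")[-1]),
        immigrant_steady_hp=None if di_steady is None else di_steady[1],
        native_steady_hp=None if dn_steady is None else dn_steady[1],
        steady_time=max(times) if len(times) == 2 else None,
    )


#: the five (barrier, quality) policies of the capacity-planning comparison
POLICIES = ((0.25, 0.75), (0.25, 0.5), (0.5, 0.75), (0.5, 0.5), (0.0, 1.0))


def policy_table(
    policies=POLICIES, spillover: float = 0.02, seed: int = 0
) -> pd.DataFrame:
    """Minimum sufficient HC capacity and run summary per policy."""
    rows = []
    for barrier, quality in policies:
        res = find_mshc(barrier, quality, spillover=spillover, seed=seed)
        rows.append({
            "Immigrant HC barriers": res.barrier,
            "Immigrant HC quality": res.quality,
            "HC capacity": res.mshc,
            "Immigrant pop t 60": res.immigrant_pop_end,
            "Native pop t 60": res.native_pop_end,
            "Immigrant steady HP": res.immigrant_steady_hp,
            "Native steady HP": res.native_steady_hp,
            "Time of steady HP": res.steady_time,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity sweeps


def _assign(storyline: Storyline, path: str, value) -> None:
    if path == "params.hp_spillover":
        # convenience alias: the symmetric intergroup HP pc spillover share
        storyline.params.dn_dihppc_p = value
        storyline.params.di_dnhppc_p = value
        return
    parts = path.split(".")
    obj = storyline
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise AttributeError(f"unknown parameter path {path!r}")
        obj = getattr(obj, part)
    leaf = parts[-1]
    from .state import ScenarioSet  # local import to avoid cycle noise

    if isinstance(obj, ScenarioSet):
        if leaf not in obj.series:
            raise KeyError(f"unknown scenario series in path {path!r}")
        current = obj.series[leaf]
        if np.ndim(value) == 0:
            obj.series[leaf] = np.full_like(current, float(value))
        else:
            obj.series[leaf] = np.asarray(value, dtype=float)
    else:
        if not hasattr(obj, leaf):
            raise AttributeError(f"unknown parameter path {path!r}")
        setattr(obj, leaf, value)


def parameter_sweep(base: Storyline, path: str, values) -> dict[float, SimulationTrace]:
    """Run independent copies of ``base`` with one input swept over
    ``values``; all runs share the base storyline's seed.

    ``path`` is a dotted attribute path, e.g. ``params.dn_dihppc_p`` or
    ``scenarios.di_hcb_x`` (a scalar assigned to a scenario series fills the
    whole series).
    """
    traces: dict[float, SimulationTrace] = {}
    for value in values:
        sl = copy.deepcopy(base)
        _assign(sl, path, value)
        traces[value] = run(sl)
    return traces


# ---------------------------------------------------------------------------
# Analytic steady state


class NoSteadyStateError(ValueError):
    """The policy admits no finite steady health level (no healing path)."""


def steady_hp_oracle(
    barrier: float,
    quality: float,
    spillover: float,
    wear: float = 2.0,
    self_heal: float = 0.0,
    tne: float = -1.0,
    threshold: float = 48.0,
) -> tuple[float, float]:
    """Closed-form steady health levels under ample capacity.

    At a steady state with sufficient capacity and both groups above the
    need threshold, provision balances the constant pressure plus the
    spillover from the other group::

        q (1 - b) (h_i - threshold) = (wear - self_heal + tne) + s * h_n
                  (h_n - threshold) = (wear - self_heal + tne) + s * h_i

    Solves the 2x2 linear system for (immigrant, native) steady HP pc.
    Raises :class:`NoSteadyStateError` when ``q (1 - b) = 0`` (provision
    cannot heal the immigrants, so their level grows without bound).
    """
    g = quality * (1.0 - barrier)
    if g == 0.0:
        raise NoSteadyStateError(
            f"q(1-b) = 0 for (b={barrier}, q={quality}): no finite steady state"
        )
    net = wear - self_heal + tne
    a = np.array([[g, -spillover], [-spillover, 1.0]])
    rhs = np.array([net + threshold * g, net + threshold])
    if abs(np.linalg.det(a)) < 1e-12:
        raise NoSteadyStateError("degenerate spillover coupling")
    h_i, h_n = np.linalg.solve(a, rhs)
    return float(h_i), float(h_n)


# ---------------------------------------------------------------------------
# Fit


def fit_score(simulated, observed) -> float:
    """Sum of squared per-period differences between a simulated and an
    observed series (the calibration objective)."""
    y = np.asarray(simulated, dtype=float)
    yd = np.asarray(observed, dtype=float)
    if y.shape != yd.shape:
        raise ValueError(f"series lengths differ: {y.shape} vs {yd.shape}")
    return float(np.sum((y - yd) ** 2))
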