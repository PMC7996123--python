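"""Threshold response functions and seeded random draws.

The simulator expresses every nonlinear coupling through two generic shapes:

* a *rise* function ``R(x)`` that is zero up to a threshold and non-decreasing
  beyond it (used e.g. for death rates and damage terms), and
* a *rise-fall* function ``RF(x)`` that is zero up to ``p1``, peaks at ``fm``
  when ``x = pm``, returns to zero at ``p2`` and turns negative beyond it
  (used e.g. for conflict effects that first mobilise and then exhaust).

Both families return exactly 0 whenever all their parameters are 0, which is
how a storyline switches a coupling off.  Stochastic terms (conflict-risk
thresholds, health chance shocks) come from named, independently seeded
substreams so that enabling one source of randomness never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RiseFunction",
    "RiseFallFunction",
    "RandomStream",
    "FunctionBank",
    "SUBSTREAMS",
]


@dataclass(frozen=True)
class RiseFunction:
    """Non-decreasing threshold response, zero on ``[0, threshold]``.

    Two concrete forms are supported:

    ``linear``
        ``value(x) = slope * max(x - threshold, 0)``.
    ``exponential_death``
        ``value(x) = scale * (exp(max(x - offset, 0)) - 1)`` — the per-period
        excess death rate once health problems per capita cross the death
        level ``offset``.
    """

    form: str = "linear"
    threshold: float = 0.0
    slope: float = 0.0
    scale: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "exponential_death"):
            raise ValueError(f"unknown rise-function form {self.form!r}")
        if self.threshold < 0 or self.slope < 0 or self.scale < 0:
            raise ValueError("rise-function parameters must be non-negative")

    def __call__(self, x: float) -> float:
        if x < 0:
            raise ValueError(f"rise function evaluated at negative input x={x}")
        if self.form == "linear":
            return self.slope * max(x - self.threshold, 0.0)
        return self.scale * (math.exp(max(x - self.offset, 0.0)) - 1.0)

    @property
    def is_zero(self) -> bool:
        """True when the function is identically zero."""
        if self.form == "linear":
            return self.slope == 0.0
        return self.scale == 0.0


@dataclass(frozen=True)
class RiseFallFunction:
    """Piecewise-linear hump: 0 on ``[0, p1]``, ``fm`` at ``pm``, 0 at ``p2``,
    and declining with slope ``-fall_slope`` beyond ``p2``."""

    p1: float = 0.0
    pm: float = 0.0
    p2: float = 0.0
    fm: float = 0.0
    fall_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= self.pm <= self.p2):
            raise ValueError(
                f"rise-fall knots must satisfy 0 <= p1 <= pm <= p2, "
                f"got ({self.p1}, {self.pm}, {self.p2})"
            )
        if self.fm < 0 or self.fall_slope < 0:
            raise ValueError("fm and fall_slope must be non-negative")

    def __call__(self, x: float) -> float:
        if x < 0:
            raise ValueError(f"rise-fall function evaluated at negative input x={x}")
        if x <= self.p1:
            return 0.0
        if x <= self.pm:
            # pm > p1 here since x > p1 and x <= pm
            return self.fm * (x - self.p1) / (self.pm - self.p1)
        if x <= self.p2:
            if self.p2 == self.pm:
                return self.fm if x == self.pm else 0.0
            return self.fm * (self.p2 - x) / (self.p2 - self.pm)
        return -self.fall_slope * (x - self.p2)

    @property
    def is_zero(self) -> bool:
        return self.fm == 0.0 and self.fall_slope == 0.0


#: Named substreams, in spawn order (order is part of the seeding contract).
SUBSTREAMS = (
    "origin_conflict",
    "destination_conflict",
    "origin_hp_chance",
    "immigrant_hp_chance",
    "native_hp_chance",
)


class RandomStream:
    """Seeded random draws split into independent named substreams.

    Each substream owns its own ``numpy`` generator spawned from one root
    seed, so the sequence a substream produces depends only on the seed and
    on how many draws *that* substream made — enabling, say, conflict
    randomness without disturbing the health-chance shocks.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(SUBSTREAMS))
        self._gens = {
            name: np.random.default_rng(child)
            for name, child in zip(SUBSTREAMS, children)
        }

    def _gen(self, substream: str) -> np.random.Generator:
        try:
            return self._gens[substream]
        except KeyError:
            raise KeyError(f"unknown substream {substream!r}") from None

    def uniform(self, substream: str) -> float:
        """One draw from Uniform(0, 1)."""
        return float(self._gen(substream).uniform(0.0, 1.0))

    def normal(self, substream: str, variance: float) -> float:
        """One draw from Normal(0, variance); exactly 0 when variance is 0.

        The degenerate case consumes no randomness, so deterministic runs
        are bit-identical across seeds.
        """
        if variance < 0:
            raise ValueError("variance must be non-negative")
        if variance == 0.0:
            return 0.0
        return float(self._gen(substream).normal(0.0, math.sqrt(variance)))

    def draw(self, substream: str, distribution: str, variance: float = 0.0) -> float:
        """Generic draw dispatcher: ``uniform`` on [0,1] or ``normal`` with
        mean 0 and the given variance."""
        if distribution == "uniform":
            return self.uniform(substream)
        if distribution == "normal":
            return self.normal(substream, variance)
        raise ValueError(f"unknown distribution {distribution!r}")


_DEATH_FN = RiseFunction(form="exponential_death", scale=0.001, offset=50.0)

#: 1-based indices of the rise functions acting as per-period death rates
#: (origin, immigrant, native population flows).
DEATH_RATE_INDICES = (29, 48, 49)

N_RISE = 49
N_RISEFALL = 24


@dataclass(frozen=True)
class FunctionBank:
    """Parameter sets of the serially numbered rise (R1..R49) and rise-fall
    (RF1..RF24) functions; addressable by 1-based index."""

    rise: tuple = field(default_factory=tuple)
    risefall: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.rise) != N_RISE:
            raise ValueError(f"expected {N_RISE} rise functions, got {len(self.rise)}")
        if len(self.risefall) != N_RISEFALL:
            raise ValueError(
                f"expected {N_RISEFALL} rise-fall functions, got {len(self.risefall)}"
            )

    def r(self, index: int, x: float) -> float:
        """Evaluate R_index(x), index in 1..49."""
        return self.rise[index - 1](x)

    def rf(self, index: int, x: float) -> float:
        """Evaluate RF_index(x), index in 1..24."""
        return self.risefall[index - 1](x)

    @classmethod
    def zeroed(cls, death_fn: RiseFunction = _DEATH_FN) -> "FunctionBank":
        """All couplings off except the death-rate functions R29/R48/R49.

        This is the configuration every storyline uses: conflict, climate
        and environmental couplings are disabled, while populations still die
        at rate ``0.001 (e^{max(hppc - 50, 0)} - 1)`` once health problems
        per capita cross the death level.
        """
        rise = [RiseFunction() for _ in range(N_RISE)]
        for idx in DEATH_RATE_INDICES:
            rise[idx - 1] = death_fn
        return cls(rise=tuple(rise), risefall=tuple(RiseFallFunction() for _ in range(N_RISEFALL)))

    @classmethod
    def all_zero(cls) -> "FunctionBank":
        """Every function identically zero (death rates included)."""
        return cls(
            rise=tuple(RiseFunction() for _ in range(N_RISE)),
            risefall=tuple(RiseFallFunction() for _ in range(N_RISEFALL)),
        )
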