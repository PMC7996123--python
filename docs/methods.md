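# Methods

## Model structure

The simulator is an explicit unit-step difference system. Per period it
evaluates auxiliaries and flows from start-of-period stocks in a fixed
order — conflict, migration, origin health-care (HC) block, origin
environmental-service (ES) block, origin population flow, destination HC
block, destination HP flows, destination ES block, destination EP and
population flows — and then updates all nine stocks simultaneously. No
stock is mutated mid-period, so the order of evaluation inside a period is
purely notational. There is no continuous-time integration and no adaptive
stepping: the period is the model's native unit.

Conventions the whole model relies on:

* **Clamping.** Conflict risks, qualities and barriers are kept in [0, 1];
  stocks are floored at 0. Clamps are recorded as structured events in the
  trace, never applied silently — extinction of a group *is* the event
  "population stock clamped to 0".
* **Zero-population rule.** Any per-capita quantity of an empty group is 0.
  This extends to the per-capita health stock itself: when a group's
  population hits 0 its HP pc stock is reset to 0. Without this, the
  orphaned per-capita stock would keep integrating wear & tear and keep
  spilling health problems into the surviving group; with it, the natives'
  health relaxes back to its no-neighbour equilibrium after an immigrant
  extinction, which is the behaviour the storyline results show.
* **Arrival timing.** Migration completes within a period: movers counted
  at step t appear in that same step's mixing term, EP creation, and both
  population flows, and are therefore part of the stocks reported at t+1.
  Consequently the built-in arrival wave occupies flow steps 0..7, so that
  "the arrivals of period k" are inside the period-k stocks.

## Response functions

Two families carry every nonlinear coupling. Rise functions are zero up to
a threshold and non-decreasing beyond; the default concrete form is linear,
`s·max(x − p, 0)`, the simplest shape with the required properties.
Rise-fall functions are piecewise linear through (p1, 0), (pm, fm), (p2, 0)
and continue with slope −fall_slope. The built-in storylines zero all of
them except the three death-rate functions, which use the exponential form

    death(hppc) = 0.001 · (e^max(hppc − 50, 0) − 1)   per period,

zero at or below the death level 50 and growing fast enough above it that a
group under a sustained health crisis can overshoot into the stock floor
(extinction). Because the storylines zero every other R/RF, the choice of
linear defaults cannot affect any reported result.

## Parameters and baseline inputs

All baseline values are part of the storyline definitions (units in
brackets): need thresholds 48 [HP pc] and 48 [EP] with death level 50
[HP pc]; wear & tear 2 and self-healing 0 [HP pc/period]; chance variance 0;
net birth rates 0.001 [1/period]; HC/ES capacities 4200 [service units];
qualities 1 and barriers 0 unless a storyline varies them; EP creation and
decay 0; an exogenous pro-health impact of −1 [HP pc/period] per group; 100
immigrants and 2000 natives with HP pc 48 and EP 47 at t = 0; horizon 60
periods. The sensitivity knobs are the intergroup HP spillover share
s ∈ {0, 0.01, 0.02}, the immigrants' HC barrier b ∈ {0.25, 0.5} (S3) and HC
quality q ∈ {0.75, 0.5} (S4); the policy analysis combines b and q freely at
s = 0.02.

The origin site's own inputs are deliberately inert: arrivals and arrival
health follow override series in all storylines, so the origin's internal
dynamics never reach the destination. Its fixtures mirror the native hosts
(population 2000, HP pc 48, EP 47, perfect services).

Controllers make a normally computed variable follow an exogenous series
instead; the storylines override four of them (mover count, arrival health,
and both conflict intensities, all zero except the arrival wave). An
overridden conflict intensity consumes no random draw, and a zero chance
variance returns exactly 0 without drawing, so the storyline runs are
bit-identical across seeds. When stochastic terms are enabled, draws come
from five named substreams seeded independently from one root seed, so
enabling one noise source never perturbs another.

## Analysis procedures

**Steady-state detection** rounds a series to 2 decimals and reports the
first index whose next 3 successive differences stay within 0.005 —
i.e. the first time the displayed value stops moving for three periods —
together with the rounded value there. On a slowly settling series this
fires a few periods before the asymptote is reached to full precision;
absence of a steady state is a valid result, not an error.

**Minimum sufficient HC capacity (MSHC).** Capacity feeds back on need
(shortage raises health problems, which raises need), so sufficiency of a
capacity c is defined on the run *at* c: total need for provision ≤ c in
every period 1..60. The search is an integer bisection between an
infeasible lower and a feasible upper bound (the upper bound doubles until
feasible), returning the smallest sufficient integer. Minimality is
testable directly: one unit below the result, some period is short.

**Analytic steady state.** Under ample capacity, with both groups above the
need threshold, the per-capita balances are linear:

    q(1 − b)(h_i − 48) = 1 + s·h_n
            (h_n − 48) = 1 + s·h_i

The 2×2 solve provides an independent cross-check of the simulated steady
levels (agreement within 0.1 HP pc units in the tests). With q(1 − b) = 0
provision cannot heal the immigrants and no finite steady state exists,
which is signalled rather than returned.

**Fit score.** For matching a simulated to an observed series the package
exposes the plain sum of squared per-period differences. No calibration to
real-world data is performed here: all inputs are synthetic storylines.

## What the storylines do and do not show

The storyline generator *is* the study design: two sites, one immigrant
cohort, composite one-dimensional health and environmental stocks, no age
or sex structure, no inter-site conflict, no feedback from destination to
origin other than the mover count, and a deterministic core (variance 0,
conflict off). Passing tests therefore demonstrate internal consistency and
exact reproducibility of the scenario results — not real-world predictive
accuracy, which would require case-specific inputs, disaggregated health
types, and calibration against observed series.

## Numerical choices and edge cases

* Populations are carried as continuous quantities; integers appear only in
  display/comparison rounding. A dying group decays multiplicatively and
  reaches exact 0 only by overshoot (flow more negative than the stock);
  at near-sufficient capacity a group can instead dwindle to a vanishing
  but positive size.
* Shortage allocation mode 2 (fixed shares) is capped at each group's need
  so provision never over-serves; the built-in storylines use mode 1
  (need-share allocation), under which summed provision equals
  min(total need, capacity) exactly, every period.
* Equality ties go to sufficiency: need equal to capacity is not a
  shortage, and a conflict risk equal to the drawn threshold yields no
  conflict.
* Degenerate rise-fall knots (p1 = pm with fm > 0) cannot satisfy both
  boundary constraints; the implementation keeps the left limit (0 at p1)
  and the tests exclude the degenerate corner from shape properties.
* Non-finite values anywhere in a period abort the run with the period and
  variable named.

## Known limitations

Two reported reference numbers are not reproduced by the equations as
published, and are documented rather than forced: the S2 (1% spillover)
health-equalization period computes to 14 (reference 15; the two-decimal
stocks first agree at 50.46/50.46 with a raw gap of 2.1·10⁻³), and the S3
(b = 0.25) immigrant population trough computes to 22.7 → 23, reached at
t = 21 (reference 21, with end value 23 — a pair that cannot jointly hold
here, since post-trough net growth is ≈5·10⁻⁵ per period and the computed
end value matches the reference exactly). Steady-state times printed for
the capacity-policy comparison depend on the detection rule; the rule above
is stated explicitly so its outputs are reproducible.
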