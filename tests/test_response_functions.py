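"""Rise / rise-fall response shapes and the seeded random substreams."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climmigsim import FunctionBank, RandomStream, RiseFallFunction, RiseFunction

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


class TestRiseFunction:
    def test_zero_parameters_give_zero_everywhere(self):
        fn = RiseFunction()
        assert fn(0.0) == 0.0
        assert fn(5.0) == 0.0

    @pytest.mark.parametrize(
        "x, expected",
        [
            (50.0, 0.0),                              # at the death level
            (53.0, 0.001 * (math.e**3 - 1)),          # ~0.019086
            (40.0, 0.0),                              # below the level
        ],
    )
    def test_exponential_death_form(self, x, expected):
        fn = RiseFunction(form="exponential_death", scale=0.001, offset=50.0)
        assert fn(x) == pytest.approx(expected, abs=1e-12)

    def test_linear_form(self):
        fn = RiseFunction(threshold=2.0, slope=0.5)
        assert fn(2.0) == 0.0
        assert fn(4.0) == pytest.approx(1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            RiseFunction(slope=1.0)(-0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RiseFunction(threshold=-1.0)
        with pytest.raises(ValueError):
            RiseFunction(form="cubic")

    @given(
        threshold=st.floats(0, 10),
        slope=st.floats(0, 5),
        scale=st.floats(0, 1),
        offset=st.floats(0, 10),
        form=st.sampled_from(["linear", "exponential_death"]),
    )
    def test_zero_below_threshold_and_nondecreasing(self, threshold, slope, scale, offset, form):
        fn = RiseFunction(form=form, threshold=threshold, slope=slope, scale=scale, offset=offset)
        grid = np.linspace(0, 20, 101)
        vals = [fn(x) for x in grid]
        cut = threshold if form == "linear" else offset
        assert all(v == 0.0 for x, v in zip(grid, vals) if x <= cut)
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRiseFallFunction:
    def test_zero_parameters_give_zero(self):
        fn = RiseFallFunction()
        for x in (0.0, 0.5, 3.0, 100.0):
            assert fn(x) == 0.0

    def test_knot_values(self):
        fn = RiseFallFunction(p1=1.0, pm=3.0, p2=6.0, fm=2.0, fall_slope=0.5)
        assert fn(1.0) == 0.0
        assert fn(3.0) == 2.0          # peak value fm at pm
        assert fn(6.0) == 0.0          # back to zero at p2
        assert fn(8.0) == -1.0         # negative beyond p2

    def test_sign_structure(self):
        fn = RiseFallFunction(p1=1.0, pm=2.0, p2=4.0, fm=1.0, fall_slope=1.0)
        eps = 1e-6
        assert fn(0.5) == 0.0
        assert fn(1.5) > 0.0
        assert fn(4.0) == 0.0
        assert fn(4.0 + eps) < 0.0

    def test_invalid_knot_order_rejected(self):
        with pytest.raises(ValueError):
            RiseFallFunction(p1=3.0, pm=2.0, p2=4.0, fm=1.0)

    @given(
        p1=st.floats(0, 3), rise=st.floats(0.01, 3), fall=st.floats(0, 3),
        fm=st.floats(0, 5), fall_slope=st.floats(0, 2),
    )
    def test_monotone_on_each_side_of_peak(self, p1, rise, fall, fm, fall_slope):
        # rise > 0: with p1 == pm and fm > 0 no function can be both 0 on
        # [0, p1] and fm at pm, so the degenerate knot is excluded
        pm, p2 = p1 + rise, p1 + rise + fall
        fn = RiseFallFunction(p1=p1, pm=pm, p2=p2, fm=fm, fall_slope=fall_slope)
        up = np.linspace(0, pm, 50) if pm > 0 else [0.0]
        down = np.linspace(pm, pm + 10, 50)
        up_vals = [fn(x) for x in up]
        down_vals = [fn(x) for x in down]
        assert all(b >= a - 1e-9 for a, b in zip(up_vals, up_vals[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(down_vals, down_vals[1:]))


class TestRandomStream:
    def test_same_seed_identical_sequences(self):
        a = RandomStream(42)
        b = RandomStream(42)
        assert [a.uniform("origin_conflict") for _ in range(10)] == [
            b.uniform("origin_conflict") for _ in range(10)
        ]

    def test_substreams_are_independent(self):
        a = RandomStream(7)
        b = RandomStream(7)
        # consuming another substream must not shift this one
        for _ in range(5):
            b.uniform("destination_conflict")
        assert a.uniform("origin_conflict") == b.uniform("origin_conflict")

    def test_zero_variance_normal_is_exactly_zero(self):
        s = RandomStream(1)
        assert s.normal("native_hp_chance", 0.0) == 0.0

    def test_uniform_law_of_large_numbers(self):
        s = RandomStream(3)
        draws = [s.uniform("origin_conflict") for _ in range(100_000)]
        assert 0.49 <= np.mean(draws) <= 0.51
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_normal_variance_matches(self):
        s = RandomStream(5)
        draws = [s.normal("native_hp_chance", 4.0) for _ in range(50_000)]
        assert np.var(draws) == pytest.approx(4.0, rel=0.05)
        assert np.mean(draws) == pytest.approx(0.0, abs=0.05)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError):
            RandomStream(0).draw("origin_conflict", "poisson")

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            RandomStream(0).normal("origin_hp_chance", -1.0)


class TestFunctionBank:
    def test_zeroed_bank_keeps_death_functions(self):
        fb = FunctionBank.zeroed()
        assert fb.r(1, 100.0) == 0.0
        assert fb.rf(7, 10.0) == 0.0
        # death rate at HP pc 53: 0.001 (e^3 - 1)
        assert fb.r(48, 53.0) == pytest.approx(0.001 * (math.e**3 - 1))
        assert fb.r(29, 50.0) == 0.0

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            FunctionBank(rise=(RiseFunction(),), risefall=())
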