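"""Unit and property tests of the per-event tissue kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relapsim import (
    ModelParams,
    TissueState,
    classify_tissue,
    event_rates,
    selection_weights,
    transition_probabilities,
    turnover_kernel,
)


def make(N=1000, r0=1.0, r1=1.0, mu1=0.0, mu2=0.0, **kw):
    kw.setdefault("r2", 1.5)
    kw.setdefault("d2", 1.0)
    return ModelParams(N=N, r0=r0, r1=r1, mu1=mu1, mu2=mu2, **kw)


class TestSelectionWeights:
    @pytest.mark.parametrize(
        "i, F, c0, c1",
        [
            (0, 1000.0, 1.0, 0.0),
            (1000, 750.0, 0.0, 1.0),
            (500, 875.0, 4.0 / 7.0, 3.0 / 7.0),
        ],
    )
    def test_worked_values(self, i, F, c0, c1):
        w = selection_weights(make(r1=0.75), i)
        assert w.F == pytest.approx(F)
        assert w.c0 == pytest.approx(c0)
        assert w.c1 == pytest.approx(c1)

    def test_out_of_range_raises(self):
        p = make()
        with pytest.raises(ValueError):
            selection_weights(p, -1)
        with pytest.raises(ValueError):
            selection_weights(p, p.N + 1)


class TestTransitionProbabilities:
    def test_no_type1_reduces_to_mutation_influx(self):
        p = make(mu1=0.003, mu2=0.2)
        up, down, stay = transition_probabilities(p, 0)
        assert up == pytest.approx(0.003)
        assert down == 0.0

    def test_fixed_tissue_cannot_lose_type1(self):
        p = make(mu1=0.01, mu2=0.01)
        up, down, stay = transition_probabilities(p, p.N)
        assert down == 0.0

    def test_neutral_midpoint(self):
        # N=1000, i=500, r0=r1=1, no mutation: (1/4, 1/4, 1/2)
        up, down, stay = transition_probabilities(make(), 500)
        assert (up, down, stay) == pytest.approx((0.25, 0.25, 0.5))

    @given(
        i=st.integers(0, 60),
        r0=st.floats(0.2, 3.0),
        r1=st.floats(0.2, 3.0),
        mu1=st.floats(0.0, 1.0),
        mu2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probabilities_normalized(self, i, r0, r1, mu1, mu2):
        p = make(N=60, r0=r0, r1=r1, mu1=mu1, mu2=mu2)
        up, down, stay = transition_probabilities(p, i)
        assert 0.0 <= up <= 1.0 and 0.0 <= down <= 1.0
        assert up + down + stay == pytest.approx(1.0, abs=1e-12)


class TestTurnoverKernel:
    def test_kernel_matches_enumeration(self, small_grid, kernel_oracle):
        """Six-outcome kernel equals the brute-force probability tree."""
        for p, i in small_grid:
            k = turnover_kernel(p, i)
            tree = kernel_oracle(p, i)
            got = {
                (1, False): k.p_up_nofounder,
                (1, True): k.p_up_founder,
                (0, False): k.p_stay_nofounder,
                (0, True): k.p_stay_founder,
                (-1, False): k.p_down_nofounder,
                (-1, True): k.p_down_founder,
            }
            for key, val in got.items():
                assert val == pytest.approx(tree.get(key, 0.0), abs=1e-12), (
                    p, i, key)
            assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)

    def test_marginals_equal_transition_probabilities(self, small_grid):
        for p, i in small_grid:
            k = turnover_kernel(p, i)
            up, down, stay = transition_probabilities(p, i)
            assert k.p_up == pytest.approx(up, abs=1e-14)
            assert k.p_down == pytest.approx(down, abs=1e-14)
            assert k.p_stay == pytest.approx(stay, abs=1e-14)

    @pytest.mark.parametrize(
        "kw, i, expected",
        [
            ({"mu2": 0.0, "mu1": 0.01}, 500, 0.0),
            ({"mu2": 0.1}, 0, 0.0),
            ({"mu2": 0.1}, 500, 0.05),  # r1*i*mu2/F = 500*0.1/1000
        ],
    )
    def test_founder_probability(self, kw, i, expected):
        k = turnover_kernel(make(**kw), i)
        assert k.p_founder == pytest.approx(expected, abs=1e-15)

    def test_founder_probability_monotone_when_type1_fitter(self):
        p = make(r0=1.0, r1=1.3, mu1=0.001, mu2=0.01)
        pf = [turnover_kernel(p, i).p_founder for i in range(p.N + 1)]
        assert all(b >= a - 1e-15 for a, b in zip(pf, pf[1:]))


class TestEventRates:
    @pytest.mark.parametrize(
        "N, delta, x2, d2, r2, expected_wait",
        [
            (1000, 1.0, 0, 1.0, 1.5, 1e-3),
            (2, 2.0, 0, 1.0, 1.5, 1.0),  # rate N/delta = 1/day
            (1000, 1.0, 1000, 1.0, 1.5, 1.0 / 3500.0),
        ],
    )
    def test_mean_wait(self, N, delta, x2, d2, r2, expected_wait):
        p = ModelParams(N=N, delta=delta, r2=r2, d2=d2)
        state = TissueState(i=0, x2=x2)
        rt, rd, rb, wait = event_rates(p, state)
        assert rt == pytest.approx(N / delta)
        assert rd == pytest.approx(d2 * x2)
        assert rb == pytest.approx(r2 * x2)
        assert wait == pytest.approx(expected_wait)


class TestClassifyTissue:
    @pytest.mark.parametrize(
        "i, N, expected",
        [
            (100, 1000, "small"),       # boundary i <= 0.1N inclusive
            (101, 1000, "intermediate"),
            (500, 1000, "intermediate"),
            (900, 1000, "intermediate"),  # i > 0.9N strict
            (901, 1000, "large"),
            (0, 10, "small"),
            (10, 10, "large"),
        ],
    )
    def test_boundaries(self, i, N, expected):
        assert classify_tissue(i, N) == expected

    def test_range_check(self):
        with pytest.raises(ValueError):
            classify_tissue(11, 10)


class TestModelParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(N=1)
        with pytest.raises(ValueError):
            ModelParams(N=100, r2=0.9, d2=1.0)
        with pytest.raises(ValueError):
            ModelParams(N=100, mu1=1.5)
        with pytest.raises(ValueError):
            ModelParams(N=1000, M_detect=1500.0)  # below 2N

    def test_d2_defaults_to_turnover_rate(self):
        assert ModelParams(N=100, delta=2.0, r2=1.5).d2 == pytest.approx(0.5)

    def test_roundtrip_yaml_json_bitexact(self, tmp_path):
        p = ModelParams(N=1000, delta=1.0, r1=0.123456789012345,
                        r2=1.2, d2=1.0, mu1=10 ** -3.6, mu2=3.16e-4)
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            p.save(path)
            assert ModelParams.load(path) == p
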