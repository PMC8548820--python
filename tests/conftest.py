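import itertools

import numpy as np
import pytest

from relapsim import ModelParams


# Parameter sets of the three initiation patterns (sporadic / moderate /
# field-dominated), as printed alongside the pattern classification.
@pytest.fixture(scope="session")
def sporadic_params():
    return ModelParams(N=1000, delta=1.0, r0=1.0, r1=0.75, r2=1.5, d2=1.0,
                       mu1=1e-3, mu2=0.1)


@pytest.fixture(scope="session")
def moderate_params():
    return ModelParams(N=1000, delta=1.0, r0=1.0, r1=1.0, r2=1.2, d2=1.0,
                       mu1=0.01, mu2=0.01)


@pytest.fixture(scope="session")
def dominated_params():
    return ModelParams(N=1000, delta=1.0, r0=1.0, r1=1.5, r2=1.5, d2=1.0,
                       mu1=3.16e-4, mu2=3.16e-4)


@pytest.fixture(scope="session")
def fast_params():
    """Small-tissue, high-mutation set: patients resolve in a few days
    of model time; used wherever the property under test does not pin
    parameter values."""
    return ModelParams(N=100, delta=1.0, r0=1.0, r1=1.0, r2=1.5, d2=1.0,
                       mu1=0.02, mu2=0.02)


def enumerate_turnover(params: ModelParams, i: int):
    """Brute-force enumeration of one turnover event's probability tree.

    Death choice (uniform over N cells) x first-round division choice
    (selection-weighted over all N cells, dying cell included) x
    mutation outcome x — if the daughter is a Type2 founder — the
    mutation-free redraw division.  Returns the six-outcome totals as a
    dict keyed by (delta_i, founder).
    """
    N, r0, r1, mu1, mu2 = params.N, params.r0, params.r1, params.mu1, params.mu2
    F = r0 * (N - i) + r1 * i
    out = {}

    def add(di, founder, p):
        out[(di, founder)] = out.get((di, founder), 0.0) + p

    for die_type, p_die in ((0, (N - i) / N), (1, i / N)):
        for div_type, w in ((0, r0 * (N - i)), (1, r1 * i)):
            p_div = w / F
            if p_div == 0.0:
                continue
            if div_type == 0:
                # daughter Type1 with prob mu1, else Type0
                daughters = ((1, mu1), (0, 1.0 - mu1))
            else:
                # daughter Type2 (founder) with prob mu2, else Type1
                daughters = ((2, mu2), (1, 1.0 - mu2))
            for daughter, p_mut in daughters:
                p = p_die * p_div * p_mut
                if p == 0.0:
                    continue
                if daughter == 2:
                    # founder leaves the tissue; redraw division fills
                    # the dead cell's slot, no mutation
                    for redraw, wr in ((0, r0 * (N - i)), (1, r1 * i)):
                        pr = p * wr / F
                        if pr == 0.0:
                            continue
                        di = redraw - die_type
                        add(di, True, pr)
                else:
                    di = daughter - die_type
                    add(di, False, p)
    return out


@pytest.fixture(scope="session")
def kernel_oracle():
    return enumerate_turnover


@pytest.fixture(scope="session")
def small_grid():
    """(params, i) grid for exhaustive kernel checks at N <= 12."""
    cases = []
    for N in (2, 5, 12):
        for r0, r1 in ((1.0, 1.0), (1.0, 0.75), (0.8, 1.3)):
            for mu1, mu2 in ((0.0, 0.0), (0.01, 0.1), (0.5, 0.3)):
                p = ModelParams(N=N, r0=r0, r1=r1, r2=1.5, d2=1.0,
                                mu1=mu1, mu2=mu2, M_detect=1e9)
                for i in range(N + 1):
                    cases.append((p, i))
    return cases
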