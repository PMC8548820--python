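"""Compiled event engine.

The Gillespie process has three competing Poisson event streams:
tissue turnover (rate N/delta), Type2 birth (r2*x2) and Type2 death
(d2*x2).  While (i, x2) is unchanged all rates are constant, so the
silent turnover outcome (Type1 count unchanged, no founder emitted) can
be thinned out analytically: state-changing turnover events form a
Poisson stream of rate (N/delta) * p_change, and the engine jumps
directly from one state change to the next.  The per-event distribution
is exactly the closed-form kernel's; only the silent events — which by
construction touch nothing — are never materialized.

All routines are numba-njit and use numba's per-thread np.random state,
seeded explicitly per patient for bit-for-bit reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# leg status codes
DETECTED = 0
CENSORED = 1


@njit(cache=False)
def _kernel_changing(N, r0, r1, mu1, mu2, i):
    """Probabilities of the five state-changing turnover outcomes at i.

    Returns (up_nofounder, up_founder, stay_founder, down_nofounder,
    down_founder); their sum is p_change = 1 - p(silent).
    """
    F = r0 * (N - i) + r1 * i
    c1 = r1 * i / F
    c0 = 1.0 - c1
    p_die0 = (N - i) / N
    p_die1 = i / N
    founder = r1 * i * mu2 / F
    up_nf = p_die0 * (r1 * i * (1.0 - mu2) + r0 * (N - i) * mu1) / F
    up_f = p_die0 * founder * c1
    st_f = p_die0 * founder * c0 + p_die1 * founder * c1
    dn_nf = p_die1 * (r0 * (N - i) * (1.0 - mu1)) / F
    dn_f = p_die1 * founder * c0
    return up_nf, up_f, st_f, dn_nf, dn_f


@njit(cache=False)
def _tissue_advance(N, delta, r0, r1, mu1, mu2, i, duration):
    """Advance only the Moran tissue for `duration` days; return final i.

    Type1-count moves are sampled from the marginal (p_up, p_down);
    founder emissions in this window are ignored by the caller's
    contract (used during the deterministic tumor-growth leg).
    """
    if duration <= 0.0:
        return i
    t = 0.0
    turn = N / delta
    while True:
        F = r0 * (N - i) + r1 * i
        c1 = r1 * i / F
        c0 = 1.0 - c1
        p_up = (r0 * (N - i) * mu1 + r1 * i * (1.0 - mu2 + mu2 * c1)) / F * (N - i) / N
        p_down = (r0 * (N - i) * (1.0 - mu1) + r1 * i * mu2 * c0) / F * i / N
        p_change = p_up + p_down
        if p_change <= 0.0:
            return i
        t += np.random.exponential(1.0 / (turn * p_change))
        if t > duration:
            return i
        if np.random.random() * p_change < p_up:
            i += 1
        else:
            i -= 1


@njit(cache=False)
def _run_leg(N, delta, r0, r1, r2, d2, mu1, mu2, M_detect, switch_x2, t_max,
             i0, x2_0, t0):
    """Simulate one leg: from (i0, x2_0, t0) to tumor detection or censoring.

    Returns (status, t_detect, i_at_detect, t_founding, i_final, t_final).
    t_founding is the most recent 0 -> positive transition of x2 (-1.0
    if none, e.g. the leg started with x2 > 0 or never founded).
    """
    i = i0
    x2 = x2_0
    t = t0
    t_found = -1.0
    turn = N / delta

    while x2 < switch_x2:
        up_nf, up_f, st_f, dn_nf, dn_f = _kernel_changing(N, r0, r1, mu1, mu2, i)
        p_change = up_nf + up_f + st_f + dn_nf + dn_f
        lam_turn = turn * p_change
        lam_birth = r2 * x2
        lam_death = d2 * x2
        lam = lam_turn + lam_birth + lam_death
        if lam <= 0.0:
            # absorbing silent state (e.g. i = 0 with mu1 = 0, no tumor)
            return CENSORED, t_max, i, t_found, i, t_max
        t += np.random.exponential(1.0 / lam)
        if t > t_max:
            return CENSORED, t_max, i, t_found, i, t_max
        u = np.random.random() * lam
        if u < lam_birth:
            x2 += 1
        elif u < lam_birth + lam_death:
            x2 -= 1
        else:
            v = np.random.random() * p_change
            if v < up_nf:
                i += 1
            elif v < up_nf + up_f:
                i += 1
                if x2 == 0:
                    t_found = t
                x2 += 1
            elif v < up_nf + up_f + st_f:
                if x2 == 0:
                    t_found = t
                x2 += 1
            elif v < up_nf + up_f + st_f + dn_nf:
                i -= 1
            else:
                i -= 1
                if x2 == 0:
                    t_found = t
                x2 += 1

    # deterministic growth from switch size to detection size
    dts = np.log(M_detect / x2) / (r2 - d2)
    t_detect = t + dts
    if t_detect > t_max:
        i = _tissue_advance(N, delta, r0, r1, mu1, mu2, i, t_max - t)
        return CENSORED, t_max, i, t_found, i, t_max
    i = _tissue_advance(N, delta, r0, r1, mu1, mu2, i, dts)
    return DETECTED, t_detect, i, t_found, i, t_detect


@njit(cache=False)
def _simulate_patient(seed, N, delta, r0, r1, r2, d2, mu1, mu2,
                      M_detect, switch_x2, t_max):
    """Full patient protocol: initiation -> resection -> recurrence.

    Returns (t_first_detection, i_at_first_surgery, t_founding_first,
    detection_censored, t_recurrence, recurrence_censored).  Censored
    durations are reported at the horizon (t_max, or t_max minus the
    surgery time for the recurrence leg).
    """
    np.random.seed(seed)
    s1, t_det1, i_det1, tf1, i_end, t_end = _run_leg(
        N, delta, r0, r1, r2, d2, mu1, mu2, M_detect, switch_x2, t_max,
        0, 0, 0.0)
    if s1 == CENSORED:
        return t_max, i_end, tf1, 1, t_max, 1
    # surgery: all Type2 cells removed, Type1 count preserved
    s2, t_det2, i_det2, tf2, i_end2, t_end2 = _run_leg(
        N, delta, r0, r1, r2, d2, mu1, mu2, M_detect, switch_x2, t_max,
        i_det1, 0, t_det1)
    if s2 == CENSORED:
        return t_det1, i_det1, tf1, 0, t_max - t_det1, 1
    return t_det1, i_det1, tf1, 0, t_det2 - t_det1, 0


@njit(cache=False)
def _run_leg_seeded(seed, N, delta, r0, r1, r2, d2, mu1, mu2,
                    M_detect, switch_x2, t_max, i0, x2_0, t0):
    np.random.seed(seed)
    return _run_leg(N, delta, r0, r1, r2, d2, mu1, mu2,
                    M_detect, switch_x2, t_max, i0, x2_0, t0)


@njit(cache=False)
def _tissue_advance_seeded(seed, N, delta, r0, r1, mu1, mu2, i, duration):
    np.random.seed(seed)
    return _tissue_advance(N, delta, r0, r1, mu1, mu2, i, duration)


@njit(cache=False)
def _tissue_absorb(seed, N, delta, r0, r1, i):
    """Mutation-free Moran chain run to absorption; returns 0 or N.

    Used by validation harnesses to probe fixation probabilities.
    """
    np.random.seed(seed)
    while 0 < i < N:
        # mutation-free marginals; thinned to i-changing events only
        F = r0 * (N - i) + r1 * i
        p_up = r1 * i / F * (N - i) / N
        p_down = r0 * (N - i) / F * i / N
        if np.random.random() * (p_up + p_down) < p_up:
            i += 1
        else:
            i -= 1
    return i


@njit(cache=False)
def _branch_extinct(seed, r2, d2, x0, cap):
    """Per-event birth-death lineage from x0: 1 if extinct before
    reaching `cap` cells, else 0."""
    np.random.seed(seed)
    x = x0
    p_birth = r2 / (r2 + d2)
    while 0 < x < cap:
        if np.random.random() < p_birth:
            x += 1
        else:
            x -= 1
    return 1 if x == 0 else 0


@njit(cache=False)
def _branch_at_time(seed, r2, d2, x0, t_end):
    """Exact per-event birth-death simulation; population at t_end."""
    np.random.seed(seed)
    x = x0
    t = 0.0
    while x > 0:
        rate = (r2 + d2) * x
        t += np.random.exponential(1.0 / rate)
        if t > t_end:
            break
        if np.random.random() * (r2 + d2) < r2:
            x += 1
        else:
            x -= 1
    return x
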