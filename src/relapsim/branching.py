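"""Validation samplers for the linear birth-death (branching) tumor.

A Type2 lineage is a linear birth-death process with per-cell birth
rate r2 and death rate d2; it is supercritical when r2 > d2, goes
extinct with probability d2/r2 from a single founder, and conditional
mean size grows as exp((r2 - d2) t).  These routines provide exact
simulators used to validate the simulator's deterministic-switch
approximation and its extinction behavior:

* per-event Gillespie simulation, feasible for small populations;
* the exact single-generation transition law at a time step dt (each
  cell leaves 0 offspring with probability alpha, else a geometric
  number), which makes whole-population updates O(1) draws and allows
  fully stochastic passage-time experiments up to 1e9 cells.
"""

from __future__ import annotations

import math

import numpy as np

from . import _engine

__all__ = [
    "extinction_probability",
    "simulate_extinction",
    "simulate_size_at",
    "transition_coefficients",
    "sample_transition",
    "passage_time",
]


def extinction_probability(r2: float, d2: float) -> float:
    """Extinction probability of a single-founder lineage: d2/r2
    (1 if subcritical)."""
    if r2 <= 0:
        return 1.0
    return min(1.0, d2 / r2)


def simulate_extinction(
    r2: float, d2: float, n_founders: int, master_seed: int, cap: int = 1000
) -> float:
    """Fraction of single-founder lineages that die out before reaching
    `cap` cells (per-event exact simulation).  For supercritical
    parameters the probability of extinction after reaching `cap` is
    (d2/r2)**cap, negligible for the default cap."""
    from .simulator import derive_seeds

    seeds = derive_seeds(master_seed, n_founders)
    hits = 0
    for s in seeds:
        hits += _engine._branch_extinct(int(s), r2, d2, 1, cap)
    return hits / n_founders


def simulate_size_at(
    r2: float, d2: float, x0: int, t: float, n_rep: int, master_seed: int
) -> np.ndarray:
    """Population sizes at time t across n_rep exact per-event
    replicates (extinct replicates report 0)."""
    from .simulator import derive_seeds

    seeds = derive_seeds(master_seed, n_rep)
    out = np.empty(n_rep, dtype=np.int64)
    for k, s in enumerate(seeds):
        out[k] = _engine._branch_at_time(int(s), r2, d2, x0, t)
    return out


def transition_coefficients(r2: float, d2: float, dt: float) -> tuple[float, float]:
    """(alpha, beta) of the exact birth-death transition over dt.

    One cell leaves 0 descendants with probability alpha, and k >= 1
    descendants with probability (1-alpha)(1-beta) beta**(k-1), where

        alpha = d2 (e^{g dt} - 1) / (r2 e^{g dt} - d2),
        beta  = r2 (e^{g dt} - 1) / (r2 e^{g dt} - d2),  g = r2 - d2

    (critical case r2 == d2: alpha = beta = r2 dt / (1 + r2 dt)).
    """
    if r2 == d2:
        a = r2 * dt / (1.0 + r2 * dt)
        return a, a
    g = r2 - d2
    e = math.exp(g * dt)
    denom = r2 * e - d2
    return d2 * (e - 1.0) / denom, r2 * (e - 1.0) / denom


def sample_transition(
    x: int, r2: float, d2: float, dt: float, rng: np.random.Generator
) -> int:
    """Exact draw of the population size after dt, given x cells now.

    Survivor count S ~ Binomial(x, 1-alpha); total offspring is S plus
    NegativeBinomial(S, 1-beta) extra cells (sum of S geometrics).
    """
    alpha, beta = transition_coefficients(r2, d2, dt)
    s = rng.binomial(x, 1.0 - alpha)
    if s == 0:
        return 0
    return int(s + rng.negative_binomial(s, 1.0 - beta))


def passage_time(
    x0: int,
    target: float,
    r2: float,
    d2: float,
    rng: np.random.Generator,
    dt: float = 0.02,
) -> float | None:
    """First time the population reaches `target`, sampled on a dt grid
    via the exact transition law (None if the lineage dies out).

    The recorded time is the first grid point at or beyond the true
    passage, so the discretisation bias is below dt.
    """
    x = x0
    t = 0.0
    while 0 < x < target:
        x = sample_transition(x, r2, d2, dt, rng)
        t += dt
    return None if x == 0 else t
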