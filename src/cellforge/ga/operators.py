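"""GA operators: initialization, pairwise tournament selection, uniform
crossover, log-normal mutation and elitism.

Selection/crossover pair the population through random permutations of a
single seeded generator; the whole evolution is deterministic given the
seed, and objective evaluation order never touches the RNG.
"""

from __future__ import annotations

import numpy as np

from .genome import (
    N_CUSTOM_MAX, N_CUSTOM_MIN, SCALING_HIGH, SCALING_LOW,
)


def init_population(n: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """n genomes: channel scalings and gap scaling i.i.d. uniform on
    [0.0001, 10]; cell count discrete uniform on {1..5}."""
    if n_channels < 1:
        raise ValueError("empty channel roster")
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")
    pop = np.empty((n, n_channels + 2))
    pop[:, :n_channels + 1] = rng.uniform(SCALING_LOW, SCALING_HIGH,
                                          size=(n, n_channels + 1))
    pop[:, n_channels + 1] = rng.integers(N_CUSTOM_MIN, N_CUSTOM_MAX + 1, size=n)
    return pop


def _beats(n_pass_a, total_a, n_pass_b, total_b) -> bool:
    """True if A wins against B: more objectives passed, then lower summed
    normalized RMSE; exact ties keep the first of the pair."""
    if n_pass_a != n_pass_b:
        return n_pass_a > n_pass_b
    return total_a <= total_b


def tournament_select(pop: np.ndarray, n_pass: np.ndarray, total: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Two independent random pairings of the full population; the winner of
    each pair advances, keeping the population size constant (each original
    genome advances 0, 1 or 2 times)."""
    n = pop.shape[0]
    if n % 2:
        raise ValueError("population size must be even")
    winners = np.empty_like(pop)
    w = 0
    for _ in range(2):
        perm = rng.permutation(n)
        for k in range(0, n, 2):
            a, b = perm[k], perm[k + 1]
            keep = a if _beats(n_pass[a], total[a], n_pass[b], total[b]) else b
            winners[w] = pop[keep]
            w += 1
    return winners


def crossover(pop: np.ndarray, pair_prob: float, param_prob: float,
              rng: np.random.Generator) -> np.ndarray:
    """Random pairing; each pair recombines with ``pair_prob``, in which
    case every parameter independently swaps with ``param_prob``."""
    n, m = pop.shape
    if n % 2:
        raise ValueError("population size must be even")
    out = pop.copy()
    perm = rng.permutation(n)
    for k in range(0, n, 2):
        a, b = perm[k], perm[k + 1]
        if rng.random() < pair_prob:
            swap = rng.random(m) < param_prob
            tmp = out[a, swap].copy()
            out[a, swap] = out[b, swap]
            out[b, swap] = tmp
    return out


def mutation_multipliers(n: int, sigma_log: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal multipliers: exp(N(0, sigma_log))."""
    return np.exp(rng.normal(0.0, sigma_log, size=n))


def mutate(pop: np.ndarray, prob: float, sigma_log: float,
           rng: np.random.Generator) -> np.ndarray:
    """Each parameter independently mutates with ``prob``; continuous
    parameters are scaled by a log-normal multiplier (which may exit the
    initial sampling range); the cell count is scaled, rounded and clamped
    back to [1, 5]."""
    n, m = pop.shape
    out = pop.copy()
    mask = rng.random((n, m)) < prob
    mult = np.exp(rng.normal(0.0, sigma_log, size=(n, m)))
    cont = mask[:, :m - 1]
    out[:, :m - 1] = np.where(cont, out[:, :m - 1] * mult[:, :m - 1], out[:, :m - 1])
    ncol = out[:, m - 1]
    mutated_n = np.clip(np.round(ncol * mult[:, m - 1]), 1, 5)
    out[:, m - 1] = np.where(mask[:, m - 1], mutated_n, ncol)
    return out


def elitism(pop: np.ndarray, n_pass: np.ndarray, total: np.ndarray,
            elite_frac: float, elite_pool=None):
    """Copies of the best ``elite_frac`` overwrite the worst; rank by
    (objectives passed desc, summed normalized RMSE asc).  Returns the new
    population together with re-ordered score arrays.

    ``elite_pool`` optionally supplies the (population, n_pass, total) the
    elites are drawn from — the GA driver passes the previous generation
    there, which guarantees the best score never worsens across
    generations; by default elites come from ``pop`` itself."""
    n = pop.shape[0]
    k = int(round(elite_frac * n))
    pool_pop, pool_np, pool_tot = (pop, n_pass, total) if elite_pool is None else elite_pool
    out = pop.copy()
    np_out = np.asarray(n_pass, dtype=float).copy()
    tot_out = np.asarray(total, dtype=float).copy()
    if k > 0:
        best = np.lexsort((pool_tot, -np.asarray(pool_np)))[:k]
        worst = np.lexsort((total, -np.asarray(n_pass)))[-k:]
        out[worst] = pool_pop[best]
        np_out[worst] = np.asarray(pool_np, dtype=float)[best]
        tot_out[worst] = np.asarray(pool_tot, dtype=float)[best]
    return out, np_out, tot_out
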