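"""Exact samplers for truncated distributions and constructed test fixtures.

The inverse-CDF samplers draw from the *exact* discrete truncated pmfs used
by the fitting module, so they double as generators of ground-truth data with
known exponents.  :func:`make_crackling_fixture` assembles avalanche sets
whose size marginal, duration marginal and mean-size-versus-duration curve
are controlled independently — which makes it possible to build data that
satisfies the crackling relation exactly, or violates it by a chosen amount,
while keeping both marginal exponents fixed.
"""

from __future__ import annotations

import bisect

import numpy as np

from .avalanches import AvalancheSet
from .fitting import lognormal_pmf, powerlaw_pmf

__all__ = [
    "sample_truncated_powerlaw",
    "sample_truncated_lognormal",
    "make_coupled_avalanches",
    "make_crackling_fixture",
]


def _sample_pmf(pmf: np.ndarray, x_min: int, size: int, rng: np.random.Generator):
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(size)
    return x_min + np.searchsorted(cdf, u, side="right").astype(np.int64)


def sample_truncated_powerlaw(
    tau: float, x_min: int, x_max: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF draws from the truncated discrete power law."""
    return _sample_pmf(powerlaw_pmf(tau, x_min, x_max), x_min, size, rng)


def sample_truncated_lognormal(
    mu: float, sigma: float, x_min: int, x_max: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact inverse-CDF draws from the discretized truncated log-normal."""
    return _sample_pmf(lognormal_pmf(mu, sigma, x_min, x_max), x_min, size, rng)


def make_coupled_avalanches(
    n: int,
    tau: float,
    tau_t: float,
    a_exp: float,
    rng: np.random.Generator,
    s_max: int = 2000,
    d_max: int = 30,
    bin_width: float = 1.0,
) -> AvalancheSet:
    """Avalanches with power-law marginals and a prescribed <S>(D) ~ D^a_exp.

    Durations are exact truncated power-law draws with exponent ``tau_t`` and
    sizes exact draws with exponent ``tau``; the two are then *paired by a
    greedy permutation* so that the mean size within each duration group
    tracks c * d**a_exp (c set by total-mass conservation) while both
    marginals — hence the fitted exponents — are left untouched.  Pairs also
    respect size >= duration.

    For ``a_exp = (tau_t - 1)/(tau - 1)`` the result satisfies the crackling
    relation; other values violate it at fixed marginal exponents.
    """
    durations = sample_truncated_powerlaw(tau_t, 1, d_max, n, rng)
    sizes = sample_truncated_powerlaw(tau, 1, s_max, n, rng)

    d_values, d_counts = np.unique(durations, return_counts=True)
    c = sizes.sum() / float(np.sum(d_counts * d_values.astype(float) ** a_exp))

    pool = sorted(sizes.tolist())
    out_sizes = np.empty(n, dtype=np.int64)
    out_durs = np.empty(n, dtype=np.int64)
    pos = 0
    # fill duration groups from largest d down, picking for each slot the
    # pooled size closest to the remaining per-slot target (subject to >= d)
    for d, n_d in sorted(zip(d_values.tolist(), d_counts.tolist()), reverse=True):
        target_sum = c * float(d) ** a_exp * n_d
        acc = 0.0
        for slot in range(n_d):
            need = (target_sum - acc) / (n_d - slot)
            lo = bisect.bisect_left(pool, d)  # enforce size >= duration
            if lo >= len(pool):
                pick = len(pool) - 1
            else:
                k = bisect.bisect_left(pool, need, lo=lo)
                if k <= lo:
                    pick = lo
                elif k >= len(pool):
                    pick = len(pool) - 1
                else:
                    # pace controller: round up while the group sum trails its
                    # target, down once it leads — keeps the realized group
                    # mean pinned to c * d**a_exp despite the discrete pool
                    behind = acc <= target_sum * slot / n_d
                    pick = k if behind else max(k - 1, lo)
            s = pool.pop(pick)
            s = max(s, d)  # clamp if the pool ran out of large values
            acc += s
            out_sizes[pos] = s
            out_durs[pos] = d
            pos += 1

    _rebalance_groups(out_sizes, out_durs, c, a_exp)
    return AvalancheSet(
        sizes=out_sizes,
        durations=out_durs,
        bin_width=bin_width,
        metadata={"tau": tau, "tau_t": tau_t, "a_exp": a_exp},
    )


def _rebalance_groups(sizes: np.ndarray, durs: np.ndarray, c: float, a_exp: float,
                      rel_tol: float = 0.01, max_sweeps: int = 400) -> None:
    """Swap sizes between duration groups until every group mean is on target.

    Swapping is a permutation, so the size marginal stays exactly as drawn;
    only the coupling (hence the conditional means) moves.  Swaps respect
    size >= duration.
    """
    d_values = np.unique(durs)
    groups = {int(d): np.flatnonzero(durs == d) for d in d_values}
    targets = {int(d): c * float(d) ** a_exp * idx.size for d, idx in groups.items()}
    errs = {d: float(sizes[idx].sum() - targets[d]) for d, idx in groups.items()}
    tols = {d: max(rel_tol * targets[d], float(d)) for d in groups}
    def try_swap(d_hi: int, d_lo: int) -> bool:
        # one swap moving size mass from the surplus group to the deficit
        # group: s_in (from lo, entering hi) must be >= d_hi and s_out
        # (from hi, entering lo) must be >= d_lo
        delta = min(errs[d_hi], -errs[d_lo])
        lo_idx, hi_idx = groups[d_lo], groups[d_hi]
        lo_sorted = lo_idx[np.argsort(sizes[lo_idx])]
        in_candidates = lo_sorted[sizes[lo_sorted] >= d_hi]
        if in_candidates.size == 0:
            return False
        j_in = in_candidates[0]
        hi_sorted = hi_idx[np.argsort(sizes[hi_idx])]
        out_candidates = hi_sorted[sizes[hi_sorted] >= d_lo]
        if out_candidates.size == 0:
            return False
        want_out = sizes[j_in] + delta
        k = int(np.searchsorted(sizes[out_candidates], want_out))
        for kk in (min(k, out_candidates.size - 1), max(k - 1, 0)):
            j_out = out_candidates[kk]
            transfer = float(sizes[j_out] - sizes[j_in])
            if 0 < transfer <= 2 * delta:
                sizes[j_in], sizes[j_out] = sizes[j_out], sizes[j_in]
                errs[d_hi] -= transfer
                errs[d_lo] += transfer
                return True
        return False

    for _ in range(max_sweeps):
        order = sorted(errs, key=lambda d: errs[d] / tols[d], reverse=True)
        surplus = [d for d in order if errs[d] > tols[d]]
        deficit = [d for d in reversed(order) if -errs[d] > tols[d]]
        if not surplus or not deficit:
            break
        if not any(try_swap(h, l) for h in surplus for l in deficit):
            break


def make_crackling_fixture(
    n_reps: int,
    n_per_rep: int,
    a_exp: float,
    tau: float = 1.5,
    tau_t: float = 2.0,
    seed: int = 0,
    s_max: int = 2000,
    d_max: int = 30,
) -> list[AvalancheSet]:
    """Seeded repetitions of :func:`make_coupled_avalanches`.

    With the defaults (tau = 3/2, tau_t = 2, the mean-field directed
    percolation reference exponents) and ``a_exp = 2`` the repetitions
    satisfy the crackling relation; ``a_exp = 3`` keeps the same marginals
    but breaks it.
    """
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    return [
        make_coupled_avalanches(
            n_per_rep, tau, tau_t, a_exp, np.random.default_rng(s),
            s_max=s_max, d_max=d_max,
        )
        for s in ss
    ]
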