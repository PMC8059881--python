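"""Testing the crackling-noise scaling relation over a grid of cutoff pairs.

At criticality, crackling-noise systems satisfy the scaling identity

    (tau_t - 1) / (tau - 1) = a,

where tau and tau_t are the avalanche size and duration exponents and a is
the scaling exponent of mean avalanche size versus duration.  The criterion
under audit declares a system "consistent with criticality" at a given pair
of truncation cutoffs (s_max for sizes, d_max for durations) when a pooled
two-sample t-test does not reject equality between the per-repetition ratios
(tau_t - 1)/(tau - 1) and the per-repetition slopes a.  This module fits the
three exponents per repetition, runs the test at one cutoff pair, and scans
a whole grid of pairs, labeling 4-connected regions of consistent cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .avalanches import AvalancheSet, fit_loglog_slope, mean_size_by_duration
from .fitting import (
    InsufficientDataError,
    compare_aic,
    fit_truncated_lognormal,
    fit_truncated_powerlaw,
)

__all__ = [
    "CutoffPair",
    "CracklingResult",
    "CutoffGrid",
    "crackling_ratio",
    "consistency_ttest",
    "evaluate_cutoff",
    "scan_cutoff_grid",
]

S_MAX_FLOOR = 5
D_MAX_FLOOR = 3
DEFAULT_N_TTEST = 14  # repetitions entering each t-test, as in the audited analysis


@dataclass(frozen=True)
class CutoffPair:
    """A (size cutoff, duration cutoff) pair; fits below the floors are vacuous."""

    s_max: int
    d_max: int

    def __post_init__(self) -> None:
        if self.s_max < S_MAX_FLOOR:
            raise ValueError(f"s_max must be >= {S_MAX_FLOOR}")
        if self.d_max < D_MAX_FLOOR:
            raise ValueError(f"d_max must be >= {D_MAX_FLOOR}")


@dataclass
class CracklingResult:
    """Verdict at one cutoff pair.

    ``ratios`` holds the per-repetition (tau_t - 1)/(tau - 1) values and
    ``a_values`` the per-repetition mean-size-versus-duration slopes entering
    the t-test; ``consistent`` is True when equality of means is *not*
    rejected (p > alpha).  ``usable`` is False when fewer than 3 repetitions
    produced valid fits, in which case no verdict is issued.
    """

    cutoff: CutoffPair
    ratios: np.ndarray
    a_values: np.ndarray
    p_value: float
    consistent: Optional[bool]
    n_reps_used: int
    alpha: float
    usable: bool = True
    aic_pass_size: int = 0
    aic_pass_duration: int = 0
    aic_total_size: int = 0
    aic_total_duration: int = 0
    mean_tau: float = float("nan")
    mean_tau_t: float = float("nan")


def crackling_ratio(tau: float, tau_t: float) -> float:
    """The exponent ratio (tau_t - 1)/(tau - 1); undefined at tau = 1."""
    if abs(tau - 1.0) < 1e-12:
        raise ValueError("crackling ratio is undefined at tau = 1")
    return (tau_t - 1.0) / (tau - 1.0)


def consistency_ttest(
    ratios: Sequence[float], a_values: Sequence[float], alpha: float = 0.05
) -> tuple[float, bool]:
    """Pooled-variance two-sample t-test of mean equality.

    Returns ``(p_value, consistent)`` where consistency means the test does
    *not* reject equality: p > alpha.  Degenerate zero-variance inputs give
    p = 1 for equal means and p = 0 otherwise.
    """
    x = np.asarray(ratios, dtype=np.float64)
    y = np.asarray(a_values, dtype=np.float64)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled_ss = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    if pooled_ss == 0.0:
        p = 1.0 if x.mean() == y.mean() else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    return p, p > alpha


def _rep_size_fit(av: AvalancheSet, s_max: int, min_samples: int):
    sizes = av.sizes
    in_support = sizes[sizes <= s_max]
    if in_support.size == 0:
        raise InsufficientDataError("no sizes at or below the cutoff")
    x_min = int(in_support.min())
    if x_min >= s_max:
        raise InsufficientDataError("size support collapses to a point")
    return fit_truncated_powerlaw(sizes, x_min, s_max, min_samples=min_samples)


def _rep_duration_fit(av: AvalancheSet, d_max: int, min_samples: int):
    durs = av.durations
    in_support = durs[durs <= d_max]
    if in_support.size == 0:
        raise InsufficientDataError("no durations at or below the cutoff")
    x_min = int(in_support.min())
    if x_min >= d_max:
        raise InsufficientDataError("duration support collapses to a point")
    return fit_truncated_powerlaw(durs, x_min, d_max, min_samples=min_samples)


class _FitCache:
    """Per-repetition fits keyed by cutoff, shared across grid cells.

    A size fit depends only on s_max and a duration fit (and the mean-size
    slope) only on d_max, so an S x D grid needs S + D fits per repetition,
    not S * D.
    """

    def __init__(self, reps: Sequence[AvalancheSet], min_samples: int, with_aic: bool):
        self.reps = list(reps)
        self.min_samples = min_samples
        self.with_aic = with_aic
        self._size: dict[tuple[int, int], Optional[dict]] = {}
        self._dur: dict[tuple[int, int], Optional[dict]] = {}

    def size_fit(self, rep_idx: int, s_max: int) -> Optional[dict]:
        key = (rep_idx, s_max)
        if key not in self._size:
            av = self.reps[rep_idx]
            try:
                pl = _rep_size_fit(av, s_max, self.min_samples)
                entry = {"tau": pl.exponent, "degenerate": pl.degenerate}
                if self.with_aic:
                    ln = fit_truncated_lognormal(
                        av.sizes, pl.x_min, pl.x_max, min_samples=self.min_samples
                    )
                    entry["aic_pass"] = compare_aic(pl, ln).passes
                self._size[key] = None if pl.degenerate else entry
            except InsufficientDataError:
                self._size[key] = None
        return self._size[key]

    def duration_fit(self, rep_idx: int, d_max: int) -> Optional[dict]:
        key = (rep_idx, d_max)
        if key not in self._dur:
            av = self.reps[rep_idx]
            try:
                pl = _rep_duration_fit(av, d_max, self.min_samples)
                pairs = mean_size_by_duration(av, d_max)
                a, a_err = fit_loglog_slope(pairs)
                entry = {"tau_t": pl.exponent, "a": a, "degenerate": pl.degenerate}
                if self.with_aic:
                    ln = fit_truncated_lognormal(
                        av.durations, pl.x_min, pl.x_max, min_samples=self.min_samples
                    )
                    entry["aic_pass"] = compare_aic(pl, ln).passes
                self._dur[key] = None if pl.degenerate else entry
            except (InsufficientDataError, ValueError):
                self._dur[key] = None
        return self._dur[key]


def _evaluate_from_cache(
    cache: _FitCache,
    cutoff: CutoffPair,
    alpha: float,
    n_ttest: Optional[int],
    cell_seed: int,
) -> CracklingResult:
    ratios, a_values, taus, tau_ts = [], [], [], []
    aic = {"ps": 0, "ts": 0, "pd": 0, "td": 0}
    for idx in range(len(cache.reps)):
        sf = cache.size_fit(idx, cutoff.s_max)
        df = cache.duration_fit(idx, cutoff.d_max)
        if cache.with_aic:
            if sf is not None:
                aic["ts"] += 1
                aic["ps"] += bool(sf.get("aic_pass"))
            if df is not None:
                aic["td"] += 1
                aic["pd"] += bool(df.get("aic_pass"))
        if sf is None or df is None:
            continue
        ratios.append(crackling_ratio(sf["tau"], df["tau_t"]))
        a_values.append(df["a"])
        taus.append(sf["tau"])
        tau_ts.append(df["tau_t"])

    ratios_arr = np.asarray(ratios)
    a_arr = np.asarray(a_values)
    if ratios_arr.size < 3:
        return CracklingResult(
            cutoff=cutoff,
            ratios=ratios_arr,
            a_values=a_arr,
            p_value=float("nan"),
            consistent=None,
            n_reps_used=int(ratios_arr.size),
            alpha=alpha,
            usable=False,
            aic_pass_size=aic["ps"],
            aic_total_size=aic["ts"],
            aic_pass_duration=aic["pd"],
            aic_total_duration=aic["td"],
        )
    if n_ttest is not None and ratios_arr.size > n_ttest:
        rng = np.random.default_rng(cell_seed)
        pick = np.sort(rng.choice(ratios_arr.size, size=n_ttest, replace=False))
        ratios_arr = ratios_arr[pick]
        a_arr = a_arr[pick]
        taus = [taus[i] for i in pick]
        tau_ts = [tau_ts[i] for i in pick]
    p, consistent = consistency_ttest(ratios_arr, a_arr, alpha=alpha)
    return CracklingResult(
        cutoff=cutoff,
        ratios=ratios_arr,
        a_values=a_arr,
        p_value=p,
        consistent=consistent,
        n_reps_used=int(ratios_arr.size),
        alpha=alpha,
        usable=True,
        aic_pass_size=aic["ps"],
        aic_total_size=aic["ts"],
        aic_pass_duration=aic["pd"],
        aic_total_duration=aic["td"],
        mean_tau=float(np.mean(taus)),
        mean_tau_t=float(np.mean(tau_ts)),
    )


def evaluate_cutoff(
    repetition_avalanches: Sequence[AvalancheSet],
    cutoff: CutoffPair,
    alpha: float = 0.05,
    n_ttest: Optional[int] = DEFAULT_N_TTEST,
    seed: int = 0,
    min_samples: int = 10,
    with_aic: bool = False,
) -> CracklingResult:
    """Fit exponents per repetition at one cutoff pair and run the t-test.

    Per repetition: tau on sizes <= s_max, tau_t on durations <= d_max (each
    from the smallest observed value), and a as the log-log slope of mean
    size versus duration for durations <= d_max.  Repetitions with degenerate
    or data-starved fits are dropped; fewer than 3 usable repetitions marks
    the cutoff unusable.  When more than ``n_ttest`` repetitions are usable,
    a seeded subsample without replacement of ``n_ttest`` of them enters the
    test.
    """
    cache = _FitCache(repetition_avalanches, min_samples, with_aic)
    return _evaluate_from_cache(cache, cutoff, alpha, n_ttest, cell_seed=seed)


@dataclass
class CutoffGrid:
    """Verdicts over the cartesian grid s_grid x d_grid of cutoff pairs.

    ``consistent_mask`` is 1.0 where the t-test does not reject, 0.0 where it
    rejects, and NaN for unusable cells; ``largest_component_size`` counts
    the cells of the largest connected region of consistent cells.
    """

    s_grid: np.ndarray
    d_grid: np.ndarray
    results: list = field(repr=False)
    consistent_mask: np.ndarray = field(repr=False, default=None)
    component_labels: np.ndarray = field(repr=False, default=None)
    largest_component_size: int = 0

    def result(self, i: int, j: int) -> CracklingResult:
        """Result at s_grid[i], d_grid[j]."""
        return self.results[i][j]


def _label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    consistent = np.nan_to_num(mask, nan=0.0) == 1.0
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n_comp = ndimage.label(consistent, structure=structure)
    if n_comp == 0:
        return labels, 0
    sizes = ndimage.sum_labels(consistent, labels, index=np.arange(1, n_comp + 1))
    return labels, int(sizes.max())


def scan_cutoff_grid(
    repetition_avalanches: Sequence[AvalancheSet],
    s_grid: Sequence[int],
    d_grid: Sequence[int],
    alpha: float = 0.05,
    n_ttest: Optional[int] = DEFAULT_N_TTEST,
    seed: int = 0,
    min_samples: int = 10,
    with_aic: bool = False,
    connectivity: int = 4,
) -> CutoffGrid:
    """Evaluate every (s_max, d_max) pair and label consistent regions.

    Grids must be non-empty and strictly increasing.  Fits are cached per
    repetition and per cutoff value (a size fit depends only on s_max, a
    duration fit only on d_max).  Connected components of consistent cells
    use 4-neighbor adjacency by default (8-neighbor available).
    """
    s_grid = np.asarray(list(s_grid), dtype=np.int64)
    d_grid = np.asarray(list(d_grid), dtype=np.int64)
    if s_grid.size == 0 or d_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(s_grid) <= 0) or np.any(np.diff(d_grid) <= 0):
        raise ValueError("grids must be strictly increasing")

    cache = _FitCache(repetition_avalanches, min_samples, with_aic)
    cell_seeds = np.random.SeedSequence(seed).generate_state(s_grid.size * d_grid.size)
    results = []
    mask = np.full((s_grid.size, d_grid.size), np.nan)
    for i, s_max in enumerate(s_grid):
        row = []
        for j, d_max in enumerate(d_grid):
            res = _evaluate_from_cache(
                cache,
                CutoffPair(int(s_max), int(d_max)),
                alpha,
                n_ttest,
                cell_seed=int(cell_seeds[i * d_grid.size + j]),
            )
            row.append(res)
            if res.usable:
                mask[i, j] = 1.0 if res.consistent else 0.0
        results.append(row)
    labels, largest = _label_components(mask, connectivity)
    return CutoffGrid(
        s_grid=s_grid,
        d_grid=d_grid,
        results=results,
        consistent_mask=mask,
        component_labels=labels,
        largest_component_size=largest,
    )
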