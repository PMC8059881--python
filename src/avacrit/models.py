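"""Non-critical spiking models used as negative controls for avalanche analysis.

Two generators are provided, each with full seed-level reproducibility:

* :func:`simulate_brunel` — a sparsely connected excitatory–inhibitory network
  of current-based leaky integrate-and-fire units with delta synapses and a
  transmission delay (the classical balanced random network), operated by
  default in the asynchronous-irregular regime, far from any phase transition.
* :func:`simulate_surrogate` — a population of conditionally independent
  Poisson units whose common firing rate follows a mean-reverting
  Ornstein–Uhlenbeck process rectified at zero (a doubly-stochastic population
  with no interactions at all).

Both return a :class:`SpikeRaster`, which also round-trips through a
plain-text event file via :func:`write_raster` / :func:`read_raster`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "BrunelParams",
    "SurrogateParams",
    "SpikeRaster",
    "simulate_brunel",
    "simulate_surrogate",
    "ou_rate_path",
    "write_raster",
    "read_raster",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BrunelParams:
    """Parameters of the balanced excitatory–inhibitory LIF network.

    The defaults place a 1,250-unit network in an inhibition-dominated
    (``g`` above the balance point 4), slightly subthreshold-driven
    (``nu_ext_ratio`` below 1) operating point: the burst-dominated
    synchronized-irregular onset regime, where collective population bursts
    ride on irregular single-unit firing at a few Hz.  This is a classical,
    provably non-critical state of the model, and the one whose avalanche
    statistics resemble spontaneous cortical activity.

    Attributes
    ----------
    n_exc, n_inh
        Number of excitatory / inhibitory units.
    conn_prob
        Connection probability per ordered pair, in (0, 1].
    J
        Excitatory synaptic efficacy in mV (post-synaptic potential jump).
    g
        Ratio of inhibitory to excitatory synaptic weight (dimensionless).
    nu_ext_ratio
        External Poisson drive expressed as a multiple of the threshold rate
        ``nu_thr = theta / (J * C_E * tau_m)``; each unit receives
        ``C_E = conn_prob * n_exc`` independent external lines at
        ``nu_ext_ratio * nu_thr`` each.
    tau_m
        Membrane time constant (ms).
    theta, v_reset
        Firing threshold and post-spike reset potential (mV).
    t_ref
        Absolute refractory period (ms).
    delay
        Synaptic transmission delay (ms), rounded to an integer number of
        integration steps.
    """

    n_exc: int = 1000
    n_inh: int = 250
    conn_prob: float = 0.1
    J: float = 0.1
    g: float = 5.0
    nu_ext_ratio: float = 0.9
    tau_m: float = 20.0
    theta: float = 20.0
    v_reset: float = 10.0
    t_ref: float = 2.0
    delay: float = 1.5

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("n_exc and n_inh must be positive")
        if not (0.0 < self.conn_prob <= 1.0):
            raise ValueError("conn_prob must lie in (0, 1]")
        for name in ("J", "g", "nu_ext_ratio", "tau_m", "theta", "v_reset", "t_ref", "delay"):
            _require_finite(name, getattr(self, name))
        if self.tau_m <= 0 or self.t_ref <= 0 or self.delay <= 0:
            raise ValueError("tau_m, t_ref and delay must be positive")
        if self.theta <= self.v_reset:
            raise ValueError("theta must exceed v_reset")
        if self.g < 0 or self.J < 0 or self.nu_ext_ratio < 0:
            raise ValueError("g, J and nu_ext_ratio must be non-negative")

    @property
    def n_units(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def nu_thr(self) -> float:
        """Threshold rate per external line, in spikes/ms."""
        c_e = self.conn_prob * self.n_exc
        return self.theta / (self.J * c_e * self.tau_m)

    @property
    def ext_rate_total(self) -> float:
        """Total external Poisson rate per unit, in spikes/ms.

        Each unit receives ``C_E`` independent external lines at
        ``nu_ext_ratio * nu_thr``, so the total is
        ``nu_ext_ratio * theta / (J * tau_m)`` — independent of ``C_E``.
        """
        if self.nu_ext_ratio == 0:
            return 0.0
        return self.nu_ext_ratio * self.theta / (self.J * self.tau_m)


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the OU-rate doubly-stochastic Poisson population.

    A single shared rate ``lambda(t)`` (Hz per unit) follows an
    Ornstein–Uhlenbeck process with stationary mean ``ou_mean``, relaxation
    time ``ou_timescale`` and diffusion amplitude ``ou_noise``
    (stationary SD = ``ou_noise * sqrt(ou_timescale / 2)``); the rate is
    rectified at zero before driving the units.  With ``shared_rate=False``
    each unit gets its own independent OU path instead.

    The defaults put the latent rate near the rectification boundary
    (stationary SD well above the mean), so activity is intermittent:
    quiescence broken by slow, culture-like population bursts whose
    avalanches are excursions of the rate process.  ``coeff_ranges`` holds
    the (low, high) intervals used when coefficients are randomized per
    call: ``ou_mean`` in Hz, ``ou_timescale`` in ms, and ``ou_sd`` — the
    stationary SD in Hz, from which
    ``ou_noise = ou_sd * sqrt(2 / ou_timescale)`` is derived.
    """

    n_units: int = 100
    ou_mean: float = 0.5
    ou_timescale: float = 800.0
    ou_noise: float = 0.075
    shared_rate: bool = True
    coeff_ranges: dict = field(
        default_factory=lambda: {
            "ou_mean": (0.0, 1.0),
            "ou_timescale": (300.0, 1200.0),
            "ou_sd": (1.0, 2.5),
        }
    )

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.ou_timescale <= 0:
            raise ValueError("ou_timescale must be positive")
        if self.ou_noise < 0:
            raise ValueError("ou_noise must be non-negative")
        for name in ("ou_mean", "ou_timescale", "ou_noise"):
            _require_finite(name, getattr(self, name))
        for key, rng in self.coeff_ranges.items():
            lo, hi = rng
            if lo > hi:
                raise ValueError(f"coeff_ranges[{key!r}] has low > high")

    @property
    def stationary_sd(self) -> float:
        """Stationary SD of the (unrectified) OU rate, in Hz."""
        return self.ou_noise * math.sqrt(self.ou_timescale / 2.0)


@dataclass
class SpikeRaster:
    """Timestamped spike events from ``n_units`` units on ``[t_start, t_end)``.

    ``times`` (ms, float64) are non-decreasing; ``units`` are integer ids in
    ``[0, n_units)``.  ``seed`` records the RNG seed that produced a simulated
    raster (``None`` for user-loaded data); ``metadata`` carries free-form
    provenance such as the realized OU coefficients.
    """

    times: np.ndarray
    units: np.ndarray
    n_units: int
    t_start: float
    t_end: float
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.times.shape != self.units.shape or self.times.ndim != 1:
            raise ValueError("times and units must be 1-D arrays of equal length")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("event times must be non-decreasing")
            if self.times[0] < self.t_start or self.times[-1] >= self.t_end:
                raise ValueError("event times must lie in [t_start, t_end)")
            if self.units.min() < 0 or self.units.max() >= self.n_units:
                raise ValueError("unit ids must lie in [0, n_units)")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def events(self):
        """Events as a list of (time_ms, unit_id) pairs, sorted by time."""
        return list(zip(self.times.tolist(), self.units.tolist()))

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def mean_rate(self) -> float:
        """Population-average firing rate in Hz."""
        return self.n_events / self.n_units / (self.duration * 1e-3)

    def subsample(self, n_record: int, seed: int) -> "SpikeRaster":
        """Keep a seeded random subset of units, remapped to ``0..n_record-1``.

        Emulates recording from a subset of the population, as an electrode
        array does; avalanche statistics are computed on such recorded
        subsets.
        """
        if n_record >= self.n_units:
            return self
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(self.n_units, size=n_record, replace=False))
        mask = np.isin(self.units, keep)
        remap = np.full(self.n_units, -1, dtype=np.int64)
        remap[keep] = np.arange(n_record)
        meta = dict(self.metadata)
        meta["n_record"] = n_record
        meta["subsample_seed"] = seed
        return replace(
            self,
            times=self.times[mask],
            units=remap[self.units[mask]],
            n_units=n_record,
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# Brunel network
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lif_chunk(
    v,
    ref,
    buf,
    step0,
    n_steps,
    u_ext,
    poisson_cdf,
    decay,
    J,
    theta,
    v_reset,
    ref_steps,
    delay_steps,
    indptr,
    indices,
    weights,
    spike_steps,
    spike_units,
):
    # One integration chunk of the clock-driven LIF network.  `buf` is a ring
    # buffer of (delay_steps + 1) rows holding the synaptic input due at each
    # future step; row (s % rows) is consumed, then zeroed, at step s.  The
    # external Poisson count per unit-step is read off `poisson_cdf` with one
    # pre-generated uniform (inverse-CDF; the cdf table is truncated where
    # the tail mass is below 1e-15).
    n = v.size
    rows = buf.shape[0]
    cap = spike_steps.size
    kmax = poisson_cdf.size
    ns = 0
    for s in range(n_steps):
        row = (step0 + s) % rows
        deliver_row = (step0 + s + delay_steps) % rows
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
            else:
                u = u_ext[s, i]
                k = 0
                while k < kmax and u >= poisson_cdf[k]:
                    k += 1
                vi = v[i] * decay + buf[row, i] + J * k
                if vi >= theta:
                    if ns >= cap:
                        return -1
                    spike_steps[ns] = step0 + s
                    spike_units[ns] = i
                    ns += 1
                    v[i] = v_reset
                    ref[i] = ref_steps
                    for j in range(indptr[i], indptr[i + 1]):
                        buf[deliver_row, indices[j]] += weights[i]
                else:
                    v[i] = vi
        for i in range(n):
            buf[row, i] = 0.0
    return ns


def simulate_brunel(
    params: BrunelParams,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    v_init: str | float = "uniform",
    chunk_steps: int = 10_000,
) -> SpikeRaster:
    """Simulate the balanced random network with clock-driven Euler integration.

    Parameters
    ----------
    params
        Network parameters; see :class:`BrunelParams`.
    duration
        Biological time to simulate, in ms.
    dt
        Integration step in ms; must not exceed the synaptic delay, which is
        rounded to an integer number of steps.
    seed
        Master seed.  Connectivity, initial conditions and external drive use
        independent seed-derived streams, so structural and dynamical noise
        can be varied independently.
    v_init
        ``"uniform"`` draws initial potentials uniformly on
        ``[v_reset, theta)``; a float sets every unit to that value.

    Returns
    -------
    SpikeRaster
        Spikes over ``[0, duration)``; a unit crossing threshold during step
        ``k`` is stamped at time ``k * dt``.  Bit-identical for identical
        ``(params, duration, dt, seed)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.delay:
        raise ValueError("dt must not exceed the synaptic delay")

    n = params.n_units
    n_steps = int(round(duration / dt))
    delay_steps = max(1, int(round(params.delay / dt)))
    ref_steps = int(round(params.t_ref / dt))
    decay = 1.0 - dt / params.tau_m

    ss_conn, ss_init, ss_drive = np.random.SeedSequence(seed).spawn(3)
    rng_conn = np.random.default_rng(ss_conn)
    rng_init = np.random.default_rng(ss_init)
    rng_drive = np.random.default_rng(ss_drive)

    # Erdos–Renyi connectivity stored as per-source adjacency (CSR-like);
    # sources 0..n_exc-1 are excitatory (weight +J), the rest inhibitory (-gJ).
    targets = []
    counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        tgt = np.flatnonzero(rng_conn.random(n) < params.conn_prob)
        counts[i] = tgt.size
        targets.append(tgt)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.concatenate(targets) if n else np.empty(0, dtype=np.int64)
    weights = np.where(
        np.arange(n) < params.n_exc, params.J, -params.g * params.J
    ).astype(np.float64)

    if v_init == "uniform":
        v = rng_init.uniform(params.v_reset, params.theta, size=n)
    else:
        v = np.full(n, float(v_init))
    ref = np.zeros(n, dtype=np.int64)
    buf = np.zeros((delay_steps + 1, n), dtype=np.float64)

    lam_ext = params.ext_rate_total * dt  # expected external spikes/step/unit
    # cdf table for the per-step external count, truncated at negligible tail
    kmax = 2
    while stats.poisson.sf(kmax, lam_ext) > 1e-15:
        kmax += 1
    poisson_cdf = stats.poisson.cdf(np.arange(kmax + 1), lam_ext)

    all_steps: list[np.ndarray] = []
    all_units: list[np.ndarray] = []
    step0 = 0
    while step0 < n_steps:
        m = min(chunk_steps, n_steps - step0)
        u_ext = rng_drive.random((m, n))
        cap = max(4096, m * n // 8)
        while True:
            v_try = v.copy()
            ref_try = ref.copy()
            buf_try = buf.copy()
            sp_s = np.empty(cap, dtype=np.int64)
            sp_u = np.empty(cap, dtype=np.int64)
            ns = _lif_chunk(
                v_try, ref_try, buf_try, step0, m, u_ext, poisson_cdf, decay,
                params.J, params.theta, params.v_reset, ref_steps,
                delay_steps, indptr, indices, weights, sp_s, sp_u,
            )
            if ns >= 0:
                break
            cap = m * n  # absolute worst case: every unit spikes every step
        v, ref, buf = v_try, ref_try, buf_try
        all_steps.append(sp_s[:ns].copy())
        all_units.append(sp_u[:ns].copy())
        step0 += m

    steps = np.concatenate(all_steps) if all_steps else np.empty(0, dtype=np.int64)
    units = np.concatenate(all_units) if all_units else np.empty(0, dtype=np.int64)
    times = steps * dt
    # guard against float rounding pushing the last step onto the boundary
    np.clip(times, 0.0, np.nextafter(duration, 0.0), out=times)
    return SpikeRaster(
        times=times,
        units=units,
        n_units=n,
        t_start=0.0,
        t_end=float(duration),
        seed=seed,
        metadata={"model": "brunel", "dt": dt},
    )


# ---------------------------------------------------------------------------
# OU-rate Poisson surrogate
# ---------------------------------------------------------------------------


def ou_rate_path(
    mean: float,
    timescale: float,
    noise: float,
    duration: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler–Maruyama path of the (unrectified) OU rate, one value per step.

    Started from a draw of the stationary law N(mean, noise^2 * timescale/2).
    """
    n_steps = int(round(duration / dt))
    lam = np.empty(n_steps, dtype=np.float64)
    sd0 = noise * math.sqrt(timescale / 2.0)
    x = mean + sd0 * rng.standard_normal() if sd0 > 0 else mean
    a = dt / timescale
    b = noise * math.sqrt(dt)
    xi = rng.standard_normal(n_steps) if noise > 0 else np.zeros(n_steps)
    for k in range(n_steps):
        lam[k] = x
        x = x + a * (mean - x) + b * xi[k]
    return lam


def simulate_surrogate(
    params: SurrogateParams,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    randomize_coeffs: bool = False,
) -> SpikeRaster:
    """Simulate Poisson units driven by a rectified Ornstein–Uhlenbeck rate.

    The OU path is integrated by Euler–Maruyama at step ``dt`` and rectified
    at zero; given the path, every unit is an independent inhomogeneous
    Poisson process (piecewise-constant rate, spikes placed uniformly within
    their step).  With ``randomize_coeffs`` the coefficients
    (mean, timescale, noise) are drawn once per call from
    ``params.coeff_ranges``; the realized values are recorded in the raster
    metadata.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")

    ss_coeff, ss_path, ss_spikes = np.random.SeedSequence(seed).spawn(3)
    mean, timescale, noise = params.ou_mean, params.ou_timescale, params.ou_noise
    if randomize_coeffs:
        if not params.coeff_ranges:
            raise ValueError("randomize_coeffs requires non-empty coeff_ranges")
        rng_c = np.random.default_rng(ss_coeff)
        r = params.coeff_ranges
        mean = rng_c.uniform(*r["ou_mean"])
        timescale = rng_c.uniform(*r["ou_timescale"])
        sd = rng_c.uniform(*r["ou_sd"])
        noise = sd * math.sqrt(2.0 / timescale)

    rng_path = np.random.default_rng(ss_path)
    rng_spk = np.random.default_rng(ss_spikes)
    n_steps = int(round(duration / dt))
    dt_s = dt * 1e-3  # rate is in Hz, steps in ms

    all_times: list[np.ndarray] = []
    all_units: list[np.ndarray] = []
    if params.shared_rate:
        lam = np.maximum(ou_rate_path(mean, timescale, noise, duration, dt, rng_path), 0.0)
        lam_dt = lam * dt_s
        for u in range(params.n_units):
            counts = rng_spk.poisson(lam_dt)
            steps = np.repeat(np.arange(n_steps), counts)
            t = (steps + rng_spk.random(steps.size)) * dt
            all_times.append(t)
            all_units.append(np.full(steps.size, u, dtype=np.int64))
    else:
        for u in range(params.n_units):
            lam = np.maximum(
                ou_rate_path(mean, timescale, noise, duration, dt, rng_path), 0.0
            )
            counts = rng_spk.poisson(lam * dt_s)
            steps = np.repeat(np.arange(n_steps), counts)
            t = (steps + rng_spk.random(steps.size)) * dt
            all_times.append(t)
            all_units.append(np.full(steps.size, u, dtype=np.int64))

    times = np.concatenate(all_times)
    units = np.concatenate(all_units)
    order = np.lexsort((units, times))
    times = np.clip(times[order], 0.0, np.nextafter(duration, 0.0))
    return SpikeRaster(
        times=times,
        units=units[order],
        n_units=params.n_units,
        t_start=0.0,
        t_end=float(duration),
        seed=seed,
        metadata={
            "model": "surrogate",
            "dt": dt,
            "ou_mean": mean,
            "ou_timescale": timescale,
            "ou_noise": noise,
        },
    )


# ---------------------------------------------------------------------------
# Plain-text raster I/O
# ---------------------------------------------------------------------------

_META_FLOAT_KEYS = {"t_start", "t_end", "dt", "ou_mean", "ou_timescale", "ou_noise"}


def write_raster(raster: SpikeRaster, path) -> None:
    """Write a raster as '#key=value' header lines plus 'time_ms,unit_id' rows.

    Times are serialized with :func:`repr` so the round-trip is exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#n_units={raster.n_units}\n")
        fh.write(f"#t_start={raster.t_start!r}\n")
        fh.write(f"#t_end={raster.t_end!r}\n")
        if raster.seed is not None:
            fh.write(f"#seed={raster.seed}\n")
        for key, val in raster.metadata.items():
            fh.write(f"#{key}={val!r}\n" if isinstance(val, float) else f"#{key}={val}\n")
        for t, u in zip(raster.times.tolist(), raster.units.tolist()):
            fh.write(f"{t!r},{u}\n")


def read_raster(path) -> SpikeRaster:
    """Read a raster event file (comma- or whitespace-delimited time, unit id).

    Header lines start with '#'; '#key=value' lines populate the window
    bounds, unit count and metadata.  Malformed lines are rejected with their
    line number.
    """
    path = Path(path)
    meta: dict = {}
    times: list[float] = []
    units: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'time,unit', got {line!r}")
            try:
                t = float(fields[0])
                u = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable event {line!r}") from exc
            if not math.isfinite(t):
                raise ValueError(f"{path}:{lineno}: non-finite time")
            if u < 0:
                raise ValueError(f"{path}:{lineno}: negative unit id {u}")
            times.append(t)
            units.append(u)

    times_arr = np.asarray(times, dtype=np.float64)
    units_arr = np.asarray(units, dtype=np.int64)
    n_units = int(meta.pop("n_units", 0)) or (int(units_arr.max()) + 1 if units_arr.size else 1)
    t_start = float(meta.pop("t_start", times_arr[0] if times_arr.size else 0.0))
    default_end = float(times_arr[-1]) + 1.0 if times_arr.size else 1.0
    t_end = float(meta.pop("t_end", default_end))
    seed = meta.pop("seed", None)
    seed = int(seed) if seed is not None else None
    for key in list(meta):
        if key in _META_FLOAT_KEYS:
            meta[key] = float(meta[key])
    return SpikeRaster(
        times=times_arr,
        units=units_arr,
        n_units=n_units,
        t_start=t_start,
        t_end=t_end,
        seed=seed,
        metadata=meta,
    )
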