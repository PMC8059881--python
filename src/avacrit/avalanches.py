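"""Avalanche extraction from spike rasters.

A neuronal avalanche is a maximal run of consecutive time bins that each
contain at least one spike (from any unit), delimited by empty bins.  Its
*size* is the total spike count in the run and its *duration* the run length
in bins.  The bin width defaults to the population mean inter-event interval,
the standard convention in the avalanche literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import SpikeRaster

__all__ = [
    "BinnedActivity",
    "AvalancheSet",
    "bin_spikes",
    "default_bin_width",
    "extract_avalanches",
    "mean_size_by_duration",
    "fit_loglog_slope",
    "write_avalanches",
    "read_avalanches",
]


@dataclass
class BinnedActivity:
    """Per-bin population spike counts at a fixed bin width (ms)."""

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass
class AvalancheSet:
    """Sizes (total spikes) and durations (bins) of extracted avalanches."""

    sizes: np.ndarray
    durations: np.ndarray
    bin_width: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if self.sizes.shape != self.durations.shape:
            raise ValueError("sizes and durations must have equal length")
        if self.sizes.size:
            if self.sizes.min() < 1 or self.durations.min() < 1:
                raise ValueError("sizes and durations must be >= 1")
            if np.any(self.sizes < self.durations):
                raise ValueError("every avalanche must satisfy size >= duration")

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)


def bin_spikes(raster: SpikeRaster, bin_width: float) -> BinnedActivity:
    """Count population spikes in half-open bins of width ``bin_width`` ms.

    Bin ``b`` covers ``[t_start + b*w, t_start + (b+1)*w)``; an event exactly
    on a boundary belongs to the later bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    window = raster.t_end - raster.t_start
    n_bins = max(1, math.ceil(window / bin_width))
    if bin_width >= window:
        warnings.warn(
            "bin_width >= raster window; all activity falls in a single bin",
            stacklevel=2,
        )
    idx = np.floor((raster.times - raster.t_start) / bin_width).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedActivity(counts=counts, bin_width=bin_width)


def default_bin_width(raster: SpikeRaster) -> float:
    """Population mean inter-event interval: window length / event count (ms)."""
    if raster.n_events < 2:
        raise ValueError("need at least 2 events to define the mean inter-event interval")
    return (raster.t_end - raster.t_start) / raster.n_events


def extract_avalanches(binned: BinnedActivity, drop_edges: bool = False) -> AvalancheSet:
    """Split the binned activity into maximal runs of nonzero bins.

    Every nonzero bin belongs to exactly one avalanche.  Runs touching the
    first or last bin are kept unless ``drop_edges`` is set (edge runs have
    unobserved starts/ends but dropping them discards data).
    """
    counts = binned.counts
    active = counts > 0
    if not active.any():
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            bin_width=binned.bin_width,
        )
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    if drop_edges:
        keep = np.ones(starts.size, dtype=bool)
        if starts[0] == 0:
            keep[0] = False
        if ends[-1] == counts.size:
            keep[-1] = False
        starts, ends = starts[keep], ends[keep]
    csum = np.concatenate(([0], np.cumsum(counts)))
    sizes = csum[ends] - csum[starts]
    durations = ends - starts
    return AvalancheSet(sizes=sizes, durations=durations, bin_width=binned.bin_width)


def mean_size_by_duration(av: AvalancheSet, d_max: int) -> np.ndarray:
    """Mean avalanche size for each duration ``1..d_max`` present in the data.

    Returns an array of (duration, mean size) rows, one per duration value
    that occurs; durations above ``d_max`` are excluded.
    """
    if d_max < 2:
        raise ValueError("d_max must be >= 2")
    mask = av.durations <= d_max
    if not mask.any():
        raise ValueError(f"no avalanche with duration <= {d_max}")
    dur = av.durations[mask]
    siz = av.sizes[mask]
    values = np.unique(dur)
    means = np.array([siz[dur == d].mean() for d in values], dtype=np.float64)
    return np.column_stack((values.astype(np.float64), means))


def fit_loglog_slope(pairs: np.ndarray) -> tuple[float, float]:
    """OLS slope of log(mean size) against log(duration), with standard error.

    This is the scaling exponent ``a`` of <S>(D) ~ D^a; at criticality in
    crackling-noise systems it equals (tau_t - 1)/(tau - 1).  Requires at
    least 3 distinct durations.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (duration, mean size)")
    if np.unique(pairs[:, 0]).size < 3:
        raise ValueError("need >= 3 distinct durations to fit a slope")
    x = np.log(pairs[:, 0])
    y = np.log(pairs[:, 1])
    n = x.size
    xc = x - x.mean()
    sxx = np.dot(xc, xc)
    slope = np.dot(xc, y) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    if n > 2:
        s2 = np.dot(resid, resid) / (n - 2)
        stderr = math.sqrt(s2 / sxx)
    else:
        stderr = 0.0
    return float(slope), float(stderr)


def write_avalanches(av: AvalancheSet, path) -> None:
    """Serialize as two-column CSV (size, duration) with a '#' header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#bin_width={av.bin_width!r}\n")
        for key, val in av.metadata.items():
            fh.write(f"#{key}={val}\n")
        fh.write("size,duration\n")
        for s, d in zip(av.sizes.tolist(), av.durations.tolist()):
            fh.write(f"{s},{d}\n")


def read_avalanches(path) -> AvalancheSet:
    """Read an avalanche CSV written by :func:`write_avalanches`."""
    path = Path(path)
    meta: dict = {}
    sizes: list[int] = []
    durations: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.lower().startswith("size"):
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'size,duration'")
            sizes.append(int(fields[0]))
            durations.append(int(fields[1]))
    bin_width = float(meta.pop("bin_width", 1.0))
    return AvalancheSet(
        sizes=np.asarray(sizes, dtype=np.int64),
        durations=np.asarray(durations, dtype=np.int64),
        bin_width=bin_width,
        metadata=meta,
    )
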