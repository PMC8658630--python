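"""Photon binning — the software twin of the hardware acquisition block.

Converts a photon timetag stream into integer counts per fixed-width
bin. Bins are left-closed/right-open: a photon exactly on a boundary
belongs to the later bin, matching sequential-counter semantics. The
operation is single-pass (see :func:`iter_bin_counts`) but the batch
path is vectorized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .simulator import PhotonStream

__all__ = ["BinnedTrace", "bin_photons", "iter_bin_counts", "check_bin_width"]


@dataclass(frozen=True)
class BinnedTrace:
    """Integer photon counts per fixed-width bin."""

    counts: np.ndarray    # int64, >= 0
    bin_width: float      # s
    start_time: float = 0.0  # s, left edge of bin 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return int(self.counts.size)

    def bin_edges(self) -> np.ndarray:
        """Left edges of every bin, in seconds."""
        return self.start_time + np.arange(len(self)) * self.bin_width

    def rebin(self, factor: int) -> "BinnedTrace":
        """Merge every ``factor`` consecutive bins (trailing partial dropped)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        n = (len(self) // factor) * factor
        merged = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return BinnedTrace(merged, self.bin_width * factor, self.start_time)


def bin_photons(stream: PhotonStream, bin_width: float,
                start_time: float = 0.0) -> BinnedTrace:
    """Bin a photon stream into counts per ``bin_width`` seconds.

    ``counts[k]`` is the number of timestamps in
    ``[start_time + k*bin_width, start_time + (k+1)*bin_width)``.
    Photons before ``start_time`` are dropped; the trace covers
    ``ceil((duration - start_time)/bin_width)`` bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ts = stream.timestamps
    if ts.size > 1 and np.any(np.diff(ts) < 0):
        raise ValueError("photon stream must be sorted")
    span = stream.duration - start_time
    n_bins = max(0, math.ceil(span / bin_width - 1e-12))
    if n_bins == 0:
        return BinnedTrace(np.zeros(0, dtype=np.int64), bin_width, start_time)

    # exact integer arithmetic when the bin is a whole number of ticks
    ratio = bin_width / stream.resolution
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
        bin_ticks = round(ratio)
        start_tick = round(start_time / stream.resolution)
        idx = (ts - start_tick) // bin_ticks
        idx = idx[(ts >= start_tick)]
    else:
        times = stream.times_s()
        times = times[times >= start_time]
        idx = np.floor((times - start_time) / bin_width).astype(np.int64)
    idx = idx[idx < n_bins]
    counts = np.bincount(idx.astype(np.int64), minlength=n_bins)
    return BinnedTrace(counts.astype(np.int64), bin_width, start_time)


def iter_bin_counts(times_s: Iterable[float], bin_width: float,
                    start_time: float = 0.0) -> Iterator[int]:
    """Single-pass binning over an iterator of sorted arrival times (s).

    Holds only the current bin's counter — the streaming contract of the
    acquisition block. Yields one count per completed bin; photons
    before ``start_time`` are ignored.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    current = 0
    count = 0
    last = -math.inf
    for t in times_s:
        if t < last:
            raise ValueError("times must be sorted")
        last = t
        if t < start_time:
            continue
        # epsilon guards quantized timestamps that land a float ulp
        # below an exact bin boundary
        k = int((t - start_time) / bin_width + 1e-9)
        while k > current:
            yield count
            count = 0
            current += 1
        count += 1
    yield count


def check_bin_width(bin_width: float, spot_fwhm_um: float,
                    velocity_mean_um_s: float) -> None:
    """Warn when a single peak would span < 3 or > 1000 bins.

    Undersampling hides the multi-peak shape; oversampling leaves too
    few counts per bin for the level/difference triggers.
    """
    peak_duration = spot_fwhm_um / velocity_mean_um_s
    n = peak_duration / bin_width
    if n < 3:
        warnings.warn(
            f"bin width {bin_width:.3g}s undersamples the expected peak "
            f"({n:.2f} bins per peak; want >= 3)", stacklevel=2)
    elif n > 1000:
        warnings.warn(
            f"bin width {bin_width:.3g}s oversamples the expected peak "
            f"({n:.0f} bins per peak; want <= 1000)", stacklevel=2)
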