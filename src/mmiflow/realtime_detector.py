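"""Streaming finite-state-machine detector for multi-peak burst clusters.

The detector mirrors a hardware processing block: it consumes binned
photon counts one bin at a time, holds O(1) state, and emits one
:class:`ClusterEvent` per detected particle transit. A cluster is a
group of peaks produced by one particle crossing the N-spot excitation
pattern; the machine has three phases:

``BASELINE``
    Waiting for a cluster. A bin with ``count >= start_threshold`` and
    (optionally) a consecutive-difference jump ``>= diff_threshold``
    opens a cluster and its first peak.
``IN_PEAK``
    Inside a peak; a bin dropping below ``end_threshold`` closes the
    peak and enters the gap phase.
``GAP``
    Between peaks or after the cluster. A re-cross of ``end_threshold``
    opens the next peak of the same cluster; once the counts stay below
    ``end_threshold`` for ``wait_time``, the cluster is confirmed over
    and the event is emitted. The confirmation wait is excluded from
    the reported cluster width.

The detection time tag ``t[i]`` is the left edge of the first
above-threshold bin measured from the start of the experiment; the
cluster width ``dt[i]`` spans first to last above-threshold bin.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .acquisition import BinnedTrace

__all__ = [
    "DetectorConfig",
    "PeakRecord",
    "ClusterEvent",
    "DetectorState",
    "Phase",
    "StreamingDetector",
    "step",
    "detect_stream",
    "auto_threshold",
]


class Phase(enum.Enum):
    BASELINE = "baseline"
    IN_PEAK = "in_peak"
    GAP = "gap"


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters that fully determine detection.

    Thresholds are in counts per bin. ``wait_time`` must exceed the
    inter-peak gap of a cluster but stay below typical inter-event
    times; :meth:`validate_for` checks this against known flow
    parameters.
    """

    bin_width: float = 100e-6        # s
    background_level: float = 0.0    # counts/bin
    start_threshold: float = 10.0    # counts/bin, cluster start level
    end_threshold: float = 5.0       # counts/bin, peak end level
    diff_threshold: float = 0.0      # counts/bin, consecutive-difference trigger
    wait_time: float = 1e-3          # s, cluster-end confirmation
    max_cluster_width: float = 0.5   # s, safety bound
    subtract_background: bool = False  # report heights minus background

    def __post_init__(self) -> None:
        if not (self.start_threshold >= self.end_threshold
                >= self.background_level >= 0):
            raise ValueError(
                "need start_threshold >= end_threshold >= background_level >= 0")
        if self.wait_time <= 0:
            raise ValueError("wait_time must be > 0")
        if self.diff_threshold < 0:
            raise ValueError("diff_threshold must be >= 0")
        if self.bin_width <= 0 or self.max_cluster_width <= 0:
            raise ValueError("bin_width and max_cluster_width must be > 0")

    @property
    def wait_bins(self) -> int:
        """Number of quiet bins that confirm a cluster end."""
        return max(1, math.ceil(self.wait_time / self.bin_width - 1e-9))

    @property
    def max_cluster_bins(self) -> int:
        return max(1, math.ceil(self.max_cluster_width / self.bin_width - 1e-9))

    def validate_for(self, inter_peak_gap_s: float,
                     mean_inter_event_s: float) -> None:
        """Warn when the wait time conflicts with the flow timescales."""
        if self.wait_time <= inter_peak_gap_s:
            warnings.warn(
                f"wait_time {self.wait_time:.3g}s does not exceed the "
                f"inter-peak gap {inter_peak_gap_s:.3g}s; clusters will "
                "fragment", stacklevel=2)
        if self.wait_time >= mean_inter_event_s:
            warnings.warn(
                f"wait_time {self.wait_time:.3g}s is not below the mean "
                f"inter-event time {mean_inter_event_s:.3g}s; events will "
                "merge", stacklevel=2)


@dataclass
class PeakRecord:
    """One peak within a cluster."""

    peak_time: float  # s, left edge of the peak's first above-threshold bin
    width: float      # s, bins at/above end_threshold times bin_width
    height: float     # counts/bin, max bin count in the peak


@dataclass
class ClusterEvent:
    """One particle detection event."""

    index: int                  # 1-based event number
    detection_time_tag: float   # s, t[i]
    cluster_width: float        # s, dt[i]
    peaks: list[PeakRecord]
    truncated: bool = False     # force-closed at max_cluster_width

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class DetectorState:
    """O(1) running state of the FSM (size independent of trace length)."""

    phase: Phase = Phase.BASELINE
    last_count: float = 0.0
    gap_bins: int = 0
    first_bin: int = -1          # first above-threshold bin of the cluster
    last_above_bin: int = -1     # last above-threshold bin seen
    peak_start_bin: int = -1
    peak_max: float = 0.0
    peak_bins: int = 0
    peaks: list[PeakRecord] = field(default_factory=list)
    start_time: float = 0.0      # s, left edge of bin 0


def _close_peak(state: DetectorState, config: DetectorConfig) -> None:
    height = state.peak_max
    if config.subtract_background:
        height -= config.background_level
    state.peaks.append(PeakRecord(
        peak_time=state.start_time + state.peak_start_bin * config.bin_width,
        width=state.peak_bins * config.bin_width,
        height=height))
    state.peak_bins = 0
    state.peak_max = 0.0


def _emit(state: DetectorState, config: DetectorConfig,
          truncated: bool = False) -> ClusterEvent:
    event = ClusterEvent(
        index=0,
        detection_time_tag=state.start_time + state.first_bin * config.bin_width,
        cluster_width=(state.last_above_bin - state.first_bin + 1)
        * config.bin_width,
        peaks=state.peaks,
        truncated=truncated)
    state.phase = Phase.BASELINE
    state.gap_bins = 0
    state.first_bin = -1
    state.last_above_bin = -1
    state.peaks = []
    return event


def step(state: DetectorState, bin_index: int, count: float,
         config: DetectorConfig) -> tuple[DetectorState, ClusterEvent | None]:
    """Advance the FSM by one bin; mutates and returns ``state``.

    Bins must be presented strictly in order. The emitted event (if
    any) carries ``index=0``; callers assign 1-based event numbers.
    """
    emitted: ClusterEvent | None = None
    if state.phase is Phase.BASELINE:
        if count >= config.start_threshold and \
                (count - state.last_count) >= config.diff_threshold:
            state.phase = Phase.IN_PEAK
            state.first_bin = bin_index
            state.last_above_bin = bin_index
            state.peak_start_bin = bin_index
            state.peak_max = count
            state.peak_bins = 1
    elif state.phase is Phase.IN_PEAK:
        if count < config.end_threshold:
            _close_peak(state, config)
            state.phase = Phase.GAP
            state.gap_bins = 1
            if state.gap_bins >= config.wait_bins:
                emitted = _emit(state, config)
        else:
            state.last_above_bin = bin_index
            state.peak_bins += 1
            if count > state.peak_max:
                state.peak_max = count
    else:  # GAP
        if count >= config.end_threshold:
            state.phase = Phase.IN_PEAK
            state.gap_bins = 0
            state.peak_start_bin = bin_index
            state.last_above_bin = bin_index
            state.peak_max = count
            state.peak_bins = 1
        else:
            state.gap_bins += 1
            if state.gap_bins >= config.wait_bins:
                emitted = _emit(state, config)

    # safety bound: force-close runaway clusters
    if emitted is None and state.phase is not Phase.BASELINE and \
            bin_index - state.first_bin + 1 > config.max_cluster_bins:
        if state.phase is Phase.IN_PEAK:
            _close_peak(state, config)
        emitted = _emit(state, config, truncated=True)

    state.last_count = count
    return state, emitted


class StreamingDetector:
    """Stateful wrapper around :func:`step` for chunked or live feeding.

    Output is invariant to how the trace is chunked: push bins one at a
    time or in arrays, then :meth:`finish` to flush.
    """

    def __init__(self, config: DetectorConfig, start_time: float = 0.0):
        self.config = config
        self.state = DetectorState(start_time=start_time)
        self._bin_index = 0
        self._n_events = 0

    def push(self, counts: float | Iterable[float]) -> list[ClusterEvent]:
        """Feed one bin count or an iterable of them; return new events."""
        if np.isscalar(counts):
            counts = (counts,)
        events: list[ClusterEvent] = []
        for c in counts:
            self.state, ev = step(self.state, self._bin_index, float(c),
                                  self.config)
            self._bin_index += 1
            if ev is not None:
                self._n_events += 1
                ev.index = self._n_events
                events.append(ev)
        return events

    def finish(self) -> list[ClusterEvent]:
        """Flush: close any open cluster as if the wait time had elapsed."""
        events: list[ClusterEvent] = []
        st = self.state
        if st.phase is not Phase.BASELINE:
            if st.phase is Phase.IN_PEAK:
                _close_peak(st, self.config)
            ev = _emit(st, self.config)
            self._n_events += 1
            ev.index = self._n_events
            events.append(ev)
        return events


def detect_stream(trace: BinnedTrace, config: DetectorConfig) -> list[ClusterEvent]:
    """Run the streaming detector over a whole binned trace.

    Equivalent to folding :func:`step` over every bin and flushing at
    the end; event indices are 1-based in detection order.
    """
    if abs(trace.bin_width - config.bin_width) > 1e-12 * config.bin_width:
        config = DetectorConfig(
            bin_width=trace.bin_width,
            background_level=config.background_level,
            start_threshold=config.start_threshold,
            end_threshold=config.end_threshold,
            diff_threshold=config.diff_threshold,
            wait_time=config.wait_time,
            max_cluster_width=config.max_cluster_width,
            subtract_background=config.subtract_background)
    det = StreamingDetector(config, start_time=trace.start_time)
    events = det.push(trace.counts)
    events += det.finish()
    return events


def auto_threshold(trace_prefix: np.ndarray | BinnedTrace,
                   k_sigma: float = 5.0) -> tuple[float, float, float]:
    """Derive thresholds from a cluster-free prefix of the trace.

    ``background = mean``, ``start = mean + k_sigma*std`` and
    ``end = mean + k_sigma/2*std`` floored at ``mean + 1`` (start is
    additionally floored at end so the config invariant holds).

    The caller asserts the prefix contains no clusters; at least 100
    bins are required for a stable estimate.
    """
    counts = trace_prefix.counts if isinstance(trace_prefix, BinnedTrace) \
        else np.asarray(trace_prefix, dtype=float)
    if counts.size < 100:
        raise ValueError(f"need >= 100 prefix bins, got {counts.size}")
    mean = float(np.mean(counts))
    std = float(np.std(counts, ddof=1))
    end = max(mean + 0.5 * k_sigma * std, mean + 1.0)
    start = max(mean + k_sigma * std, end)
    return start, end, mean
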