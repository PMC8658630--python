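"""Offline reference detector and real-time-vs-offline validation statistics.

The offline detector is the transparent post-processing baseline: with
the full trace in hand it takes maximal runs of bins at or above a
threshold and merges runs separated by gaps shorter than the wait time.
Under matched thresholds it is equivalent to the streaming FSM — the
concordance between the two is the central validation claim, tested as
such rather than assumed.

Event matching is greedy nearest-in-time one-to-one within a tolerance;
unmatched reference events are misses, unmatched candidates spurious.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from .acquisition import BinnedTrace
from .realtime_detector import ClusterEvent, PeakRecord

__all__ = ["MatchReport", "offline_detect", "match_events",
           "timing_error_summary"]


def offline_detect(trace: BinnedTrace, threshold: float,
                   wait_time: float = 1e-3) -> list[ClusterEvent]:
    """Two-pass threshold-run-merge detection on a complete trace.

    Maximal runs of ``counts >= threshold`` become peaks; runs whose
    separating gap is shorter than ``wait_time`` belong to the same
    cluster. Returns the same event schema as the streaming detector.
    """
    counts = np.asarray(trace.counts)
    above = counts >= threshold
    if not above.any():
        return []
    # run boundaries
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0]  # inclusive last bin of a run
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [counts.size - 1]))

    wait_bins = max(1, int(np.ceil(wait_time / trace.bin_width - 1e-9)))
    bw = trace.bin_width
    t0 = trace.start_time

    events: list[ClusterEvent] = []
    cluster: list[tuple[int, int]] = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        gap = s - cluster[-1][1] - 1
        if gap < wait_bins:
            cluster.append((int(s), int(e)))
        else:
            events.append(_make_event(cluster, counts, bw, t0))
            cluster = [(int(s), int(e))]
    events.append(_make_event(cluster, counts, bw, t0))
    for i, ev in enumerate(events, start=1):
        ev.index = i
    return events


def _make_event(runs: list[tuple[int, int]], counts: np.ndarray,
                bin_width: float, start_time: float) -> ClusterEvent:
    peaks = [PeakRecord(peak_time=start_time + s * bin_width,
                        width=(e - s + 1) * bin_width,
                        height=float(counts[s:e + 1].max()))
             for s, e in runs]
    first = runs[0][0]
    last = runs[-1][1]
    return ClusterEvent(index=0,
                        detection_time_tag=start_time + first * bin_width,
                        cluster_width=(last - first + 1) * bin_width,
                        peaks=peaks)


@dataclass
class MatchReport:
    """Outcome of matching a candidate event list against a reference."""

    n_reference: int
    n_matched: int
    n_missed: int
    n_spurious: int
    accuracy_pct: float
    timing_errors_ms: list[float] = field(default_factory=list)
    tolerance_ms: float = 50.0


def _event_times(events) -> np.ndarray:
    return np.array([e.detection_time_tag if isinstance(e, ClusterEvent)
                     else float(e) for e in events], dtype=float)


def match_events(reference, candidate,
                 tolerance_ms: float = 50.0) -> MatchReport:
    """Greedy nearest-time one-to-one matching within a tolerance.

    Both inputs are time-sorted lists of events (or raw times in
    seconds). Pairs are matched in order of increasing absolute time
    difference, each event used at most once; the result is invariant
    to permutations of the candidate list. Timing errors are candidate
    minus reference, in ms.
    """
    ref = np.sort(_event_times(reference))
    cand = np.sort(_event_times(candidate))
    tol = tolerance_ms * 1e-3

    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, t in enumerate(ref):
        j0 = int(np.searchsorted(cand, t - tol, side="left"))
        j = j0
        while j < cand.size and cand[j] <= t + tol:
            pairs.append((abs(cand[j] - t), i, j))
            j += 1
    pairs.sort()
    used_ref: set[int] = set()
    used_cand: set[int] = set()
    errors: list[float] = []
    for _, i, j in pairs:
        if i in used_ref or j in used_cand:
            continue
        used_ref.add(i)
        used_cand.add(j)
        errors.append((cand[j] - ref[i]) * 1e3)
    n_ref = int(ref.size)
    n_matched = len(used_ref)
    accuracy = 100.0 * n_matched / n_ref if n_ref else float("nan")
    return MatchReport(n_reference=n_ref, n_matched=n_matched,
                       n_missed=n_ref - n_matched,
                       n_spurious=int(cand.size) - n_matched,
                       accuracy_pct=accuracy,
                       timing_errors_ms=sorted(errors),
                       tolerance_ms=tolerance_ms)


def timing_error_summary(timing_errors_ms, band_ms: float = 5.0,
                         hist_bin_ms: float = 1.0
                         ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Fraction of timing errors inside a +/-band, plus their histogram.

    Returns ``(percentage, (counts, bin_edges_ms))``.
    """
    err = np.asarray(list(timing_errors_ms), dtype=float)
    if err.size == 0:
        raise ValueError("empty timing-error list")
    pct = 100.0 * float(np.mean(np.abs(err) <= band_ms))
    lim = max(band_ms, float(np.abs(err).max())) + hist_bin_ms
    n = int(np.ceil(lim / hist_bin_ms))
    edges = np.arange(-n, n + 1) * hist_bin_ms
    counts, _ = np.histogram(err, bins=edges)
    return pct, (counts, edges)
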