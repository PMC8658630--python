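"""Flow statistics computed from detected particle events.

From each event's time tag ``t(i)`` and cluster width ``dt(i)`` the
module derives:

* per-particle velocity          ``v(i) = W / dt(i)``
* instantaneous concentration    ``c_i(i) = i / (v(i) * A * t(i))``
* cumulative mean concentration  ``C(i) = mean of c_i(1..i)``
* relative step deviation        ``dC(i)/C(i) = (C(i) - C(i-1))/C(i)``,
  with ``C(0) = 0`` so the first value is 1
* the settling point: the smallest event index ``M`` after which the
  step deviation stays inside a +/-5 % window, and its time ``t_s``
* detection-rate and inter-arrival (Poisson) statistics
* number-concentration <-> molarity conversion.

Velocities use the full MMI width ``W`` as the transit length. The
N-spot envelope that actually crosses the detection thresholds spans
slightly less than ``W``, so an optional pattern-span correction factor
(effective span / W) can rescale velocities when ground truth is known;
the default of 1.0 keeps the plain ``W/dt`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FlowGeometry
from .realtime_detector import ClusterEvent, DetectorConfig
from .simulator import FWHM_TO_SIGMA, UM3_PER_ML, SimulationParams

__all__ = [
    "FlowSeries",
    "ArrivalStats",
    "AVOGADRO",
    "particle_velocity",
    "instantaneous_concentration",
    "cumulative_mean",
    "relative_deviation",
    "settling_point",
    "settling_constant_flow",
    "detection_rate",
    "interarrival_stats",
    "to_molar",
    "from_molar",
    "pattern_span_correction",
    "analyze_events",
]

#: exact SI Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23


def particle_velocity(event: ClusterEvent | float, mmi_width: float,
                      span_correction: float = 1.0) -> float:
    """Per-particle velocity v = W/dt in µm/s.

    ``event`` may be a :class:`ClusterEvent` or a cluster width in
    seconds. ``span_correction`` rescales the transit length to the
    effective above-threshold span of the spot pattern (default 1.0,
    i.e. the plain ``W/dt`` convention).
    """
    dt = event.cluster_width if isinstance(event, ClusterEvent) else float(event)
    if dt <= 0:
        raise ValueError("cluster width must be > 0")
    return span_correction * mmi_width / dt


def instantaneous_concentration(i: int, velocity: float, cross_section: float,
                                time_tag: float) -> float:
    """Instantaneous concentration c_i(i) = i/(v·A·t(i)) in particles/mL.

    ``velocity`` in µm/s, ``cross_section`` in µm², ``time_tag`` in s.
    """
    if i < 1:
        raise ValueError("event index must be >= 1")
    if velocity <= 0 or cross_section <= 0 or time_tag <= 0:
        raise ValueError("velocity, cross-section and time tag must be > 0")
    return i / (velocity * cross_section * time_tag) * UM3_PER_ML


def cumulative_mean(c_series: np.ndarray) -> tuple[np.ndarray, float]:
    """Running mean C(i) of the instantaneous concentrations, plus C_ave.

    ``C_ave`` is the unweighted mean of the reported ``C(i)`` values
    (the horizontal-line summary of a concentration trace), not the
    final ``C(n)``.
    """
    c = np.asarray(c_series, dtype=float)
    if c.size == 0:
        raise ValueError("empty concentration series")
    series = np.cumsum(c) / np.arange(1, c.size + 1)
    return series, float(series.mean())


def relative_deviation(c_cum: np.ndarray) -> np.ndarray:
    """Step deviation (C(i) - C(i-1))/C(i) with C(0) = 0.

    The first value is therefore 1. Entries where C(i) = 0 are defined
    as 0 (nothing to normalize by).
    """
    c = np.asarray(c_cum, dtype=float)
    prev = np.concatenate(([0.0], c[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(c != 0, (c - prev) / np.where(c != 0, c, 1.0), 0.0)
    return d


def _sustained_index(dev: np.ndarray, window: float) -> int | None:
    """Smallest 1-based i with |dev(j)| <= window for ALL j >= i, or None."""
    ok = np.abs(dev) <= window
    if dev.size == 0 or not ok[-1]:
        return None
    bad = np.nonzero(~ok)[0]
    return int(bad[-1]) + 2 if bad.size else 1


def settling_point(c_cum: np.ndarray, time_tags: np.ndarray,
                   window: float = 0.05) -> tuple[float, int] | None:
    """Settling time and event count of a cumulative-mean series.

    ``M`` is the smallest event index such that the step deviation
    stays within ``+/-window`` for every later event (a sustained
    criterion, not a first crossing); ``t_s = t(M)``. Returns ``None``
    when the series never settles. Since the first deviation is 1 by
    definition, ``M >= 2`` whenever it exists.
    """
    if not 0 < window < 1:
        raise ValueError("window must be in (0, 1)")
    dev = relative_deviation(np.asarray(c_cum, dtype=float))
    m = _sustained_index(dev, window)
    if m is None:
        return None
    t = np.asarray(time_tags, dtype=float)
    return float(t[m - 1]), m


def settling_constant_flow(time_tags: np.ndarray,
                           window: float = 0.05) -> int | None:
    """Settling event count M from time tags alone, at constant flow.

    With constant volumetric flow ``c_i(i)`` is proportional to
    ``i/t(i)``, so the step deviation reduces to

        dC(M)/C(M) = 1 - (M/(M-1)) * sum_{i<M} i/t(i) / sum_{i<=M} i/t(i)

    which needs no velocity or cross-section. Same sustained-window
    criterion as :func:`settling_point`; returns None when unsettled.
    """
    t = np.asarray(time_tags, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 events")
    i = np.arange(1, t.size + 1)
    s = np.cumsum(i / t)
    dev = np.empty(t.size)
    dev[0] = 1.0
    m = i[1:].astype(float)
    dev[1:] = 1.0 - (m / (m - 1)) * (s[:-1] / s[1:])
    return _sustained_index(dev, window)


@dataclass
class FlowSeries:
    """Per-event flow statistics plus the settling summary."""

    velocity: np.ndarray                 # µm/s
    instantaneous_concentration: np.ndarray  # particles/mL
    cumulative_mean: np.ndarray          # particles/mL
    relative_deviation: np.ndarray       # dimensionless
    time_tags: np.ndarray                # s
    cluster_widths: np.ndarray           # s
    mean_concentration: float            # C_ave, particles/mL
    settling_time: float | None = None   # t_s, s
    settling_events: int | None = None   # M

    def __len__(self) -> int:
        return int(self.time_tags.size)


def analyze_events(events: list[ClusterEvent], geometry: FlowGeometry,
                   window: float = 0.05,
                   span_correction: float = 1.0) -> FlowSeries:
    """Full per-event flow analysis of a detected event list."""
    if not events:
        raise ValueError("no events to analyze")
    t = np.array([e.detection_time_tag for e in events])
    dt = np.array([e.cluster_width for e in events])
    v = span_correction * geometry.mmi_width / dt
    i = np.arange(1, len(events) + 1)
    ci = i / (v * geometry.channel_cross_section * t) * UM3_PER_ML
    c_cum, c_ave = cumulative_mean(ci)
    dev = relative_deviation(c_cum)
    settle = settling_point(c_cum, t, window)
    t_s, m = settle if settle is not None else (None, None)
    return FlowSeries(v, ci, c_cum, dev, t, dt, c_ave, t_s, m)


def detection_rate(time_tags: np.ndarray, window_s: float,
                   t_max: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Windowed event rate over the experiment.

    Counts events in consecutive windows of ``window_s`` seconds from
    t = 0 and divides by the window. Returns ``(window_centers, rate)``.
    The cumulative count-vs-time view is simply
    ``(time_tags, 1..n)`` and needs no helper.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    t = np.asarray(time_tags, dtype=float)
    end = t_max if t_max is not None else (t.max() if t.size else window_s)
    n_win = max(1, math.ceil(end / window_s - 1e-12))
    edges = np.arange(n_win + 1) * window_s
    counts, _ = np.histogram(t, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / window_s


@dataclass
class ArrivalStats:
    """Inter-arrival statistics of detected events (Poisson diagnostics)."""

    arrival_rate: float            # events/s over the observed span
    exp_fit_rate: float            # 1/mean inter-arrival (exponential MLE)
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray    # s


def interarrival_stats(time_tags: np.ndarray,
                       hist_bin_s: float = 0.1) -> ArrivalStats:
    """Exponential MLE fit and histogram of inter-event times.

    For independent (Poisson) arrivals the inter-arrival distribution
    is Exponential(lambda); the MLE of lambda is 1/mean.
    """
    t = np.asarray(time_tags, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 events")
    gaps = np.diff(t)
    if np.any(gaps < 0):
        raise ValueError("time tags must be sorted")
    rate = (t.size - 1) / (t[-1] - t[0])
    fit = 1.0 / float(np.mean(gaps))
    n_bins = max(1, math.ceil(gaps.max() / hist_bin_s))
    edges = np.arange(n_bins + 1) * hist_bin_s
    counts, _ = np.histogram(gaps, bins=edges)
    # the top edge is exclusive in np.histogram except the last bin, so
    # counts always sum to n_events - 1
    return ArrivalStats(rate, fit, counts, edges)


def to_molar(number_concentration_per_ml: float) -> float:
    """Convert particles/mL to molarity in attomolar (1 aM = 1e-18 mol/L)."""
    if number_concentration_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return number_concentration_per_ml * 1e3 / AVOGADRO * 1e18


def from_molar(molarity_am: float) -> float:
    """Inverse of :func:`to_molar`: attomolar to particles/mL."""
    return molarity_am * 1e-18 * AVOGADRO / 1e3


def pattern_span_correction(params: SimulationParams,
                            config: DetectorConfig) -> float:
    """Expected above-threshold span of the spot pattern, as a fraction of W.

    The detector's cluster width runs from the first bin at or above
    ``start_threshold`` to the last at or above ``end_threshold``. For
    Gaussian spots of amplitude ``a`` counts/bin above background, the
    crossing sits ``sigma * sqrt(2 ln(a/thr))`` outside the outermost
    spot centres, so the effective transit length is

        (N-1)*spacing + sigma*(sqrt(2 ln(a/thr_start)) + sqrt(2 ln(a/thr_end)))

    clipped to [0, W]. Dividing velocities by ``W`` but multiplying by
    this factor removes the systematic overestimate when comparing with
    simulation ground truth.
    """
    sigma = params.fwhm * FWHM_TO_SIGMA
    amp = params.peak_photon_rate * config.bin_width  # counts/bin at centre
    span = (params.n_spots - 1) * params.spacing

    def cross(thr: float) -> float:
        level = thr - config.background_level
        if level <= 0 or amp <= level:
            return 0.0
        return sigma * math.sqrt(2.0 * math.log(amp / level))

    span += cross(config.start_threshold) + cross(config.end_threshold)
    w = params.geometry.mmi_width
    return min(span, w) / w
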