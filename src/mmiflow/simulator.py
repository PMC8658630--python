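"""Synthetic photon-timetag streams for particles transiting an N-spot pattern.

Particles arrive in the channel as a homogeneous Poisson process with
rate ``r = C * v_mean * A`` (concentration × mean velocity × channel
cross-section). Each transit crosses the N excitation spots at constant
velocity and emits photons as an inhomogeneous Poisson process whose
intensity is a sum of N Gaussian peaks (one per spot) riding on a
uniform background. Photon timestamps are quantized to a configurable
resolution, emulating a timetagger.

Sampling is exact: each spot's Gaussian intensity component is an
independent inhomogeneous Poisson process, so the stream is drawn as a
superposition of per-spot Poisson counts with normally distributed
arrival times plus uniform background photons. This is equal in law to
thinning the summed intensity but needs no intensity bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import FlowGeometry

__all__ = [
    "SimulationParams",
    "TransitRecord",
    "PhotonStream",
    "sample_transits",
    "emission_rate",
    "generate_photon_stream",
    "simulate",
    "arrival_rate",
]

#: µm³ per mL (1 mL = 1 cm³ = 1e12 µm³)
UM3_PER_ML = 1e12

#: FWHM → standard deviation for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: refuse simulations with more expected transits than this
MAX_EXPECTED_TRANSITS = 1e7


@dataclass(frozen=True)
class SimulationParams:
    """Full description of one synthetic experiment.

    Parameters
    ----------
    concentration : float
        True particle number density ``C`` (particles/mL).
    velocity_mean : float
        Mean transit velocity (µm/s).
    geometry : FlowGeometry
        Channel cross-section (µm²) and MMI width (µm).
    velocity_cv : float
        Coefficient of variation of per-particle velocity (truncated
        normal, resampled at <= 0). 0 gives constant velocity.
    n_spots : int
        Number of excitation spots N.
    spot_spacing : float or None
        Centre-to-centre spot spacing (µm); defaults to W/N.
    spot_fwhm : float or None
        Spot full width at half maximum (µm); defaults to W/(2N).
    peak_photon_rate : float
        Photon rate at a spot centre (counts/s) for a particle at full
        brightness.
    background_rate : float
        Uniform background photon rate (counts/s).
    duration : float
        Experiment duration (s).
    timestamp_resolution : float
        Timetag quantization (s); default 100 ns.
    brightness_min : float
        Lower bound of the per-transit brightness scale factor drawn
        uniformly from [brightness_min, 1]; 1.0 (default) disables the
        wall-proximity dimming model.
    seed : int
        Seed that fully determines the output.
    """

    concentration: float
    velocity_mean: float
    geometry: FlowGeometry
    velocity_cv: float = 0.0
    n_spots: int = 7
    spot_spacing: float | None = None
    spot_fwhm: float | None = None
    peak_photon_rate: float = 5e5
    background_rate: float = 1e3
    duration: float = 60.0
    timestamp_resolution: float = 100e-9
    brightness_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.background_rate < 0 \
                or self.peak_photon_rate < 0 or self.duration < 0:
            raise ValueError("rates, concentration and duration must be >= 0")
        if self.velocity_mean <= 0:
            raise ValueError("velocity_mean must be > 0")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if not 0 < self.brightness_min <= 1:
            raise ValueError("brightness_min must be in (0, 1]")
        span = (self.n_spots - 1) * self.spacing + self.fwhm
        if span > self.geometry.mmi_width * (1 + 1e-9):
            raise ValueError("spot pattern does not fit inside the MMI width")

    @property
    def spacing(self) -> float:
        """Spot spacing in µm (default W/N)."""
        if self.spot_spacing is not None:
            return self.spot_spacing
        return self.geometry.mmi_width / self.n_spots

    @property
    def fwhm(self) -> float:
        """Spot FWHM in µm (default W/(2N))."""
        if self.spot_fwhm is not None:
            return self.spot_fwhm
        return self.geometry.mmi_width / (2 * self.n_spots)

    @property
    def spot_positions(self) -> np.ndarray:
        """Spot centre positions (µm) along the channel, pattern centred on W."""
        w = self.geometry.mmi_width
        j = np.arange(self.n_spots)
        return w / 2 + (j - (self.n_spots - 1) / 2) * self.spacing


def arrival_rate(params: SimulationParams) -> float:
    """Expected particle arrival rate r = C·v_mean·A in events/s."""
    c_per_um3 = params.concentration / UM3_PER_ML
    return c_per_um3 * params.velocity_mean * params.geometry.channel_cross_section


@dataclass
class TransitRecord:
    """Ground truth for one particle transit (simulation bookkeeping)."""

    entry_time: float        # s, particle reaches position 0 of the MMI width
    velocity: float          # µm/s
    photon_count: int = 0    # filled in by generate_photon_stream
    brightness: float = 1.0  # per-transit intensity scale in (0, 1]


@dataclass(frozen=True)
class PhotonStream:
    """Ordered photon arrival timetags.

    ``timestamps`` are integer multiples of ``resolution`` (ticks);
    use :meth:`times_s` for seconds.
    """

    timestamps: np.ndarray   # int64 ticks, non-decreasing
    resolution: float        # s per tick
    duration: float          # s

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        object.__setattr__(self, "timestamps", ts)
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if ts.size and (ts[0] < 0 or ts[-1] * self.resolution > self.duration):
            raise ValueError("timestamps outside [0, duration]")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def times_s(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.timestamps * self.resolution


def sample_transits(params: SimulationParams,
                    rng: np.random.Generator | None = None) -> list[TransitRecord]:
    """Draw particle transits as a homogeneous Poisson process.

    Entry times are the cumulative sum of Exponential(r) inter-arrival
    times with ``r = C·v_mean·A``; velocities are normal with the given
    mean and CV, resampled when non-positive.
    """
    rate = arrival_rate(params)
    if rate * params.duration > MAX_EXPECTED_TRANSITS:
        raise ValueError(
            f"expected transit count {rate * params.duration:.3g} exceeds "
            f"{MAX_EXPECTED_TRANSITS:.0g}; reduce concentration or duration")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if rate == 0 or params.duration == 0:
        return []

    entries: list[float] = []
    t = 0.0
    # draw in chunks until past the duration
    chunk = max(16, int(rate * params.duration * 1.5) + 16)
    while True:
        gaps = rng.exponential(1.0 / rate, size=chunk)
        for g in gaps:
            t += g
            if t >= params.duration:
                break
            entries.append(t)
        if t >= params.duration:
            break

    transits = []
    for entry in entries:
        v = params.velocity_mean
        if params.velocity_cv > 0:
            sd = params.velocity_cv * params.velocity_mean
            v = rng.normal(params.velocity_mean, sd)
            while v <= 0:
                v = rng.normal(params.velocity_mean, sd)
        b = 1.0
        if params.brightness_min < 1.0:
            b = rng.uniform(params.brightness_min, 1.0)
        transits.append(TransitRecord(entry, v, 0, b))
    return transits


def emission_rate(transit: TransitRecord, params: SimulationParams,
                  t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous fluorescence photon rate (counts/s) of one transit.

    Sum of N unit-peak Gaussians centred at the times the particle
    crosses each spot, scaled by ``peak_photon_rate`` and the transit's
    brightness. Background is not included.
    """
    t = np.asarray(t, dtype=float)
    sigma_t = params.fwhm * FWHM_TO_SIGMA / transit.velocity
    centers = transit.entry_time + params.spot_positions / transit.velocity
    rate = np.zeros_like(t, dtype=float)
    for tc in centers:
        rate += np.exp(-0.5 * ((t - tc) / sigma_t) ** 2)
    rate *= params.peak_photon_rate * transit.brightness
    return rate if rate.ndim else float(rate)


def generate_photon_stream(transits: Sequence[TransitRecord],
                           params: SimulationParams,
                           rng: np.random.Generator | None = None) -> PhotonStream:
    """Draw the photon timetag stream for the given transits plus background.

    Each transit's ``photon_count`` is updated in place with the number
    of signal photons it contributed within [0, duration).
    """
    if rng is None:
        # distinct stream from sample_transits for the same seed
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    times = []
    n_bg = rng.poisson(params.background_rate * params.duration)
    if n_bg:
        times.append(rng.uniform(0.0, params.duration, size=n_bg))

    for tr in transits:
        sigma_t = params.fwhm * FWHM_TO_SIGMA / tr.velocity
        centers = tr.entry_time + params.spot_positions / tr.velocity
        # expected photons per spot: rate * integral of the unit Gaussian
        mu = params.peak_photon_rate * tr.brightness * sigma_t * np.sqrt(2 * np.pi)
        total = 0
        for tc in centers:
            n = rng.poisson(mu)
            if n == 0:
                continue
            tt = rng.normal(tc, sigma_t, size=n)
            tt = tt[(tt >= 0.0) & (tt < params.duration)]
            total += tt.size
            if tt.size:
                times.append(tt)
        tr.photon_count = total

    if times:
        all_times = np.concatenate(times)
    else:
        all_times = np.empty(0)
    ticks = np.rint(all_times / params.timestamp_resolution).astype(np.int64)
    max_tick = int(np.floor(params.duration / params.timestamp_resolution))
    ticks = np.clip(ticks, 0, max_tick)
    ticks.sort()
    return PhotonStream(ticks, params.timestamp_resolution, params.duration)


def simulate(params: SimulationParams) -> tuple[list[TransitRecord], PhotonStream]:
    """Run a full simulation: sample transits, then their photon stream.

    All randomness derives from ``params.seed``; equal parameters give
    bit-identical output.
    """
    transits = sample_transits(params)
    stream = generate_photon_stream(transits, params)
    return transits, stream
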