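"""File formats, configuration, and the live per-event display stream.

Formats
-------
* Photon timetag CSV: one integer tick per line after two header lines
  ``# resolution_ns=...`` and ``# duration_s=...``.
* Photon timetag binary: 32-byte header (8-byte magic ``MMIFLOW1``,
  float64 resolution in ns, float64 duration in s, 8 reserved bytes)
  followed by little-endian uint64 ticks.
* Binned trace CSV: columns ``bin_start_s, count``.
* Events CSV: ``index, t_s, dt_ms, n_peaks`` then per-peak triplets
  ``peak{k}_t_s, peak{k}_w_ms, peak{k}_h``.
* Reports: JSON.

Display records emulate the per-event line a live instrument prints
over a serial link: either a fixed 25-character human-readable line or
a compact fixed-width base-64 line that decodes exactly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FlowGeometry, mmi_spot_count
from .realtime_detector import ClusterEvent, DetectorConfig, PeakRecord
from .simulator import PhotonStream, SimulationParams
from .acquisition import BinnedTrace

__all__ = [
    "DisplayRecord", "emit_display", "decode_display", "uart_line_time",
    "write_photon_csv", "read_photon_csv",
    "write_photon_binary", "read_photon_binary",
    "write_trace_csv", "read_trace_csv",
    "write_events_csv", "read_events_csv",
    "write_report", "read_report",
    "RunConfig", "load_config", "save_config", "default_config",
]

_MAGIC = b"MMIFLOW1"
_B64_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                 "abcdefghijklmnopqrstuvwxyz0123456789+/")
_B64_INDEX = {c: i for i, c in enumerate(_B64_ALPHABET)}

# (field width in chars, unit scale) of the packed display line
_B64_FIELDS = (("event_number", 3, 1.0),        # plain count
               ("detection_time_tag", 6, 1e3),  # s -> ms
               ("cluster_duration", 4, 1e5),    # s -> 10 µs units
               ("cumulative_mean_concentration", 8, 1.0))  # particles/mL


# ---------------------------------------------------------------- display

@dataclass(frozen=True)
class DisplayRecord:
    """The four live-display variables reported per detection event."""

    event_number: int
    detection_time_tag: float             # s
    cluster_duration: float               # s
    cumulative_mean_concentration: float  # particles/mL


def uart_line_time(n_chars: int, baud: float, bits_per_char: int = 10) -> float:
    """Serial transfer time (s) of one line: n_chars * bits_per_char / baud.

    The default 10 bits per character is standard 8N1 framing (start
    bit, 8 data bits, stop bit).
    """
    if n_chars <= 0 or baud <= 0 or bits_per_char <= 0:
        raise ValueError("all arguments must be positive")
    return n_chars * bits_per_char / baud


def _b64_encode_int(value: int, width: int) -> str:
    if value < 0 or value >= 64 ** width:
        raise OverflowError(f"value {value} does not fit in {width} base-64 chars")
    out = []
    for _ in range(width):
        out.append(_B64_ALPHABET[value % 64])
        value //= 64
    return "".join(reversed(out))


def _b64_decode_int(text: str) -> int:
    value = 0
    for c in text:
        value = value * 64 + _B64_INDEX[c]
    return value


def emit_display(record: DisplayRecord, encoding: str = "plain") -> str:
    """Format one display record as a newline-terminated line.

    ``plain`` is a fixed 25-character human-readable line (terminator
    included); ``b64`` packs each field as a fixed-width big-endian
    unsigned integer over the RFC 4648 alphabet (event number, time tag
    in ms, duration in 10 µs units, concentration in particles/mL) and
    decodes exactly via :func:`decode_display`.
    """
    if encoding == "plain":
        if not 0 <= record.event_number <= 999:
            raise OverflowError("event number does not fit in 3 characters")
        if record.detection_time_tag >= 1e5:
            raise OverflowError("time tag does not fit in 8 characters")
        if record.cluster_duration * 1e3 >= 100:
            raise OverflowError("duration does not fit in 5 characters")
        conc = record.cumulative_mean_concentration
        if conc >= 9.5e98:
            raise OverflowError("concentration does not fit in 5 characters")
        if conc < 1e-9:  # below any physical concentration; 3-digit
            conc = 0.0   # exponents would break the fixed width
        line = (f"{record.event_number:3d} "
                f"{record.detection_time_tag:8.2f} "
                f"{record.cluster_duration * 1e3:5.1f} "
                f"{conc:5.0e}\n")
        assert len(line) == 25
        return line
    if encoding == "b64":
        parts = []
        for name, width, scale in _B64_FIELDS:
            raw = getattr(record, name)
            parts.append(_b64_encode_int(int(round(raw * scale)), width))
        return "".join(parts) + "\n"
    raise ValueError(f"unknown encoding {encoding!r}")


def decode_display(line: str, encoding: str = "b64") -> DisplayRecord:
    """Decode a display line back into a record (exact for ``b64``)."""
    line = line.rstrip("\n")
    if encoding == "b64":
        pos = 0
        values = {}
        for name, width, scale in _B64_FIELDS:
            values[name] = _b64_decode_int(line[pos:pos + width]) / scale
            pos += width
        return DisplayRecord(event_number=int(values["event_number"]),
                             detection_time_tag=values["detection_time_tag"],
                             cluster_duration=values["cluster_duration"],
                             cumulative_mean_concentration=values[
                                 "cumulative_mean_concentration"])
    if encoding == "plain":
        n, t, dt_ms, conc = line.split()
        return DisplayRecord(int(n), float(t), float(dt_ms) * 1e-3, float(conc))
    raise ValueError(f"unknown encoding {encoding!r}")


# ---------------------------------------------------------------- photon IO

def write_photon_csv(stream: PhotonStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resolution_ns={stream.resolution * 1e9:.17g}\n")
        fh.write(f"# duration_s={stream.duration:.17g}\n")
        for t in stream.timestamps:
            fh.write(f"{int(t)}\n")


def read_photon_csv(path: str | Path) -> PhotonStream:
    resolution_ns = duration_s = None
    ticks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key == "resolution_ns":
                    resolution_ns = float(val)
                elif key == "duration_s":
                    duration_s = float(val)
                continue
            try:
                ticks.append(int(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp {line!r}") from exc
    if resolution_ns is None or duration_s is None:
        raise ValueError(f"{path}: missing resolution_ns/duration_s header")
    return PhotonStream(np.asarray(ticks, dtype=np.int64),
                        resolution_ns * 1e-9, duration_s)


def write_photon_binary(stream: PhotonStream, path: str | Path) -> None:
    header = _MAGIC + struct.pack("<dd", stream.resolution * 1e9,
                                  stream.duration)
    header += b"\x00" * (32 - len(header))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(stream.timestamps.astype("<u8").tobytes())


def read_photon_binary(path: str | Path) -> PhotonStream:
    with open(path, "rb") as fh:
        header = fh.read(32)
        if len(header) < 32 or header[:8] != _MAGIC:
            raise ValueError(f"{path}: not a mmiflow photon binary")
        resolution_ns, duration_s = struct.unpack("<dd", header[8:24])
        ticks = np.frombuffer(fh.read(), dtype="<u8").astype(np.int64)
    return PhotonStream(ticks, resolution_ns * 1e-9, duration_s)


# ---------------------------------------------------------------- tables

def write_trace_csv(trace: BinnedTrace, path: str | Path) -> None:
    pd.DataFrame({"bin_start_s": trace.bin_edges(),
                  "count": trace.counts}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> BinnedTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["bin_start_s", "count"]:
        raise ValueError(f"{path}: expected columns bin_start_s,count")
    edges = df["bin_start_s"].to_numpy()
    if edges.size < 2:
        raise ValueError(f"{path}: need >= 2 bins to infer the bin width")
    bin_width = float(np.median(np.diff(edges)))
    return BinnedTrace(df["count"].to_numpy(dtype=np.int64), bin_width,
                       float(edges[0]))


def write_events_csv(events: list[ClusterEvent], path: str | Path) -> None:
    max_peaks = max((e.n_peaks for e in events), default=0)
    rows = []
    for e in events:
        row: dict[str, object] = {"index": e.index,
                                  "t_s": e.detection_time_tag,
                                  "dt_ms": e.cluster_width * 1e3,
                                  "n_peaks": e.n_peaks}
        for k in range(max_peaks):
            if k < e.n_peaks:
                p = e.peaks[k]
                row[f"peak{k + 1}_t_s"] = p.peak_time
                row[f"peak{k + 1}_w_ms"] = p.width * 1e3
                row[f"peak{k + 1}_h"] = p.height
            else:
                row[f"peak{k + 1}_t_s"] = np.nan
                row[f"peak{k + 1}_w_ms"] = np.nan
                row[f"peak{k + 1}_h"] = np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[ClusterEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        peaks = []
        for k in range(1, int(row["n_peaks"]) + 1):
            peaks.append(PeakRecord(peak_time=float(row[f"peak{k}_t_s"]),
                                    width=float(row[f"peak{k}_w_ms"]) * 1e-3,
                                    height=float(row[f"peak{k}_h"])))
        events.append(ClusterEvent(index=int(row["index"]),
                                   detection_time_tag=float(row["t_s"]),
                                   cluster_width=float(row["dt_ms"]) * 1e-3,
                                   peaks=peaks))
    return events


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------- config

_GEOMETRY_KEYS = {"wavelength_nm", "mmi_width_um", "mmi_length_um",
                  "core_index", "channel_width_um", "channel_height_um"}
_SIMULATION_KEYS = {"concentration_per_ml", "velocity_um_s", "velocity_cv",
                    "spot_fwhm_um", "spot_spacing_um", "peak_rate_per_s",
                    "background_rate_per_s", "duration_s",
                    "resolution_ns", "brightness_min"}
_DETECTOR_KEYS = {"bin_us", "background_level", "start_threshold",
                  "end_threshold", "diff_threshold", "wait_ms",
                  "max_cluster_ms", "auto_threshold", "k_sigma",
                  "subtract_background"}
_ANALYSIS_KEYS = {"window", "hist_bin_s", "tolerance_ms", "rate_window_s",
                  "span_correction"}
_IO_KEYS = {"seed", "stream_format"}


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration (geometry/simulation/detector/
    analysis/io blocks of the YAML file)."""

    geometry: dict
    simulation: dict
    detector: dict
    analysis: dict
    io: dict

    def flow_geometry(self) -> FlowGeometry:
        g = self.geometry
        return FlowGeometry(
            channel_cross_section=g["channel_width_um"] * g["channel_height_um"],
            mmi_width=g["mmi_width_um"])

    def n_spots(self) -> int:
        g = self.geometry
        return mmi_spot_count(g["wavelength_nm"] * 1e-3, g["mmi_width_um"],
                              g["mmi_length_um"], g["core_index"])

    def simulation_params(self, seed: int | None = None) -> SimulationParams:
        s = self.simulation
        return SimulationParams(
            concentration=s["concentration_per_ml"],
            velocity_mean=s["velocity_um_s"],
            geometry=self.flow_geometry(),
            velocity_cv=s.get("velocity_cv", 0.0),
            n_spots=self.n_spots(),
            spot_spacing=s.get("spot_spacing_um"),
            spot_fwhm=s.get("spot_fwhm_um"),
            peak_photon_rate=s.get("peak_rate_per_s", 5e5),
            background_rate=s.get("background_rate_per_s", 1e3),
            duration=s.get("duration_s", 60.0),
            timestamp_resolution=s.get("resolution_ns", 100.0) * 1e-9,
            brightness_min=s.get("brightness_min", 1.0),
            seed=seed if seed is not None else self.io.get("seed", 0))

    def detector_config(self) -> DetectorConfig:
        d = self.detector
        return DetectorConfig(
            bin_width=d.get("bin_us", 100.0) * 1e-6,
            background_level=d.get("background_level", 0.0),
            start_threshold=d.get("start_threshold", 10.0),
            end_threshold=d.get("end_threshold", 5.0),
            diff_threshold=d.get("diff_threshold", 0.0),
            wait_time=d.get("wait_ms", 1.0) * 1e-3,
            max_cluster_width=d.get("max_cluster_ms", 500.0) * 1e-3,
            subtract_background=d.get("subtract_background", False))


def _check_block(name: str, block: dict, allowed: set[str]) -> None:
    if not isinstance(block, dict):
        raise ValueError(f"config block {name!r} must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: "
                         f"{sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate_config(raw, str(path))


def _validate_config(raw: object, origin: str = "<config>") -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError(f"{origin}: config must be a mapping")
    blocks = {"geometry": _GEOMETRY_KEYS, "simulation": _SIMULATION_KEYS,
              "detector": _DETECTOR_KEYS, "analysis": _ANALYSIS_KEYS,
              "io": _IO_KEYS}
    unknown = set(raw) - set(blocks)
    if unknown:
        raise ValueError(f"{origin}: unknown config blocks {sorted(unknown)}")
    merged = {}
    defaults = default_config()
    for name, allowed in blocks.items():
        block = dict(getattr(defaults, name))
        user = raw.get(name, {}) or {}
        _check_block(name, user, allowed)
        block.update(user)
        merged[name] = block
    cfg = RunConfig(**merged)
    # touch the constructors so invariants are validated at load time
    cfg.flow_geometry()
    cfg.detector_config()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {name: dict(getattr(config, name))
            for name in ("geometry", "simulation", "detector", "analysis", "io")}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def default_config() -> RunConfig:
    """The reference device and acquisition settings.

    633 nm excitation, 75 µm wide MMI crossing the 5 × 12 µm channel at
    1975 µm (7 spots), 100 µs bins, 1 ms wait time.
    """
    return RunConfig(
        geometry={"wavelength_nm": 633.0, "mmi_width_um": 75.0,
                  "mmi_length_um": 1975.0, "core_index": 1.51,
                  "channel_width_um": 12.0, "channel_height_um": 5.0},
        simulation={"concentration_per_ml": 3.4e6, "velocity_um_s": 7500.0,
                    "velocity_cv": 0.0, "peak_rate_per_s": 5e5,
                    "background_rate_per_s": 1e3, "duration_s": 60.0,
                    "resolution_ns": 100.0, "brightness_min": 1.0},
        detector={"bin_us": 100.0, "background_level": 0.0,
                  "start_threshold": 10.0, "end_threshold": 5.0,
                  "diff_threshold": 0.0, "wait_ms": 1.0,
                  "max_cluster_ms": 500.0, "auto_threshold": False,
                  "k_sigma": 5.0, "subtract_background": False},
        analysis={"window": 0.05, "hist_bin_s": 0.1, "tolerance_ms": 50.0,
                  "rate_window_s": 5.0, "span_correction": 1.0},
        io={"seed": 0, "stream_format": "csv"})
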