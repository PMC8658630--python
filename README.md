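# mmiflow

Real-time single-particle fluorescence flow analysis for optofluidic
biosensors, in software.

In an optofluidic chip, fluorescently labeled particles (nanobeads,
stained plasmid DNA) flow through a liquid-core waveguide channel and
cross the excitation pattern of a multimode-interference (MMI)
waveguide. Self-imaging in an MMI of width *W* and core index *n*
crossing the channel at distance *L* produces

&nbsp;&nbsp;&nbsp;&nbsp;*N* = *nW*² / (*λL*)

excitation spots, so each particle transit emits a characteristic
*N*-peak burst. `mmiflow` implements the full live analysis chain a
hardware (FPGA-class) instrument runs on the photon stream, plus the
simulator and offline reference needed to validate it:

- **simulator** — photon timetag streams for Poisson particle arrivals
  at rate *r* = *C·v·A* crossing the *N*-spot pattern, with Poisson
  photon emission over uniform background;
- **acquisition** — single-pass binning of timetags into fixed-width
  (default 100 µs) count traces;
- **realtime_detector** — a three-state streaming finite-state machine
  (baseline / in-peak / gap) that detects multi-peak clusters with
  O(1) state: level and consecutive-difference start triggers, per-peak
  width/height, and a wait-time (default 1 ms) cluster-end
  confirmation. Each event *i* carries its detection time tag *t*(*i*)
  and cluster width Δ*t*(*i*);
- **flow_analysis** — per-event velocity *v*(*i*) = *W*/Δ*t*(*i*),
  instantaneous concentration *c*ᵢ(*i*) = *i*/(*v*(*i*)·*A*·*t*(*i*)),
  the cumulative mean *C*(*i*), its step deviation
  (*C*(*i*)−*C*(*i*−1))/*C*(*i*), the ±5 % settling point (*t*ₛ, *M*),
  detection-rate and exponential inter-arrival statistics, and
  number-density ↔ molarity conversion;
- **comparator** — a transparent two-pass threshold-run-merge detector
  and greedy one-to-one event matching, for streaming-vs-offline
  accuracy and timing-error statistics;
- **io / cli** — timetag CSV and binary dialects, trace/event tables,
  YAML configuration, and the fixed-width live display line (25
  characters plain, or a compact base-64 encoding) with its serial
  transfer-time model.

## Worked example

```sh
$ mmiflow demo --seed 1 --out-dir demo
simulated 83 transits -> detected 82 events
C_final = 2.919e+06 /mL (true 3.4e+06 /mL), M = 5
```

The demo simulates 60 s at 3.4×10⁶ particles/mL flowing at
7500 µm/s through a 5 × 12 µm channel (arrival rate
*C·v·A* ≈ 1.5 /s), bins the photons at 100 µs, runs the streaming
detector, and estimates the concentration. Here 82 of 83 transits are
detected (one coincident pair merges into a single event), and the
final cumulative mean is 2.9×10⁶ /mL — slightly below the true value
because the plain *v* = *W*/Δ*t* convention overestimates velocity by
the ratio of the MMI width to the narrower above-threshold span of the
spot pattern (see `pattern_span_correction`). `M = 5` means the running
estimate stayed inside its ±5 % settling window from the 5th event on
(`t_s ≈ 4.7 s`). The files written to `demo/` contain the photon
stream, the binned trace, the per-event table and the summary JSON.

The same steps are available separately (`mmiflow simulate`, `bin`,
`detect [--live]`, `analyze`, `compare`) and as library functions.

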