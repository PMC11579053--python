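"""Data model and I/O for CO2 rebreathing experiments.

A recording consists of a raw 50 Hz capnogram (% CO2 in breathed air) and
breathlessness ratings given every 10 s on a 0-100 visual analog scale.
The raw trace is reduced to end-tidal CO2 per breath (the maximum exhaled
concentration in each breath) and averaged over 10 s bins, yielding the
per-bin series the perceptual model consumes.

CSV dialects (UTF-8, header row, "." decimal separator):

* trace files: ``time_s,phase,etco2_pct,rating`` — ``rating`` may be empty
  for bins without a response;
* capnogram files: ``time_s,co2_pct``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "Protocol",
    "Capnogram",
    "BreathSeries",
    "ExperimentTrace",
    "segment_breaths",
    "bin_to_grid",
    "read_trace",
    "write_trace",
    "read_capnogram",
    "write_capnogram",
]

PHASES = ("baseline", "rebreathing", "recovery")

CO2_MAX_PCT = 15.0  # physiologic guard on % CO2 in breathed air


@dataclass(frozen=True)
class Protocol:
    """Timing of the rebreathing paradigm.

    Defaults: 60 s room-air baseline, 150 s rebreathing from a closed bag
    (initially 5% CO2 / 95% O2), 150 s room-air recovery; ratings and CO2
    binning on a 10 s grid; raw capnogram at 50 Hz.
    """

    baseline_s: float = 60.0
    rebreathing_s: float = 150.0
    recovery_s: float = 150.0
    bin_s: float = 10.0
    sample_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "rebreathing_s", "recovery_s", "bin_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        for name in ("baseline_s", "rebreathing_s", "recovery_s"):
            ratio = getattr(self, name) / self.bin_s
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"{name} must be an integer multiple of bin_s"
                )

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.rebreathing_s + self.recovery_s

    @property
    def n_bins(self) -> int:
        return int(round(self.total_s / self.bin_s))

    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1, dtype=float) * self.bin_s

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins, dtype=float) + 0.5) * self.bin_s

    def phase_labels(self) -> np.ndarray:
        """Phase of each bin, by bin start time (bins are [start, end))."""
        starts = np.arange(self.n_bins, dtype=float) * self.bin_s
        labels = np.where(
            starts < self.baseline_s,
            PHASES[0],
            np.where(
                starts < self.baseline_s + self.rebreathing_s,
                PHASES[1],
                PHASES[2],
            ),
        )
        return labels.astype(object)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Protocol":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class Capnogram:
    """Uniformly sampled raw CO2 trace (% CO2 vs seconds)."""

    time: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if self.time.shape != self.co2.shape or self.time.ndim != 1:
            raise ValueError("time and co2 must be 1-D arrays of equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform sampling in capnogram")
        if np.any(self.co2 < 0) or np.any(self.co2 > CO2_MAX_PCT):
            raise ValueError(f"co2 must lie within [0, {CO2_MAX_PCT}] %")

    @property
    def sample_rate_hz(self) -> float:
        if self.time.size < 2:
            raise ValueError("need >= 2 samples to infer a sample rate")
        return 1.0 / float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass
class BreathSeries:
    """End-tidal CO2 per detected breath."""

    breath_end_time: np.ndarray
    etco2: np.ndarray

    def __post_init__(self) -> None:
        self.breath_end_time = np.asarray(self.breath_end_time, dtype=float)
        self.etco2 = np.asarray(self.etco2, dtype=float)
        if self.breath_end_time.shape != self.etco2.shape:
            raise ValueError("breath_end_time and etco2 lengths differ")
        if np.any(np.diff(self.breath_end_time) <= 0):
            raise ValueError("breath_end_time must be strictly increasing")

    def __len__(self) -> int:
        return self.etco2.size


@dataclass
class ExperimentTrace:
    """Per-bin observables for one participant on the 10 s grid.

    ``rating`` uses NaN for bins without a response; ratings are real
    numbers in [0, 100] (visual analog scale, not forced to integers).
    """

    t: np.ndarray
    phase: np.ndarray
    etco2: np.ndarray
    rating: np.ndarray
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.etco2 = np.asarray(self.etco2, dtype=float)
        self.rating = np.asarray(self.rating, dtype=float)
        n = self.t.size
        for name in ("phase", "etco2", "rating"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length differs from t")
        if n != self.protocol.n_bins:
            raise ValueError(
                f"trace has {n} bins, protocol implies {self.protocol.n_bins}"
            )
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        obs = self.rating[np.isfinite(self.rating)]
        if np.any(obs < 0) or np.any(obs > 100):
            raise ValueError("ratings must lie within [0, 100]")

    def __len__(self) -> int:
        return self.t.size

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of bins with a rating."""
        return np.isfinite(self.rating)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "phase": self.phase,
                "etco2_pct": self.etco2,
                "rating": self.rating,
            }
        )


def segment_breaths(
    cap: Capnogram,
    trough_frac: float = 0.5,
    min_amplitude: float = 1.0,
    hysteresis: float = 0.3,
) -> BreathSeries:
    """Split a capnogram into breaths and extract end-tidal CO2.

    A breath ends where the signal falls below ``trough_frac`` times the
    running peak of the current cycle (the inspiratory trough); its
    end-tidal value is the maximum CO2 within the cycle.  Two guards make
    the rule noise-tolerant: a cycle only counts once its peak reaches
    ``min_amplitude`` (% CO2; sensor noise around the trough is far below
    any physiologic end-tidal level), and after a crossing the next cycle
    is only armed when the signal has risen ``hysteresis`` (% CO2) above
    the running trough, so jitter on the falling flank is not mistaken for
    a new breath.
    """
    if not 0.0 < trough_frac < 1.0:
        raise ValueError(f"trough_frac must be in (0, 1), got {trough_frac}")
    co2, t = cap.co2, cap.time
    n = co2.size
    ends: list[float] = []
    vals: list[float] = []
    seg_start = 0
    peak = co2[0] if n else 0.0
    falling = False
    trough = np.inf
    trough_idx = 0
    for i in range(1, n):
        v = co2[i]
        if falling:
            if v < trough:
                trough = v
                trough_idx = i
            elif v > trough + hysteresis:  # trough passed: new cycle
                seg_start = trough_idx
                peak = v
                falling = False
            continue
        if v > peak:
            peak = v
        if peak >= min_amplitude and v < trough_frac * peak:
            vals.append(float(np.max(co2[seg_start : i + 1])))
            ends.append(float(t[i]))
            falling = True
            trough = v
            trough_idx = i
    if not vals:
        raise ValueError("no breaths detected (signal flat or single ramp)")
    return BreathSeries(
        breath_end_time=np.array(ends), etco2=np.array(vals)
    )


def bin_to_grid(breaths: BreathSeries, protocol: Protocol) -> np.ndarray:
    """Average per-breath end-tidal CO2 over the protocol's 10 s bins.

    Each bin takes the arithmetic mean of breaths whose end time falls in
    [bin_start, bin_end); a bin without any breath inherits the previous
    bin's value.  The first bin must contain at least one breath.
    """
    if len(breaths) == 0:
        raise ValueError("breath series is empty")
    tmax = breaths.breath_end_time.max()
    if breaths.breath_end_time.min() < 0 or tmax >= protocol.total_s:
        raise ValueError("breath times fall outside the protocol span")
    idx = np.floor(breaths.breath_end_time / protocol.bin_s).astype(int)
    n = protocol.n_bins
    sums = np.bincount(idx, weights=breaths.etco2, minlength=n)
    counts = np.bincount(idx, minlength=n)
    if counts[0] == 0:
        raise ValueError("cannot initialize grid: first bin has no breath")
    out = np.empty(n, dtype=float)
    prev = np.nan
    for b in range(n):
        prev = sums[b] / counts[b] if counts[b] else prev
        out[b] = prev
    return out


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")


def read_trace(path, protocol: Protocol | None = None) -> ExperimentTrace:
    """Read a per-bin trace CSV (``time_s,phase,etco2_pct,rating``).

    ``phase`` and ``rating`` are optional; missing phases are derived from
    the protocol, missing ratings become NaN.
    """
    protocol = protocol or Protocol()
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_s", "etco2_pct"), path)
    n = len(df)
    phase = (
        df["phase"].to_numpy(dtype=object)
        if "phase" in df.columns
        else protocol.phase_labels()
    )
    rating = (
        df["rating"].to_numpy(dtype=float)
        if "rating" in df.columns
        else np.full(n, np.nan)
    )
    return ExperimentTrace(
        t=df["time_s"].to_numpy(dtype=float),
        phase=phase,
        etco2=df["etco2_pct"].to_numpy(dtype=float),
        rating=rating,
        protocol=protocol,
    )


def write_trace(trace: ExperimentTrace, path) -> None:
    """Write a trace CSV; NaN ratings are written as empty fields.

    Floats use 17 significant digits so write -> read round-trips
    bit-exactly.
    """
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_capnogram(path) -> Capnogram:
    """Read a raw capnogram CSV (``time_s,co2_pct``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_s", "co2_pct"), path)
    return Capnogram(
        time=df["time_s"].to_numpy(dtype=float),
        co2=df["co2_pct"].to_numpy(dtype=float),
    )


def write_capnogram(cap: Capnogram, path) -> None:
    pd.DataFrame({"time_s": cap.time, "co2_pct": cap.co2}).to_csv(
        path, index=False, float_format="%.17g"
    )
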