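"""Synthetic gait kinematics: elevation-angle trials with gait-like spectral structure.

Generates six-channel sagittal elevation-angle waveforms (left/right x
thigh/shank/foot) whose spectra are dominated by the first three harmonics of a
stride fundamental, whose fundamental frequency and harmonic amplitudes grow
with walking speed, whose right-side channels trail the left by half a cycle,
and whose thigh-shank-foot phase lags trace the elliptic, near-planar
covariation loop characteristic of human walking.  Trials stand in for
treadmill motion-capture recordings in all downstream analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

SEGMENTS = ("thigh", "shank", "foot")
SIDES = ("left", "right")
#: canonical channel order, also the CSV column order after ``time_s``
CHANNELS = tuple(f"{side}_{seg}" for side in SIDES for seg in SEGMENTS)

# Stride fundamental: linear in treadmill velocity, 0.6 Hz at 1 km/h -> 1.0 Hz
# at 6 km/h (plausible human stride rates; slope 0.08 Hz per km/h).
_F1_AT_1KMH = 0.6
_F1_SLOPE = 0.08

# Harmonic peak amplitudes (degrees) per segment at the 3 km/h reference
# velocity, and their fractional growth per km/h.  Third-harmonic content is
# kept small enough that harmonics 1-2 carry >= 98 % of the variance.
_AMP_REF = {
    "thigh": (21.0, 1.8, 0.6),
    "shank": (27.0, 5.5, 1.1),
    "foot": (24.0, 8.0, 1.6),
}
_AMP_SLOPE = 0.06  # per km/h, relative to the 3 km/h reference

# Harmonic phase offsets (rad) per segment.  First-harmonic lags
# thigh -> shank -> foot of (0, -0.9, -1.5) rad with a common second-harmonic
# phase keep the thigh/shank/foot loop planar (>= 98 % of variance in the
# first two principal components) while remaining an open ellipse.
_PHASES = {
    "thigh": (0.0, -1.2, 0.8),
    "shank": (-0.9, -1.2, 0.5),
    "foot": (-1.5, -1.2, 0.2),
}


def default_fundamental_map(velocity_kmh: float) -> float:
    """Stride fundamental f1 (Hz) as a strictly increasing function of speed."""
    return _F1_AT_1KMH + _F1_SLOPE * (velocity_kmh - 1.0)


def default_amplitude_map(velocity_kmh: float) -> dict[str, tuple[float, float, float]]:
    """Per-segment harmonic amplitudes (degrees), non-decreasing in speed."""
    gain = 1.0 + _AMP_SLOPE * (velocity_kmh - 3.0)
    return {seg: tuple(a * gain for a in _AMP_REF[seg]) for seg in SEGMENTS}


@dataclass(frozen=True)
class GaitGenConfig:
    """Parameters of one synthetic treadmill trial.

    ``fundamental_map`` maps velocity (km/h) to the stride fundamental f1 (Hz)
    and must be strictly increasing; ``amplitude_map`` maps velocity to the
    three harmonic amplitudes (degrees) of each segment.  ``left_right_shift``
    is the right-side delay as a fraction of one cycle.  ``cycle_jitter`` is
    the standard deviation of the per-cycle fractional period perturbation and
    ``noise_sd`` the standard deviation (degrees) of additive white noise.
    """

    velocity_kmh: float = 3.0
    duration_s: float = 40.0
    sample_rate_hz: float = 100.0
    fundamental_map: Callable[[float], float] = default_fundamental_map
    amplitude_map: Callable[[float], Mapping[str, tuple[float, float, float]]] = (
        default_amplitude_map
    )
    segment_phases: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_PHASES)
    )
    left_right_shift: float = 0.5
    noise_sd: float = 0.5
    cycle_jitter: float = 0.02
    seed: int | None = None


@dataclass
class ElevationSeries:
    """Six-channel uniformly sampled elevation-angle waveforms (degrees)."""

    time: np.ndarray
    data: np.ndarray  # (n_samples, 6), columns in CHANNELS order
    sample_rate: float
    velocity_kmh: float
    meta: dict = field(default_factory=dict)
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise InvalidConfigError("ElevationSeries requires exactly 6 channels")
        if self.data.shape[0] != self.time.shape[0]:
            raise InvalidConfigError("time and data lengths differ")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("non-finite elevation angles")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, columns=list(self.channels))
        frame.insert(0, "time_s", self.time)
        return frame


def _validate(config: GaitGenConfig) -> tuple[float, dict, int]:
    if config.duration_s <= 0 or config.sample_rate_hz <= 0:
        raise InvalidConfigError("duration and sample rate must be positive")
    if not 0.0 <= config.left_right_shift < 1.0:
        raise InvalidConfigError("left_right_shift must lie in [0, 1)")
    if config.noise_sd < 0 or config.cycle_jitter < 0:
        raise InvalidConfigError("noise_sd and cycle_jitter must be non-negative")
    f1 = float(config.fundamental_map(config.velocity_kmh))
    if f1 <= 0:
        raise InvalidConfigError("fundamental frequency must be positive")
    if config.duration_s * f1 < 2.0:
        raise InvalidConfigError("trial must span at least two gait cycles")
    if config.sample_rate_hz < 20.0 * 3.0 * f1:
        raise InvalidConfigError(
            "sample rate below 20x the third harmonic; raise sample_rate_hz"
        )
    amps = dict(config.amplitude_map(config.velocity_kmh))
    for seg in SEGMENTS:
        a = np.asarray(amps[seg], dtype=float)
        if a.shape != (3,) or np.any(a < 0):
            raise InvalidConfigError(f"amplitude_map must give 3 non-negative values for {seg}")
        if a[0] == 0 and a[1] == 0:
            raise InvalidConfigError(f"segment {seg} has no first/second harmonic content")
        if (a[0] ** 2 + a[1] ** 2) / max((a**2).sum(), 1e-300) < 0.98:
            raise InvalidConfigError(
                f"third harmonic of {seg} too large: harmonics 1-2 must carry >= 98 % variance"
            )
    n = int(round(config.duration_s * config.sample_rate_hz))
    return f1, amps, n


def _cycle_phase(config: GaitGenConfig, f1: float, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stride phase (rad).  With jitter, each cycle's period is perturbed by an
    i.i.d. factor (1 + eps), eps ~ N(0, cycle_jitter), and the phase is the
    piecewise-linear interpolant through the perturbed cycle boundaries."""
    if config.cycle_jitter == 0.0:
        return 2.0 * np.pi * f1 * t
    period = 1.0 / f1
    bounds = [0.0]
    while bounds[-1] < t[-1] + 2.0 * period:
        eps = rng.normal(0.0, config.cycle_jitter)
        bounds.append(bounds[-1] + period * max(1.0 + eps, 0.2))
    bounds = np.asarray(bounds)
    phase_at_bounds = 2.0 * np.pi * np.arange(len(bounds))
    return np.interp(t, bounds, phase_at_bounds)


def generate_trial(config: GaitGenConfig) -> ElevationSeries:
    """Generate one synthetic treadmill trial.

    Each left-side channel is a three-harmonic series
    ``theta(t) = sum_k A_k sin(k*phi(t) + phi_k) + noise`` with stride phase
    ``phi(t) = 2*pi*f1*t`` (optionally cycle-jittered); right-side channels are
    the left-side waveforms delayed by ``left_right_shift`` of a cycle.
    Identical seeds give bit-identical trials.
    """
    f1, amps, n = _validate(config)
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / config.sample_rate_hz
    phase = _cycle_phase(config, f1, t, rng)
    data = np.empty((n, 6))
    for ci, name in enumerate(CHANNELS):
        side, seg = name.split("_")
        a = amps[seg]
        ph = config.segment_phases[seg]
        p = phase if side == "left" else phase - 2.0 * np.pi * config.left_right_shift
        data[:, ci] = sum(a[k] * np.sin((k + 1) * p + ph[k]) for k in range(3))
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    meta = {"seed": config.seed, "noise_sd": config.noise_sd, "cycle_jitter": config.cycle_jitter}
    return ElevationSeries(
        time=t,
        data=data,
        sample_rate=config.sample_rate_hz,
        velocity_kmh=config.velocity_kmh,
        meta=meta,
    )


def generate_dataset(
    velocities: Sequence[float], base_config: GaitGenConfig | None = None
) -> list[ElevationSeries]:
    """One trial per velocity, sharing all other settings of ``base_config``.

    The base seed is reused for every velocity so that a singleton dataset is
    identical to a direct :func:`generate_trial` call at that velocity.
    """
    if len(velocities) == 0:
        raise InvalidConfigError("velocity list must be non-empty")
    base = base_config if base_config is not None else GaitGenConfig()
    return [
        generate_trial(dataclasses.replace(base, velocity_kmh=float(v))) for v in velocities
    ]


def write_csv(series: ElevationSeries, path: str | Path, sidecar: bool = True) -> None:
    """Write a trial as CSV (``time_s`` + six angle columns, degrees) plus a
    JSON sidecar ``<path>.json`` carrying velocity/sample-rate/seed metadata."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    if sidecar:
        doc = {
            "velocity_kmh": series.velocity_kmh,
            "sample_rate_hz": series.sample_rate,
            "meta": {k: v for k, v in series.meta.items() if _json_safe(v)},
        }
        Path(str(path) + ".json").write_text(json.dumps(doc, sort_keys=True, indent=1))


def read_csv(path: str | Path) -> ElevationSeries:
    """Read a trial written by :func:`write_csv` (sidecar optional)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in ("time_s", *CHANNELS) if c not in frame.columns]
    if missing:
        raise InvalidConfigError(f"CSV is missing columns: {missing}")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidConfigError("CSV must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidConfigError("time column is not uniformly sampled")
    velocity = float("nan")
    meta: dict = {}
    side = Path(str(path) + ".json")
    rate = 1.0 / dt[0]
    if side.exists():
        doc = json.loads(side.read_text())
        velocity = doc.get("velocity_kmh", velocity)
        rate = doc.get("sample_rate_hz", rate)
        meta = doc.get("meta", {})
    return ElevationSeries(
        time=t,
        data=frame[list(CHANNELS)].to_numpy(dtype=float),
        sample_rate=float(rate),
        velocity_kmh=velocity,
        meta=meta,
    )


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None)))
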