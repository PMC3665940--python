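"""Harmonic gait features: cycle selection, FFT harmonics, oscillator inputs.

The analysis pipeline reduces a long elevation-angle recording to (i) a
representative two-gait-cycle segment, (ii) the frequencies and peak
amplitudes of its first three spectral harmonics, and (iii) six sinusoidal
oscillator channels built from those harmonics (a sine and its sign-flipped
twin per harmonic) that drive the recurrent network.  Targets are the
two-cycle waveforms affinely normalized onto [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateNormalizationError,
    ExtractionError,
    InsufficientDataError,
    InvalidConfigError,
)
from .synthetic_gait import CHANNELS, ElevationSeries

#: frequency band (Hz) searched for the stride fundamental
PHYSIOLOGIC_BAND = (0.3, 2.0)
#: zero-padding factor used for spectral peak localization
ZERO_PAD = 4
#: frequency shift (Hz) applied to f1 by the detuned input variants
VARIANT_SHIFTS = {"SEA": 0.0, "SEB": +0.25, "SEC": -0.25, "AM": 0.0}

INPUT_CHANNELS = tuple(f"y_f{i}_{j}" for i in (1, 2, 3) for j in (1, 2))


@dataclass(frozen=True)
class HarmonicSpec:
    """First-three-harmonic frequencies (Hz) and linear peak amplitudes."""

    f1: float
    f2: float
    f3: float
    a1: float
    a2: float
    a3: float
    source_channel: str = "mean"
    velocity_kmh: float = float("nan")
    harmonic_warning: bool = False  # set when |f_k - k f1| exceeds one FFT bin

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "frequencies_hz": list(self.frequencies),
            "amplitudes": list(self.amplitudes),
            "amplitude_convention": "linear magnitude",
            "source_channel": self.source_channel,
            "velocity_kmh": self.velocity_kmh,
            "harmonic_warning": self.harmonic_warning,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonicSpec":
        doc = json.loads(Path(path).read_text())
        f = doc["frequencies_hz"]
        a = doc["amplitudes"]
        return cls(
            f1=f[0], f2=f[1], f3=f[2], a1=a[0], a2=a[1], a3=a[2],
            source_channel=doc.get("source_channel", "mean"),
            velocity_kmh=doc.get("velocity_kmh", float("nan")),
            harmonic_warning=doc.get("harmonic_warning", False),
        )


@dataclass
class CycleSegment:
    """A two-gait-cycle excision from an :class:`ElevationSeries`."""

    start: int  # sample index into the source series
    end: int  # exclusive
    time: np.ndarray
    data: np.ndarray  # (n, 6)
    sample_rate: float
    Tc: float  # one cycle period, seconds
    velocity_kmh: float = float("nan")
    channels: tuple[str, ...] = CHANNELS


@dataclass
class SineInputSet:
    """Six oscillator channels: for each harmonic i, ``y_{fi,1} = sin(2 pi fi t)``
    and its sign-flipped twin ``y_{fi,2} = -y_{fi,1}``, optionally scaled by
    the harmonic amplitude (amplitude-modulated variant)."""

    time: np.ndarray
    data: np.ndarray  # (n, 6) columns in INPUT_CHANNELS order
    variant: str
    frequencies: tuple[float, float, float]
    amplitudes: tuple[float, float, float]
    frequency_shift: float = 0.0
    channels: tuple[str, ...] = INPUT_CHANNELS

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, columns=list(self.channels))
        frame.insert(0, "time_s", self.time)
        return frame


@dataclass
class NormalizationRecord:
    """Per-channel affine map ``x = offset + scale * y`` with y in [-1, 1]."""

    offset: np.ndarray  # (6,) midrange, degrees
    scale: np.ndarray  # (6,) half-range, degrees

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offset) / self.scale

    def denormalize(self, y: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * y


def _fft_peaks(
    x: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = PHYSIOLOGIC_BAND,
    zero_pad: int = ZERO_PAD,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Linear-magnitude spectrum (scaled so a pure sine of amplitude A peaks at
    ~A) of the demeaned signal, zero-padded for peak localization.  Returns
    (freqs, amplitudes, bin width of the unpadded transform)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ExtractionError("signal too short for spectral analysis")
    xd = x - x.mean()
    spec = np.abs(np.fft.rfft(xd, n=zero_pad * n)) * 2.0 / n
    freqs = np.fft.rfftfreq(zero_pad * n, d=1.0 / sample_rate)
    return freqs, spec, sample_rate / n


def extract_harmonics(
    x: np.ndarray | ElevationSeries | CycleSegment,
    sample_rate: float | None = None,
    band: tuple[float, float] = PHYSIOLOGIC_BAND,
    source_channel: str = "",
    velocity_kmh: float = float("nan"),
) -> HarmonicSpec:
    """Extract (f1..f3, a1..a3) from a single waveform by FFT.

    f1 is the frequency of the largest spectral peak inside ``band``; the
    second and third harmonics are read at the maximal bins within +/- 2
    (unpadded) bins of 2 f1 and 3 f1.  A ``harmonic_warning`` flag is set when
    a harmonic strays more than one unpadded FFT bin from k * f1.
    """
    if isinstance(x, (ElevationSeries, CycleSegment)):
        raise TypeError("pass a 1-D waveform; use extract_trial_spec for whole trials")
    freqs, spec, bin_width = _fft_peaks(np.asarray(x, float), float(sample_rate), band)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band) or spec[in_band].max() <= 0:
        raise ExtractionError(f"no spectral peak in band {band}")
    i1 = np.flatnonzero(in_band)[np.argmax(spec[in_band])]
    f1, a1 = freqs[i1], spec[i1]
    out_f = [f1]
    out_a = [a1]
    grid = freqs[1] - freqs[0]
    # +/- 2 unpadded bins around k*f1, but never wide enough to reach the
    # neighbouring harmonic (on a two-cycle segment one bin is f1/2, so a
    # naive 2-bin window would swallow the fundamental peak)
    half_width_hz = min(2.0 * bin_width, 0.45 * f1)
    pad_bins = max(int(round(half_width_hz / grid)), 1)
    warning = False
    for k in (2, 3):
        target = k * f1
        ic = int(round(target / grid))
        lo, hi = max(ic - pad_bins, 0), min(ic + pad_bins + 1, freqs.size)
        if lo >= hi:
            raise ExtractionError(f"harmonic {k} window outside the spectrum")
        ik = lo + int(np.argmax(spec[lo:hi]))
        out_f.append(freqs[ik])
        out_a.append(spec[ik])
        if abs(freqs[ik] - target) > bin_width:
            warning = True
    return HarmonicSpec(
        f1=out_f[0], f2=out_f[1], f3=out_f[2],
        a1=out_a[0], a2=out_a[1], a3=out_a[2],
        source_channel=source_channel, velocity_kmh=velocity_kmh,
        harmonic_warning=warning,
    )


def extract_trial_spec(
    series: ElevationSeries | CycleSegment, band: tuple[float, float] = PHYSIOLOGIC_BAND
) -> HarmonicSpec:
    """Pooled six-channel spec: median harmonic frequencies across channels and
    channel-averaged amplitudes (robust to a single noisy channel)."""
    specs = [
        extract_harmonics(series.data[:, i], series.sample_rate, band, source_channel=name)
        for i, name in enumerate(series.channels)
    ]
    f = np.median([s.frequencies for s in specs], axis=0)
    a = np.mean([s.amplitudes for s in specs], axis=0)
    return HarmonicSpec(
        f1=float(f[0]), f2=float(f[1]), f3=float(f[2]),
        a1=float(a[0]), a2=float(a[1]), a3=float(a[2]),
        source_channel="mean",
        velocity_kmh=series.velocity_kmh,
        harmonic_warning=any(s.harmonic_warning for s in specs),
    )


def detect_cycles(series: ElevationSeries, channel: str = "right_thigh") -> np.ndarray:
    """Gait-cycle boundary times: successive maxima of the low-pass-filtered
    reference channel (right thigh by default, the most sinusoidal segment)."""
    x = series.channel(channel)
    try:
        spec = extract_harmonics(x, series.sample_rate)
    except ExtractionError as exc:
        raise InsufficientDataError(f"cannot estimate stride rate: {exc}") from exc
    f1 = spec.f1
    # remove content above the second harmonic before peak picking
    nyq = series.sample_rate / 2.0
    sos = signal.butter(2, min(3.5 * f1, 0.9 * nyq) / nyq, output="sos")
    smooth = signal.sosfiltfilt(sos, x - x.mean())
    min_dist = max(int(0.7 / f1 * series.sample_rate), 1)
    peaks, _ = signal.find_peaks(smooth, distance=min_dist)
    if peaks.size < 3:
        raise InsufficientDataError(
            f"only {peaks.size} cycle maxima found; need at least 3"
        )
    return series.time[peaks]


def _segment(series: ElevationSeries, start: int, end: int) -> CycleSegment:
    return CycleSegment(
        start=start,
        end=end,
        time=series.time[start:end].copy(),
        data=series.data[start:end].copy(),
        sample_rate=series.sample_rate,
        Tc=(end - start) / series.sample_rate / 2.0,
        velocity_kmh=series.velocity_kmh,
        channels=series.channels,
    )


def select_representative_cycles(series: ElevationSeries) -> CycleSegment:
    """Excise the two consecutive gait cycles whose pooled FFT peaks best match
    those of the whole recording.

    The spectral distance of a candidate pair is the sum over the three
    harmonics of the relative frequency error plus the relative amplitude
    error against the full-record spec; ties go to the earliest pair.
    """
    bounds = detect_cycles(series)
    idx = np.round(bounds * series.sample_rate).astype(int)
    full = extract_trial_spec(series)
    fref = np.asarray(full.frequencies)
    aref = np.asarray(full.amplitudes)
    best: tuple[float, int] | None = None
    for k in range(len(idx) - 2):
        seg = _segment(series, idx[k], idx[k + 2])
        try:
            spec = extract_trial_spec(seg)
        except ExtractionError:
            continue
        dist = float(
            np.sum(np.abs(np.asarray(spec.frequencies) - fref) / fref)
            + np.sum(np.abs(np.asarray(spec.amplitudes) - aref) / np.maximum(aref, 1e-12))
        )
        if best is None or dist < best[0] - 1e-12:
            best = (dist, k)
    if best is None:
        raise InsufficientDataError("no candidate cycle pair admitted a spectrum")
    k = best[1]
    return _segment(series, idx[k], idx[k + 2])


def build_sine_inputs(
    spec: HarmonicSpec,
    variant: str,
    time_grid: np.ndarray,
) -> SineInputSet:
    """Construct the six oscillator channels on ``time_grid``.

    SEA uses the extracted harmonic frequencies at unit amplitude; SEB / SEC
    shift the fundamental by +/- 0.25 Hz (and its harmonics by +/- 0.50 and
    +/- 0.75 Hz); AM keeps SEA's frequencies and scales the channel pair of
    harmonic i by its extracted amplitude a_i.
    """
    if variant not in VARIANT_SHIFTS:
        raise InvalidConfigError(f"unknown variant {variant!r}; use SEA/SEB/SEC/AM")
    if spec.f1 <= 0:
        raise InvalidConfigError("spec.f1 must be positive")
    shift = VARIANT_SHIFTS[variant]
    if variant in ("SEA", "AM"):
        freqs = spec.frequencies
    else:
        f1s = spec.f1 + shift
        if f1s <= 0:
            raise InvalidConfigError(
                f"variant {variant} shifts f1 to {f1s:.3f} Hz <= 0"
            )
        freqs = (f1s, 2.0 * spec.f1 + 2.0 * shift, 3.0 * spec.f1 + 3.0 * shift)
    amps = spec.amplitudes if variant == "AM" else (1.0, 1.0, 1.0)
    t = np.asarray(time_grid, dtype=float)
    data = np.empty((t.size, 6))
    for i, (f, a) in enumerate(zip(freqs, amps)):
        y = a * np.sin(2.0 * np.pi * f * t)
        data[:, 2 * i] = y
        data[:, 2 * i + 1] = -y
    return SineInputSet(
        time=t,
        data=data,
        variant=variant,
        frequencies=tuple(float(f) for f in freqs),
        amplitudes=tuple(float(a) for a in amps),
        frequency_shift=shift,
    )


def normalize_targets(
    segment: CycleSegment | np.ndarray,
) -> tuple[np.ndarray, NormalizationRecord]:
    """Map each channel affinely onto [-1, 1]; returns the normalized array and
    the per-channel (offset, scale) record for mapping predictions back to
    degrees."""
    data = segment.data if isinstance(segment, CycleSegment) else np.asarray(segment, float)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    if np.any(hi - lo <= 0):
        flat = [i for i in range(data.shape[1]) if hi[i] - lo[i] <= 0]
        raise DegenerateNormalizationError(f"constant channel(s) at index {flat}")
    record = NormalizationRecord(offset=(hi + lo) / 2.0, scale=(hi - lo) / 2.0)
    return record.normalize(data), record


def _refine_frequency(
    x: np.ndarray, sample_rate: float, f0: float, span: float = 0.05, n_grid: int = 201
) -> float:
    """Refine a rough tone frequency by maximizing the direct DTFT magnitude
    on a fine grid around ``f0``, free of FFT-bin quantization and most
    leakage bias."""
    xd = x - x.mean()
    t = np.arange(x.size) / sample_rate
    fgrid = f0 * np.linspace(1.0 - span, 1.0 + span, n_grid)
    power = np.abs(np.exp(-2j * np.pi * fgrid[:, None] * t[None, :]) @ xd)
    return float(fgrid[int(np.argmax(power))])


def harmonic_variance_fraction(
    x: np.ndarray, sample_rate: float, n_harmonics: int = 2
) -> float:
    """Fraction of total waveform variance carried by the first ``n_harmonics``
    spectral harmonics.

    The signal is truncated to a whole number of estimated stride periods
    (making the rectangular window leakage-free for a stationary gait) and the
    power in a narrow band around each harmonic peak -- wide enough to absorb
    cycle-to-cycle period jitter -- is compared with the total demeaned power.
    """
    x = np.asarray(x, dtype=float)
    spec = extract_harmonics(x, sample_rate)
    f1 = _refine_frequency(x, sample_rate, spec.f1)
    spec = replace(spec, f1=f1, f2=2.0 * f1, f3=3.0 * f1)
    n_cycles = int(np.floor(x.size / sample_rate * spec.f1))
    if n_cycles < 1:
        raise ExtractionError("signal shorter than one stride period")
    n = int(round(n_cycles / spec.f1 * sample_rate))
    xd = x[:n] - x[:n].mean()
    X = np.fft.rfft(xd)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    total = np.sum(np.abs(X) ** 2)
    if total <= 0:
        raise ExtractionError("zero-variance waveform")
    bin_width = sample_rate / n
    power = 0.0
    for k in range(n_harmonics):
        f = spec.frequencies[k]
        half_band = max(1.5 * bin_width, 0.08 * spec.f1)
        sel = np.abs(freqs - f) <= half_band
        power += np.sum(np.abs(X[sel]) ** 2)
    return float(power / total)
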