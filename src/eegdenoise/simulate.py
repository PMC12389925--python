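"""Seeded synthetic EEG with ground-truth-annotated muscle bursts and blinks.

The generator emulates the statistical structure the denoiser assumes:
a 1/f ("pink") background with an alpha (8–12 Hz) oscillation per channel,
occasional transient muscle bursts of band-limited (20–300 Hz) noise with
half their power concentrated in the 110–140 Hz band where myogenic activity
is most prominent, and, optionally, slow frontal blink deflections.  Burst
onsets and durations are recorded, so every downstream module can be scored
against a known truth.

Amplitudes are in µV.  Everything is driven by one seed: the same
:class:`SimConfig` always yields bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .ground_truth import ArtefactIntervals

__all__ = [
    "SimConfig",
    "SimOutput",
    "generate_background",
    "inject_muscle_bursts",
    "inject_blinks",
    "simulate",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic EEG stream.

    Defaults: 8 channels of 120 s at 1024 Hz with ~20 muscle bursts
    (10 per minute) at 8x the background RMS, and no blinks.  Set
    ``n_channels=30`` for a full-montage emulation.
    """

    n_channels: int = 8
    duration_s: float = 120.0
    sr_hz: float = 1024.0
    burst_rate: float = 10.0  # bursts per minute
    burst_dur_range: tuple[float, float] = (0.4, 1.0)
    burst_gain: float = 8.0  # burst RMS as a multiple of background RMS
    burst_band: tuple[float, float] = (20.0, 300.0)
    emphasis_band: tuple[float, float] = (110.0, 140.0)
    emphasis_frac: float = 0.5  # fraction of burst power in the emphasis band
    blink_rate: float = 0.0  # blinks per minute (0 disables)
    blink_amp_uv: float = 100.0
    background_rms_uv: float = 10.0
    alpha_freq_hz: float = 10.0
    alpha_amp_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burst_band[0] < self.burst_band[1] < self.sr_hz / 2:
            raise ValueError("burst band must lie within (0, Nyquist)")
        if not 0 < self.burst_dur_range[0] <= self.burst_dur_range[1]:
            raise ValueError("burst durations must be positive")
        if self.n_channels < 1 or self.duration_s <= 0 or self.sr_hz <= 0:
            raise ValueError("invalid geometry")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sr_hz))


@dataclass
class SimOutput:
    data: np.ndarray  # channels x samples, µV
    true_intervals: ArtefactIntervals
    blink_intervals: ArtefactIntervals
    #: channels each burst was applied to, parallel to true_intervals
    burst_channels: list[np.ndarray] = field(default_factory=list)
    config: SimConfig | None = None


def _pink_spectrum_amplitude(freqs: np.ndarray) -> np.ndarray:
    """sqrt(PSD) shaping: PSD ~ 1/f from 1 Hz, steeper (1/f^2) above 64 Hz."""
    f = np.maximum(np.abs(freqs), 1.0)
    psd = np.where(f <= 64.0, 1.0 / f, 64.0 / f**2)
    return np.sqrt(psd)


def generate_background(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """1/f-shaped Gaussian noise plus a random-phase alpha oscillation."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.sr_hz)
    shape = _pink_spectrum_amplitude(freqs)
    shape[0] = 0.0  # no DC offset
    t = np.arange(n) / cfg.sr_hz
    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        white = rng.standard_normal(n)
        pink = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        pink *= cfg.background_rms_uv / np.sqrt(np.mean(pink**2))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data[ch] = pink + cfg.alpha_amp_uv * np.sin(2.0 * np.pi * cfg.alpha_freq_hz * t + phase)
    return data


def _place_intervals(
    rng: np.random.Generator,
    n_wanted: int,
    dur_range: tuple[float, float],
    duration_s: float,
    min_gap_s: float = 0.2,
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    placed: list[tuple[float, float]] = []
    for _ in range(n_wanted):
        dur = float(rng.uniform(*dur_range))
        for _ in range(max_tries):
            onset = float(rng.uniform(0.0, duration_s - dur))
            clash = any(
                onset < o + d + min_gap_s and o < onset + dur + min_gap_s
                for o, d in placed
            )
            if not clash:
                placed.append((onset, dur))
                break
    if len(placed) < n_wanted:
        warnings.warn(
            f"placed only {len(placed)} of {n_wanted} intervals without overlap"
        )
    return sorted(placed)


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], sr: float) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=sr, output="sos")
    m = max(n, 256)  # filter a longer stretch so the zero-phase pad always fits
    x = signal.sosfiltfilt(sos, rng.standard_normal(m))[:n]
    return x / max(np.sqrt(np.mean(x**2)), 1e-30)


def inject_muscle_bursts(
    data: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimOutput:
    """Add Poisson-placed, Hann-tapered muscle bursts; record the truth.

    Each burst hits a random subset of at least half the channels with
    independent band-limited noise scaled to ``burst_gain`` times that
    channel's pre-burst RMS; a fraction ``emphasis_frac`` of burst power is
    shaped into the 110–140 Hz emphasis band.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    data = np.array(data, dtype=np.float64, copy=True)
    n_ch = data.shape[0]
    n_bursts = int(rng.poisson(cfg.burst_rate * cfg.duration_s / 60.0))
    placed = _place_intervals(rng, n_bursts, cfg.burst_dur_range, cfg.duration_s)
    rms = np.sqrt(np.mean(data**2, axis=1))
    burst_channels: list[np.ndarray] = []
    for onset, dur in placed:
        i0 = int(round(onset * cfg.sr_hz))
        n = max(int(round(dur * cfg.sr_hz)), 8)
        n_hit = int(rng.integers(math.ceil(n_ch / 2), n_ch + 1))
        hit = rng.choice(n_ch, size=n_hit, replace=False)
        taper = signal.windows.hann(n)
        for ch in hit:
            broad = _band_noise(rng, n, cfg.burst_band, cfg.sr_hz)
            narrow = _band_noise(rng, n, cfg.emphasis_band, cfg.sr_hz)
            burst = (
                math.sqrt(1.0 - cfg.emphasis_frac) * broad
                + math.sqrt(cfg.emphasis_frac) * narrow
            )
            burst *= taper
            burst *= cfg.burst_gain * rms[ch] / max(np.sqrt(np.mean(burst**2)), 1e-30)
            data[ch, i0 : i0 + n] += burst
        burst_channels.append(np.sort(hit))
    intervals = ArtefactIntervals([(o, d) for o, d in placed], None, n_ch)
    return SimOutput(data, intervals, ArtefactIntervals([]), burst_channels, cfg)


def inject_blinks(
    data: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimOutput:
    """Add half-cosine blink deflections on the frontal (first two) channels."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    data = np.array(data, dtype=np.float64, copy=True)
    n_blinks = int(rng.poisson(cfg.blink_rate * cfg.duration_s / 60.0))
    placed = _place_intervals(rng, n_blinks, (0.2, 0.7), cfg.duration_s)
    frontal = range(min(2, data.shape[0]))
    for onset, dur in placed:
        i0 = int(round(onset * cfg.sr_hz))
        n = int(round(dur * cfg.sr_hz))
        pulse = cfg.blink_amp_uv * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))
        for ch in frontal:
            data[ch, i0 : i0 + n] += pulse
    intervals = ArtefactIntervals([(o, d) for o, d in placed], None, data.shape[0])
    return SimOutput(data, ArtefactIntervals([]), intervals, [], cfg)


def simulate(cfg: SimConfig) -> SimOutput:
    """Background + muscle bursts (+ blinks when ``blink_rate > 0``)."""
    rng = np.random.default_rng(cfg.seed)
    background = generate_background(cfg, rng)
    out = inject_muscle_bursts(background, cfg, rng)
    blink_intervals = ArtefactIntervals([])
    if cfg.blink_rate > 0:
        blinked = inject_blinks(out.data, cfg, rng)
        out.data = blinked.data
        blink_intervals = blinked.blink_intervals
    return SimOutput(out.data, out.true_intervals, blink_intervals, out.burst_channels, cfg)
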