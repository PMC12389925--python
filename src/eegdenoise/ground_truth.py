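"""Offline multi-channel muscle-artefact annotation.

Muscle bursts are broadband but most prominent around 110–140 Hz, a band with
little genuine cortical power.  The annotator band-passes every channel there,
takes the Hilbert-envelope z-scores, integrates them across channels
(sum / sqrt(n)), low-pass-filters the integrated score at 4 Hz to suppress
single-sample false positives, and marks runs of samples above a z-score
threshold as artefactual intervals; gaps of good data shorter than ``min_len``
seconds are merged into the surrounding interval.

Because the z-score threshold is hard to choose a priori, a sweep from 5.0
down to 2.0 (step 0.1) picks the threshold maximizing the fraction of
intervals that pass an independent spectral check: an interval is *valid* when
its channel-averaged Welch spectrum over 30–300 Hz is stochastically larger
than that of the whole recording (one-tailed Mann–Whitney U, alpha 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ArtefactIntervals",
    "SweepResult",
    "integrated_artifact_scores",
    "detect_intervals",
    "validate_intervals",
    "sweep_threshold",
    "write_events",
    "read_events",
]

MUSCLE_BAND = (110.0, 140.0)
VALIDATION_BAND = (30.0, 300.0)
WELCH_SEGMENT_S = 0.5


@dataclass
class ArtefactIntervals:
    """Artefact annotations as (onset, duration) pairs in seconds."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    zs_threshold_used: float | None = None
    n_channels: int | None = None

    def __post_init__(self) -> None:
        onsets = [o for o, _ in self.intervals]
        if any(d <= 0 for _, d in self.intervals):
            raise ValueError("durations must be positive")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_duration(self) -> float:
        return float(sum(d for _, d in self.intervals))

    def overlaps(self, start: float, stop: float) -> bool:
        """True when any interval intersects [start, stop)."""
        return any(o < stop and o + d > start for o, d in self.intervals)


@dataclass
class SweepResult:
    ideal_threshold: float
    per_threshold: list[tuple[float, int, int, float]]  # (th, n_intervals, n_valid, ratio)
    final_intervals: ArtefactIntervals


def _sos_bandpass(l_freq: float, h_freq: float, sr: float):
    return signal.butter(4, [l_freq, h_freq], btype="bandpass", fs=sr, output="sos")


def integrated_artifact_scores(
    data: np.ndarray,
    sr: float,
    l_freq: float = MUSCLE_BAND[0],
    h_freq: float = MUSCLE_BAND[1],
) -> np.ndarray:
    """One cross-channel artefact score per sample.

    Band-pass [l_freq, h_freq] -> Hilbert envelope -> per-channel z-score ->
    sum across channels / sqrt(n) -> 4 Hz low-pass.  Zero-phase (forward–
    backward) 4th-order Butterworth filters preserve burst timing.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if not 0 < l_freq < h_freq < sr / 2:
        raise ValueError("band must satisfy 0 < l_freq < h_freq < Nyquist")
    filt = signal.sosfiltfilt(_sos_bandpass(l_freq, h_freq, sr), data, axis=1)
    envelope = np.abs(signal.hilbert(filt, axis=1))
    mu = envelope.mean(axis=1, keepdims=True)
    sd = envelope.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (envelope - mu) / sd
    integrated = z.sum(axis=0) / np.sqrt(data.shape[0])
    sos_lp = signal.butter(4, 4.0, btype="lowpass", fs=sr, output="sos")
    return signal.sosfiltfilt(sos_lp, integrated)


def detect_intervals(
    scores: np.ndarray,
    sr: float,
    zs_th: float,
    min_len_s: float = 0.1,
    n_channels: int | None = None,
) -> ArtefactIntervals:
    """Turn supra-threshold score runs into intervals, merging short good gaps."""
    if zs_th <= 0:
        raise ValueError("z-score threshold must be positive")
    mask = np.asarray(scores) > zs_th
    if not mask.any():
        return ArtefactIntervals([], zs_th, n_channels)
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    min_gap = int(round(min_len_s * sr))
    merged: list[list[int]] = [[starts[0], stops[0]]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e  # gap of good data too short: absorb it
        else:
            merged.append([s, e])
    intervals = [(s / sr, (e - s) / sr) for s, e in merged]
    return ArtefactIntervals(intervals, zs_th, n_channels)


def _band_psd(data: np.ndarray, sr: float, band: tuple[float, float]) -> np.ndarray:
    """Channel-averaged Welch PSD values at the frequency bins inside ``band``."""
    nperseg = int(round(WELCH_SEGMENT_S * sr))
    freqs, psd = signal.welch(
        data, fs=sr, nperseg=min(nperseg, data.shape[-1]), noverlap=None, axis=-1
    )
    if psd.ndim > 1:
        psd = psd.mean(axis=0)
    hi = min(band[1], sr / 2)
    sel = (freqs >= band[0]) & (freqs <= hi)
    return psd[sel]


def validate_intervals(
    data: np.ndarray,
    sr: float,
    intervals: ArtefactIntervals,
    alpha: float = 0.01,
    band: tuple[float, float] = VALIDATION_BAND,
) -> list[bool]:
    """Spectral check of each interval against the whole recording.

    Valid iff the whole-recording channel-averaged PSD bin values over
    ``band`` are stochastically less than the interval's (one-tailed
    Mann–Whitney U, p < alpha).  Intervals shorter than one Welch segment
    cannot be tested and are flagged invalid with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    duration = data.shape[1] / sr
    whole = _band_psd(data, sr, band)
    nperseg = int(round(WELCH_SEGMENT_S * sr))
    flags: list[bool] = []
    for onset, dur in intervals:
        if onset < 0 or onset + dur > duration + 1e-9:
            raise ValueError(f"interval ({onset}, {dur}) outside the recording")
        i0, i1 = int(round(onset * sr)), int(round((onset + dur) * sr))
        if i1 - i0 < nperseg:
            warnings.warn(
                f"interval at {onset:.3f}s shorter than one Welch segment; flagged invalid"
            )
            flags.append(False)
            continue
        seg = _band_psd(data[:, i0:i1], sr, band)
        p = stats.mannwhitneyu(whole, seg, alternative="less").pvalue
        flags.append(bool(p < alpha))
    return flags


def sweep_threshold(
    data: np.ndarray,
    sr: float,
    l_freq: float = MUSCLE_BAND[0],
    h_freq: float = MUSCLE_BAND[1],
    min_len_s: float = 0.1,
    alpha: float = 0.01,
) -> SweepResult:
    """Pick the precision-maximizing z-score threshold.

    Thresholds 5.0, 4.9, ..., 2.0 are tried; for each, intervals are detected
    and spectrally validated, and the ratio valid/total is tracked.  The
    earliest strictly-best ratio wins; detection is rerun at that ideal
    threshold for the final annotations.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    scores = integrated_artifact_scores(data, sr, l_freq, h_freq)
    thresholds = np.round(np.arange(50, 19, -1) / 10.0, 1)  # 5.0 ... 2.0
    best_ratio = -1.0
    ideal: float | None = None
    per_threshold: list[tuple[float, int, int, float]] = []
    for th in thresholds:
        found = detect_intervals(scores, sr, float(th), min_len_s, data.shape[0])
        if len(found) == 0:
            per_threshold.append((float(th), 0, 0, 0.0))
            continue
        with warnings.catch_warnings():
            # sub-segment intervals are routine at low thresholds; they are
            # counted as invalid, which is all the sweep needs to know
            warnings.simplefilter("ignore", UserWarning)
            valid = validate_intervals(data, sr, found, alpha)
        ratio = sum(valid) / len(found)
        per_threshold.append((float(th), len(found), int(sum(valid)), float(ratio)))
        if ratio > best_ratio:
            best_ratio = ratio
            ideal = float(th)
    if ideal is None:
        warnings.warn("no intervals found at any threshold; returning empty annotations")
        ideal = float(thresholds[-1])
        final = ArtefactIntervals([], ideal, data.shape[0])
    else:
        final = detect_intervals(scores, sr, ideal, min_len_s, data.shape[0])
    return SweepResult(ideal, per_threshold, final)


def write_events(intervals: ArtefactIntervals, path: str | Path, label: str = "muscle") -> None:
    """Write annotations as a BIDS-style events table (TSV or CSV by suffix)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset": [o for o, _ in intervals],
            "duration": [d for _, d in intervals],
            "trial_type": label,
        }
    )
    df.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",", index=False)


def read_events(path: str | Path) -> ArtefactIntervals:
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
    pairs = sorted(zip(df["onset"].astype(float), df["duration"].astype(float)))
    return ArtefactIntervals([(float(o), float(d)) for o, d in pairs])
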