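"""Denoising evaluation: per-window SNR, JS divergence, H1 comparisons.

The working hypothesis of the denoiser is that muscle activity depresses the
signal-to-noise ratio of a window — defined here as the dB ratio of neural-
band (1–30 Hz) to muscle-band (110–140 Hz) Welch power — and that denoising
restores it in artefactual windows while leaving clean windows untouched.
Per-channel SNR distributions (histograms over shared bins) are compared with
the Jensen–Shannon divergence in base 2, whose range is [0, 1].

Two aggregate comparisons are reported: the divergence between artefactual
and non-artefactual windows should shrink after denoising (O:AvsNa >
D:AvsNa), and the divergence between original and denoised windows should be
larger in the artefactual class than in the non-artefactual one (A:OvsD >
Na:OvsD).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .ground_truth import ArtefactIntervals, WELCH_SEGMENT_S

__all__ = [
    "WindowLabelSet",
    "H1Report",
    "label_windows",
    "window_snr",
    "stream_window_snrs",
    "snr_distribution_pair",
    "js_divergence",
    "evaluate_h1",
]

NEURAL_BAND = (1.0, 30.0)
MUSCLE_BAND = (110.0, 140.0)
N_BINS = 30
_EPS = 1e-12


@dataclass
class WindowLabelSet:
    """Boolean artefactual flag for every stream window (channel-agnostic)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.labels.size

    @property
    def artefactual(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    @property
    def clean(self) -> np.ndarray:
        return np.flatnonzero(~self.labels)


def label_windows(
    intervals: ArtefactIntervals, n_windows: int, rtwl_ms: float
) -> WindowLabelSet:
    """A window is artefactual iff it overlaps any interval by >= 1 sample."""
    if n_windows < 1:
        raise ValueError("need at least one window")
    t = rtwl_ms / 1000.0
    labels = np.array(
        [intervals.overlaps(w * t, (w + 1) * t) for w in range(n_windows)]
    )
    return WindowLabelSet(labels)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].mean())


def window_snr(window_samples: np.ndarray, sr: float) -> float:
    """10 log10(neural-band power / muscle-band power), Welch 0.5 s segments."""
    x = np.asarray(window_samples, dtype=np.float64)
    if x.size < WELCH_SEGMENT_S * sr:
        raise ValueError("window must span at least one 0.5 s Welch segment")
    if sr / 2 <= MUSCLE_BAND[1]:
        raise ValueError("sampling rate too low to resolve the muscle band")
    freqs, psd = signal.welch(x, fs=sr, nperseg=int(round(WELCH_SEGMENT_S * sr)))
    p_neural = _band_power(freqs, psd, NEURAL_BAND)
    p_muscle = _band_power(freqs, psd, MUSCLE_BAND)
    return 10.0 * np.log10(max(p_neural, _EPS) / max(p_muscle, _EPS))


def stream_window_snrs(channel: np.ndarray, sr: float, rtwl_ms: float) -> np.ndarray:
    """Per-window SNRs of one channel, full windows only."""
    n = int(round(rtwl_ms * sr / 1000.0))
    n_windows = channel.size // n
    return np.array(
        [window_snr(channel[w * n : (w + 1) * n], sr) for w in range(n_windows)]
    )


def snr_distribution_pair(
    x: np.ndarray, y: np.ndarray, bins: int = N_BINS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram both samples on shared bins spanning their pooled range."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(x, bins=edges)[0].astype(np.float64)
    q = np.histogram(y, bins=edges)[0].astype(np.float64)
    return p / p.sum(), q / q.sum(), edges


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence in base 2 (range [0, 1]).

    JS(P||Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P+Q)/2; zero-probability
    bins are epsilon-smoothed and renormalized.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must share their support")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("distributions must each sum to 1")
    p = (p + _EPS) / (p + _EPS).sum()
    q = (q + _EPS) / (q + _EPS).sum()
    m = 0.5 * (p + q)
    kl_pm = np.sum(p * np.log2(p / m))
    kl_qm = np.sum(q * np.log2(q / m))
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def _js_from_samples(x: np.ndarray, y: np.ndarray) -> float:
    p, q, _ = snr_distribution_pair(x, y)
    return js_divergence(p, q)


@dataclass
class H1Report:
    """Per-channel JS divergences and the two aggregate H1 comparisons."""

    per_channel: pd.DataFrame  # columns: channel, o_a_vs_na, d_a_vs_na, a_o_vs_d, na_o_vs_d
    skipped_channels: list[int] = field(default_factory=list)

    @property
    def mean_o_a_vs_na(self) -> float:
        return float(self.per_channel["o_a_vs_na"].mean())

    @property
    def mean_d_a_vs_na(self) -> float:
        return float(self.per_channel["d_a_vs_na"].mean())

    @property
    def mean_a_o_vs_d(self) -> float:
        return float(self.per_channel["a_o_vs_d"].mean())

    @property
    def mean_na_o_vs_d(self) -> float:
        return float(self.per_channel["na_o_vs_d"].mean())

    @property
    def h1_first(self) -> bool:
        """Mean JS(A vs Na) drops after denoising: O:AvsNa > D:AvsNa."""
        return self.mean_o_a_vs_na > self.mean_d_a_vs_na

    @property
    def h1_second(self) -> bool:
        """Denoising moves artefactual windows more: A:OvsD > Na:OvsD."""
        return self.mean_a_o_vs_d > self.mean_na_o_vs_d

    def channel_fraction_first(self) -> float:
        df = self.per_channel
        return float((df["o_a_vs_na"] > df["d_a_vs_na"]).mean())

    def channel_fraction_second(self) -> float:
        df = self.per_channel
        return float((df["a_o_vs_d"] > df["na_o_vs_d"]).mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_channel": self.per_channel.to_dict(orient="records"),
            "skipped_channels": self.skipped_channels,
            "mean": {
                "o_a_vs_na": self.mean_o_a_vs_na,
                "d_a_vs_na": self.mean_d_a_vs_na,
                "a_o_vs_d": self.mean_a_o_vs_d,
                "na_o_vs_d": self.mean_na_o_vs_d,
            },
            "h1": {"first": self.h1_first, "second": self.h1_second},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.per_channel.to_csv(path, index=False)


def evaluate_h1(
    original: np.ndarray,
    denoised: np.ndarray,
    labels: WindowLabelSet,
    sr: float,
    rtwl_ms: float = 1000.0,
) -> H1Report:
    """Per-channel JS divergences of per-window SNR distributions.

    For each channel: JS(O-A vs O-Na), JS(D-A vs D-Na), JS(A: O vs D) and
    JS(Na: O vs D).  Channels for which a label class is empty are skipped
    with a warning.
    """
    original = np.atleast_2d(np.asarray(original, dtype=np.float64))
    denoised = np.atleast_2d(np.asarray(denoised, dtype=np.float64))
    if original.shape != denoised.shape:
        raise ValueError("original and denoised matrices must have the same shape")
    art = labels.artefactual
    clean = labels.clean
    rows = []
    skipped: list[int] = []
    if art.size == 0 or clean.size == 0:
        warnings.warn("a label class is empty; all channels skipped")
        skipped = list(range(original.shape[0]))
    else:
        for ch in range(original.shape[0]):
            snr_o = stream_window_snrs(original[ch], sr, rtwl_ms)[: labels.n_windows]
            snr_d = stream_window_snrs(denoised[ch], sr, rtwl_ms)[: labels.n_windows]
            rows.append(
                {
                    "channel": ch,
                    "o_a_vs_na": _js_from_samples(snr_o[art], snr_o[clean]),
                    "d_a_vs_na": _js_from_samples(snr_d[art], snr_d[clean]),
                    "a_o_vs_d": _js_from_samples(snr_o[art], snr_d[art]),
                    "na_o_vs_d": _js_from_samples(snr_o[clean], snr_d[clean]),
                }
            )
    columns = ["channel", "o_a_vs_na", "d_a_vs_na", "a_o_vs_d", "na_o_vs_d"]
    return H1Report(pd.DataFrame(rows, columns=columns), skipped)
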