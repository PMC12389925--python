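"""Streaming denoiser: sliding buffer, anomaly detection, medoid mitigation.

Each channel is processed independently, window by window.  A window is
decomposed into its scaleogram; the level-normalized slice vectors of the
previous ``Bs`` windows form a sliding FIFO buffer on which an extended
isolation forest is refit for every new window.  Slices of the current window
scoring above the anomaly threshold (expanded by ``Es`` neighbours each side)
are attenuated by a Hadamard product with a mitigator vector derived from the
distance to the buffer medoid — gentle near the medoid (typical activity),
aggressive far from it — applied to the *non-normalized* coefficients, which
are then collapsed and inverted back to the time domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .iforest import ExtendedIsolationForest
from .wavelet import (
    Window,
    Scaleogram,
    build_scaleogram,
    collapse_scaleogram,
    decompose_window,
    max_level,
    normalize_scaleogram,
    reconstruct,
)

__all__ = [
    "FrameworkConfig",
    "SlidingBuffer",
    "AnomalyRecord",
    "expand_anomalies",
    "buffer_medoid",
    "mitigator_vector",
    "apply_mitigation",
    "process_window",
    "denoise_stream",
]


@dataclass
class FrameworkConfig:
    """The 8-tuple <RTWL, Sr, MW, IFS, IFt, Bs, ta, Es> plus a seed.

    Defaults are the muscle-artefact instantiation: 1000 ms windows at
    1024 Hz, db4 wavelet, forest of 100 trees subsampling 512 vectors, a
    20-window buffer, anomaly threshold 0.55 and expansion step 0.
    """

    rtwl_ms: float = 1000.0
    sr_hz: float = 1024.0
    wavelet: str = "db4"
    if_subsample: int = 512
    if_trees: int = 100
    buffer_windows: int = 20
    anomaly_threshold: float = 0.55
    expansion_step: int = 0
    seed: int = 0
    #: "per_dimension" (scale-wise distances, the default) or "scalar"
    #: (a single Euclidean distance ratio broadcast over all scales).
    mitigator_mode: str = "per_dimension"

    def __post_init__(self) -> None:
        n = self.window_samples
        if n < 2 or abs(self.rtwl_ms * self.sr_hz / 1000.0 - n) > 1e-9:
            raise ValueError("rtwl_ms * sr_hz / 1000 must be a positive integer")
        levels = max_level(n, self.wavelet)
        if n % (1 << levels) != 0:
            raise ValueError(
                f"window length {n} must be a multiple of 2**M = {1 << levels}"
            )
        if not 0.0 < self.anomaly_threshold < 1.0:
            raise ValueError("anomaly_threshold must lie in (0, 1)")
        if self.expansion_step < 0:
            raise ValueError("expansion_step must be >= 0")
        if self.buffer_windows < 1:
            raise ValueError("buffer_windows must be >= 1")
        if self.if_subsample < 2:
            raise ValueError("if_subsample must be >= 2")
        if self.if_subsample > self.buffer_windows * self.k:
            raise ValueError("if_subsample exceeds the buffer capacity in vectors")
        if self.mitigator_mode not in ("per_dimension", "scalar"):
            raise ValueError("mitigator_mode must be 'per_dimension' or 'scalar'")

    @property
    def window_samples(self) -> int:
        return int(round(self.rtwl_ms * self.sr_hz / 1000.0))

    @property
    def k(self) -> int:
        """Scaleogram columns per window (= window_samples / 2)."""
        return self.window_samples // 2

    @property
    def n_levels(self) -> int:
        return max_level(self.window_samples, self.wavelet)

    @classmethod
    def from_file(cls, path: str | Path) -> "FrameworkConfig":
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**payload)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(asdict(self), fh, indent=2)
            else:
                yaml.safe_dump(asdict(self), fh)


class SlidingBuffer:
    """FIFO of the normalized slice vectors of the last ``Bs`` windows.

    Also maintains, incrementally, each member's sum of Euclidean distances to
    every other member, so the buffer medoid is available in O(buffer size)
    after each push instead of O(size^2) from scratch.
    """

    def __init__(self, capacity_windows: int):
        if capacity_windows < 1:
            raise ValueError("capacity must be >= 1 window")
        self.capacity_windows = int(capacity_windows)
        self._windows: list[np.ndarray] = []
        self._sums: list[np.ndarray] = []
        self.window_count = 0

    def __len__(self) -> int:
        return sum(w.shape[0] for w in self._windows)

    @property
    def full(self) -> bool:
        return len(self._windows) >= self.capacity_windows

    def columns(self) -> np.ndarray:
        """All stored vectors, oldest window first, as a (size x dim) array."""
        if not self._windows:
            raise ValueError("buffer is empty")
        return np.concatenate(self._windows, axis=0)

    def push(self, cols: np.ndarray) -> None:
        """Absorb one window's vectors, evicting the oldest window at capacity."""
        cols = np.ascontiguousarray(cols, dtype=np.float64)
        if cols.ndim != 2:
            raise ValueError("expected a (k x dim) array of slice vectors")
        if self._windows and cols.shape[1] != self._windows[0].shape[1]:
            raise ValueError("vector dimensionality changed")
        if self.full:
            evicted = self._windows.pop(0)
            self._sums.pop(0)
            for w, s in zip(self._windows, self._sums):
                s -= cdist(w, evicted).sum(axis=1)
        new_sum = cdist(cols, cols).sum(axis=1)
        for w, s in zip(self._windows, self._sums):
            block = cdist(w, cols)
            s += block.sum(axis=1)
            new_sum += block.sum(axis=0)
        self._windows.append(cols)
        self._sums.append(new_sum)
        self.window_count += 1

    def distance_sums(self) -> np.ndarray:
        if not self._windows:
            raise ValueError("buffer is empty")
        return np.concatenate(self._sums)

    def medoid(self) -> np.ndarray:
        """Member minimizing the total distance to all members (earliest on ties)."""
        idx = int(np.argmin(self.distance_sums()))
        return self.columns()[idx].copy()

    def max_abs_deviation(self, center: np.ndarray) -> np.ndarray:
        """Per-dimension max |v_i - center_i| over the buffer."""
        return np.abs(self.columns() - center[None, :]).max(axis=0)

    def max_distance(self, center: np.ndarray) -> float:
        """Max Euclidean distance from ``center`` over the buffer."""
        return float(np.linalg.norm(self.columns() - center[None, :], axis=1).max())


def buffer_medoid(buffer: SlidingBuffer) -> np.ndarray:
    """Euclidean medoid of all vectors currently in the buffer."""
    return buffer.medoid()


@dataclass
class AnomalyRecord:
    """Per-window detection outcome: flagged slices and their mitigators."""

    window_index: int
    at: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    at_exp: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    mitigators: dict[int, np.ndarray] = field(default_factory=dict)
    scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "window_index": int(self.window_index),
            "at": [int(i) for i in self.at],
            "at_exp": [int(i) for i in self.at_exp],
            "mitigators": {str(t): v.tolist() for t, v in self.mitigators.items()},
        }


def expand_anomalies(at: np.ndarray, es: int, k: int) -> np.ndarray:
    """Union of [t - es, t + es] around each flagged slice, clipped to [0, k)."""
    at = np.asarray(at, dtype=np.intp)
    if at.size == 0:
        return at
    if at.min() < 0 or at.max() >= k:
        raise ValueError("anomaly indices out of range")
    expanded = (at[:, None] + np.arange(-es, es + 1)[None, :]).ravel()
    expanded = expanded[(expanded >= 0) & (expanded < k)]
    return np.unique(expanded)


def mitigator_vector(
    a: np.ndarray,
    medoid: np.ndarray,
    buffer: SlidingBuffer,
    mode: str = "per_dimension",
) -> np.ndarray:
    """Attenuation factors in [0, 1] from the distance of ``a`` to the medoid.

    ``mtg = 1 - d(a, medoid) / max_{v in buffer} d(v, medoid)`` clipped to
    [0, 1]; in per-dimension mode both the distance and the buffer maximum are
    taken scale-wise, so different frequency bands can be attenuated with
    different strengths.  A dimension in which the buffer never deviates from
    the medoid gives no evidence, so its factor stays 1.
    """
    a = np.asarray(a, dtype=np.float64)
    medoid = np.asarray(medoid, dtype=np.float64)
    if a.shape != medoid.shape:
        raise ValueError("slice vector and medoid dimensions differ")
    if mode == "per_dimension":
        max_dev = buffer.max_abs_deviation(medoid)
        mtg = np.ones_like(a)
        nz = max_dev > 0
        mtg[nz] = 1.0 - np.abs(a - medoid)[nz] / max_dev[nz]
    elif mode == "scalar":
        max_dist = buffer.max_distance(medoid)
        ratio = 0.0 if max_dist == 0 else float(np.linalg.norm(a - medoid)) / max_dist
        mtg = np.full_like(a, 1.0 - ratio)
    else:
        raise ValueError(f"unknown mitigator mode: {mode!r}")
    return np.clip(mtg, 0.0, 1.0)


def apply_mitigation(raw_slice: np.ndarray, mtg: np.ndarray) -> np.ndarray:
    """Hadamard product of a raw coefficient slice with its mitigator."""
    raw_slice = np.asarray(raw_slice, dtype=np.float64)
    mtg = np.asarray(mtg, dtype=np.float64)
    if raw_slice.shape != mtg.shape:
        raise ValueError("slice and mitigator dimensions differ")
    if np.any(mtg < 0.0) or np.any(mtg > 1.0):
        raise ValueError("mitigator values must lie in [0, 1]")
    return raw_slice * mtg


def process_window(
    w: Window,
    prev: Window | None,
    buffer: SlidingBuffer,
    cfg: FrameworkConfig,
    forest_seed: int | None = None,
) -> tuple[Window, AnomalyRecord, SlidingBuffer]:
    """Run one window through the denoiser, updating the buffer in place.

    During warm-up (buffer not yet full) the window passes through untouched;
    in either case its pre-denoising normalized slice vectors are pushed into
    the buffer afterwards, so detection for window ``c`` always trains on the
    ``Bs`` windows strictly before ``c``.
    """
    if w.n != cfg.window_samples:
        raise ValueError(
            f"window has {w.n} samples, config requires {cfg.window_samples}"
        )
    coeffs = decompose_window(w, prev, cfg.wavelet)
    scal = build_scaleogram(coeffs)
    norm = normalize_scaleogram(scal)
    cols_norm = np.ascontiguousarray(norm.columns())
    record = AnomalyRecord(window_index=w.index)
    out = w

    if buffer.full:
        seed = cfg.seed if forest_seed is None else forest_seed
        forest = ExtendedIsolationForest(
            n_trees=cfg.if_trees, subsample=cfg.if_subsample, seed=seed
        ).fit(buffer.columns())
        scores = forest.score(cols_norm)
        record.scores = scores
        record.at = np.flatnonzero(scores > cfg.anomaly_threshold)
        record.at_exp = expand_anomalies(record.at, cfg.expansion_step, cfg.k)
        if record.at_exp.size:
            medoid = buffer.medoid()
            denoised_matrix = scal.matrix.copy()
            for t in record.at_exp:
                mtg = mitigator_vector(cols_norm[t], medoid, buffer, cfg.mitigator_mode)
                record.mitigators[int(t)] = mtg
                denoised_matrix[:, t] = apply_mitigation(scal.matrix[:, t], mtg)
            denoised_scal = Scaleogram(denoised_matrix, scal.n_levels, normalized=False)
            denoised_coeffs = collapse_scaleogram(denoised_scal, coeffs.conc_context)
            out = reconstruct(denoised_coeffs)

    buffer.push(cols_norm)
    return out, record, buffer


def denoise_stream(
    data: np.ndarray, cfg: FrameworkConfig
) -> tuple[np.ndarray, list[list[AnomalyRecord]]]:
    """Denoise a (channels x samples) matrix channel by channel.

    Each channel gets its own buffer and forests; a trailing partial window is
    passed through unmodified.  Returns the denoised matrix (same shape) and
    one list of :class:`AnomalyRecord` per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.size == 0:
        raise ValueError("empty data")
    n_samples = data.shape[1]
    n = cfg.window_samples
    if n_samples < n:
        raise ValueError("need at least one full window of samples")
    n_windows = n_samples // n
    out = data.copy()
    records: list[list[AnomalyRecord]] = []
    root = np.random.SeedSequence(cfg.seed)
    for ch in range(data.shape[0]):
        rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
        buffer = SlidingBuffer(cfg.buffer_windows)
        prev: Window | None = None
        ch_records: list[AnomalyRecord] = []
        for c in range(n_windows):
            seed = int(rng.integers(0, 2**31 - 1))
            w = Window(data[ch, c * n : (c + 1) * n], index=c, sr=cfg.sr_hz)
            denoised, record, buffer = process_window(w, prev, buffer, cfg, seed)
            out[ch, c * n : (c + 1) * n] = denoised.samples
            ch_records.append(record)
            prev = w  # the raw (as-recorded) window supplies the next left context
        records.append(ch_records)
    return out, records
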