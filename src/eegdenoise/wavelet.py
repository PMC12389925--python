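"""Windowed discrete wavelet decomposition for streaming EEG.

The stream is processed one fixed-length window at a time.  To keep the left
edge of the current window out of the wavelet cone of influence, the window is
concatenated to the *previous* raw window before decomposition; the right edge
(for which no future data exists) and the cold-start left edge are extended by
smooth (first-derivative) padding.  The padded signal is decomposed with a
decimated, periodized multiresolution filter bank so that every level holds
exactly half the coefficients of the level below, and the coefficients whose
time centres fall inside the current window are retained.

Coefficients are rearranged into a *scaleogram*: a ``(levels + 1) x k`` matrix
(detail levels 1..M plus the approximation row) in which level-``m``
coefficients are replicated ``2**(m-1)`` times so that all rows share one time
axis of ``k = n/2`` slices.  Columns of the (optionally level-normalized)
scaleogram are the feature vectors consumed by the anomaly detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt

__all__ = [
    "Window",
    "ConcContext",
    "LevelCoeffs",
    "Scaleogram",
    "max_level",
    "decompose_window",
    "build_scaleogram",
    "normalize_scaleogram",
    "denormalize_scaleogram",
    "collapse_scaleogram",
    "reconstruct",
]


@dataclass(frozen=True)
class Window:
    """One fixed-length segment of a single EEG channel (amplitudes in µV)."""

    samples: np.ndarray
    index: int = 0
    sr: float = 1024.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("window samples must be a non-empty 1-D array")
        if self.sr <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class ConcContext:
    """Full (untrimmed) coefficient arrays of the padded concatenated input.

    ``coeff_arrays`` is in pywt ``wavedec`` order: ``[cA_M, cD_M, ..., cD_1]``.
    ``slices[i]`` gives the index range, within ``coeff_arrays[i]``, of the
    coefficients whose time centres lie inside the current window.  Keeping the
    whole padded context allows exact inversion after coefficient edits.
    """

    coeff_arrays: list[np.ndarray]
    slices: list[slice]
    wavelet: str
    n: int
    sr: float
    index: int


@dataclass
class LevelCoeffs:
    """Trimmed DWT coefficients of the current window.

    ``details[m-1]`` holds the level-``m`` detail coefficients (``n / 2**m`` of
    them); ``approximation`` the level-``M`` approximation (same length as the
    level-``M`` details).
    """

    details: list[np.ndarray]
    approximation: np.ndarray
    wavelet_name: str
    conc_context: ConcContext | None = None

    @property
    def n_levels(self) -> int:
        return len(self.details)


@dataclass
class Scaleogram:
    """``(M + 1) x k`` coefficient matrix; columns are time slices.

    Rows 0..M-1 are detail levels 1..M (level-``m`` values replicated
    ``2**(m-1)`` times); row M is the approximation (replicated ``2**(M-1)``
    times).  ``normalized`` marks whether row ``m`` has been divided by
    ``2**m`` (approximation row by ``2**M``).
    """

    matrix: np.ndarray
    n_levels: int
    normalized: bool = False

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def columns(self) -> np.ndarray:
        """Time-slice vectors as rows of a ``k x (M+1)`` array."""
        return self.matrix.T


def max_level(n: int, wavelet: str) -> int:
    """Deepest level with at least one valid coefficient: floor(log2(n/(L-1)))."""
    filt_len = pywt.Wavelet(wavelet).dec_len
    if n < filt_len:
        raise ValueError(f"window of {n} samples is shorter than the {wavelet} filter")
    return int(math.floor(math.log2(n / (filt_len - 1))))


def _check_wavelet(name: str) -> pywt.Wavelet:
    try:
        wav = pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet name: {name!r}") from exc
    if not wav.orthogonal:
        raise ValueError(f"wavelet {name!r} is not orthogonal")
    return wav


def decompose_window(
    current: Window, previous: Window | None = None, wavelet: str = "db4"
) -> LevelCoeffs:
    """Decompose ``current`` with left-context concatenation and edge padding.

    The previous raw window (when present) supplies the left context so the
    current window's left edge sits in the middle of the transformed signal;
    otherwise (cold start) the left side is smooth-padded.  The right side is
    always smooth-padded by one window length.  The transform is periodized on
    the padded signal, whose length is a multiple of ``2**M``, so level ``m``
    lengths halve exactly; the returned coefficients are trimmed to the
    ``n / 2**m`` whose time centres (coefficient ``j`` maps to sample
    ``j * 2**m``) fall inside the current window.
    """
    _check_wavelet(wavelet)
    n = current.n
    levels = max_level(n, wavelet)
    if levels < 1:
        raise ValueError("window too short for one decomposition level")
    if n % (1 << levels) != 0:
        raise ValueError(
            f"window length {n} is not a multiple of 2**M = {1 << levels} "
            f"required by the decimated transform (choose a power-of-2 length)"
        )
    if previous is not None:
        if previous.n != n:
            raise ValueError("previous window must have the same length")
        if previous.sr != current.sr:
            raise ValueError("previous window must have the same sampling rate")
        conc = np.concatenate([previous.samples, current.samples])
        padded = pywt.pad(conc, (0, n), mode="smooth")
    else:
        padded = pywt.pad(current.samples, (n, n), mode="smooth")

    coeff_arrays = pywt.wavedec(padded, wavelet, mode="periodization", level=levels)
    # padded layout: [left context | current window | right pad], each n samples
    slices: list[slice] = [slice(n >> levels, (2 * n) >> levels)]  # cA_M
    for m in range(levels, 0, -1):  # cD_M .. cD_1
        slices.append(slice(n >> m, (2 * n) >> m))
    ctx = ConcContext(
        coeff_arrays=[np.asarray(c) for c in coeff_arrays],
        slices=slices,
        wavelet=wavelet,
        n=n,
        sr=current.sr,
        index=current.index,
    )
    details = [coeff_arrays[levels - m + 1][slices[levels - m + 1]].copy() for m in range(1, levels + 1)]
    approximation = coeff_arrays[0][slices[0]].copy()
    return LevelCoeffs(details, approximation, wavelet, ctx)


def build_scaleogram(coeffs: LevelCoeffs) -> Scaleogram:
    """Replicate per-level coefficients onto the shared ``k = n/2`` time axis."""
    levels = coeffs.n_levels
    k = coeffs.details[0].size
    rows = []
    for m in range(1, levels + 1):
        d = coeffs.details[m - 1]
        if d.size * (1 << (m - 1)) != k:
            raise ValueError(
                f"level {m} holds {d.size} coefficients; expected {k >> (m - 1)}"
            )
        rows.append(np.repeat(d, 1 << (m - 1)))
    if coeffs.approximation.size != coeffs.details[-1].size:
        raise ValueError("approximation length must match the deepest detail level")
    rows.append(np.repeat(coeffs.approximation, 1 << (levels - 1)))
    return Scaleogram(np.vstack(rows), n_levels=levels, normalized=False)


def _level_factors(n_levels: int) -> np.ndarray:
    # detail level m is scaled by 2**m; the approximation row by 2**M
    return np.array([2.0**m for m in range(1, n_levels + 1)] + [2.0**n_levels])


def normalize_scaleogram(s: Scaleogram) -> Scaleogram:
    """Divide row ``m`` by ``2**m`` (approximation row by ``2**M``).

    Equalizes coefficient magnitudes across scales before anomaly detection;
    the normalized matrix is never fed back to the inverse transform.
    """
    if s.normalized:
        raise ValueError("scaleogram is already normalized")
    factors = _level_factors(s.n_levels)
    return Scaleogram(s.matrix / factors[:, None], s.n_levels, normalized=True)


def denormalize_scaleogram(s: Scaleogram) -> Scaleogram:
    """Exact inverse of :func:`normalize_scaleogram`."""
    if not s.normalized:
        raise ValueError("scaleogram is not normalized")
    factors = _level_factors(s.n_levels)
    return Scaleogram(s.matrix * factors[:, None], s.n_levels, normalized=False)


def collapse_scaleogram(s: Scaleogram, ctx: ConcContext) -> LevelCoeffs:
    """Undo the replication and write coefficients back into the full context.

    Takes the first value of every run of ``2**(m-1)`` replicated entries at
    level ``m``.  The returned :class:`LevelCoeffs` carries a copy of ``ctx``
    with only the current window's index ranges overwritten, ready for exact
    inversion.  Rejects normalized input: normalized coefficients would corrupt
    the inverse transform.
    """
    if s.normalized:
        raise ValueError(
            "cannot collapse a normalized scaleogram: denoising and "
            "reconstruction operate on non-normalized coefficients"
        )
    levels = s.n_levels
    if s.matrix.shape[0] != levels + 1:
        raise ValueError("scaleogram row count inconsistent with level count")
    details = [s.matrix[m - 1, :: 1 << (m - 1)].copy() for m in range(1, levels + 1)]
    approximation = s.matrix[levels, :: 1 << (levels - 1)].copy()
    new_arrays = [a.copy() for a in ctx.coeff_arrays]
    new_arrays[0][ctx.slices[0]] = approximation
    for m in range(1, levels + 1):
        i = levels - m + 1  # cD_m position in wavedec order
        new_arrays[i][ctx.slices[i]] = details[m - 1]
    new_ctx = replace(ctx, coeff_arrays=new_arrays)
    return LevelCoeffs(details, approximation, ctx.wavelet, new_ctx)


def reconstruct(coeffs: LevelCoeffs) -> Window:
    """Inverse DWT of the full padded context, sliced to the current window."""
    ctx = coeffs.conc_context
    if ctx is None:
        raise ValueError("reconstruction requires the decomposition context")
    rec = pywt.waverec(ctx.coeff_arrays, ctx.wavelet, mode="periodization")
    samples = rec[ctx.n : 2 * ctx.n]
    return Window(samples=samples, index=ctx.index, sr=ctx.sr)
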