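"""Recording I/O: EDF/BDF reading (via mne) and a plain matrix dialect.

The matrix dialect is a raw little-endian float64 file (channels x samples,
row-major) with a JSON sidecar (same stem, ``.json``) holding the sampling
rate, channel names and free-form provenance.  It is the write format of
choice here; EDF/BDF are supported read-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_recording", "write_recording"]


@dataclass
class Recording:
    """In-memory multi-channel recording, amplitudes in µV."""

    data: np.ndarray  # channels x samples
    sr_hz: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sr_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal the channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sr_hz


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_edf(path: Path, fmt: str) -> Recording:
    import mne

    reader = mne.io.read_raw_bdf if fmt == "bdf" else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return Recording(
        data=raw.get_data() * 1e6,  # mne returns Volts
        sr_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        meta={"source": str(path), "format": fmt},
    )


def _read_matrix(path: Path) -> Recording:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(f"matrix sidecar {sidecar} is missing")
    info = json.loads(sidecar.read_text())
    n_ch, n_s = int(info["n_channels"]), int(info["n_samples"])
    data = np.fromfile(path, dtype="<f8")
    if data.size != n_ch * n_s:
        raise ValueError(
            f"{path} holds {data.size} values; sidecar promises {n_ch} x {n_s}"
        )
    return Recording(
        data=data.reshape(n_ch, n_s),
        sr_hz=float(info["sr_hz"]),
        channel_names=list(info["channel_names"]),
        meta=info.get("meta", {}),
    )


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Load a recording; format inferred from the suffix unless given.

    ``fmt`` is one of ``edf``, ``bdf`` or ``matrix`` (raw float64 + JSON
    sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".edf": "edf", ".bdf": "bdf"}.get(path.suffix.lower(), "matrix")
    if fmt in ("edf", "bdf"):
        return _read_edf(path, fmt)
    if fmt == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format: {fmt!r}")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write in the matrix dialect (raw float64 plus JSON sidecar)."""
    path = Path(path)
    np.ascontiguousarray(rec.data, dtype="<f8").tofile(path)
    info = {
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sr_hz": rec.sr_hz,
        "channel_names": rec.channel_names,
        "meta": rec.meta,
    }
    _sidecar(path).write_text(json.dumps(info, indent=2))
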