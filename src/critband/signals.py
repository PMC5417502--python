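"""The Signal container and plain-text / raw-binary signal IO."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np


@dataclass
class Signal:
    """A uniformly sampled real-valued series.

    Attributes
    ----------
    samples : 1-D float array of finite values.
    fs : sampling rate in Hz; 1.0 for unitless simulations.
    meta : provenance record (generator name, parameters, seed).
    """

    samples: np.ndarray
    fs: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("Signal requires a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


def save_signal(signal: Signal, path: str | Path) -> None:
    """Write a signal plus a JSON sidecar (``<path>.json``) with fs and metadata.

    ``.txt``/``.csv``/``.tsv`` suffixes write one sample per line in plain text;
    any other suffix writes raw little-endian float64.
    """
    path = Path(path)
    if path.suffix.lower() in {".txt", ".csv", ".tsv"}:
        np.savetxt(path, signal.samples, fmt="%.17g")
    else:
        signal.samples.astype("<f8").tofile(path)
    sidecar = {"fs": signal.fs, "meta": signal.meta, "n": int(signal.samples.size)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=str))


def load_signal(path: str | Path, fs: float | None = None) -> Signal:
    """Read a signal written by :func:`save_signal` (sidecar optional)."""
    path = Path(path)
    meta: dict[str, Any] = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fs = fs if fs is not None else info.get("fs", 1.0)
        meta = info.get("meta", {})
    if path.suffix.lower() in {".txt", ".csv", ".tsv"}:
        samples = np.loadtxt(path)
    else:
        samples = np.fromfile(path, dtype="<f8")
    return Signal(samples=np.atleast_1d(samples), fs=fs if fs is not None else 1.0, meta=meta)
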