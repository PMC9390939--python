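"""WAV, annotation-CSV and manifest I/O.

Waveforms interchange as mono RIFF WAV (float32 by default, PCM-16/24/32
accepted on read, integer encodings normalized to [-1, 1]).  Annotations
are CSV files with ``time_s,label`` columns (microsecond precision);
run manifests are plain JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .synthetic import AnnotatedSignal

__all__ = ["read_wav", "write_wav", "write_annotations", "read_annotations",
           "write_manifest"]

_INT_SCALE = {np.dtype("int16"): 2 ** 15 - 1, np.dtype("int32"): 2 ** 31 - 1,
              np.dtype("uint8"): 2 ** 7 - 1}

VALID_LABELS = {"S1", "S2"}


def read_wav(path) -> AnnotatedSignal:
    """Read a mono WAV file; integer samples are scaled to [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.ndim} "
                         "channels")
    if data.dtype in _INT_SCALE:
        scale = _INT_SCALE[data.dtype]
        samples = data.astype(float)
        if data.dtype == np.dtype("uint8"):
            samples = samples - 128.0
        samples /= scale
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return AnnotatedSignal(samples, float(fs))


def write_wav(signal: AnnotatedSignal, path, encoding: str = "float32"
              ) -> None:
    """Write a mono WAV (``float32`` or ``pcm16``)."""
    if encoding == "float32":
        wavfile.write(path, int(signal.fs),
                      signal.samples.astype(np.float32))
    elif encoding == "pcm16":
        peak = float(np.max(np.abs(signal.samples))) or 1.0
        scaled = np.clip(signal.samples / peak, -1.0, 1.0)
        wavfile.write(path, int(signal.fs),
                      np.round(scaled * (2 ** 15 - 1)).astype(np.int16))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


def write_annotations(events: list[tuple[float, str]], path) -> None:
    """CSV ``time_s,label`` with microsecond time precision."""
    with open(path, "w") as fh:
        fh.write("time_s,label\n")
        for t, label in events:
            if label not in VALID_LABELS:
                raise ValueError(f"unknown label {label!r}")
            fh.write(f"{t:.6f},{label}\n")


def read_annotations(path) -> list[tuple[float, str]]:
    """Read an annotation CSV; out-of-order rows are sorted with a
    warning."""
    events = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_s,label":
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            t_str, label = line.split(",")
            if label not in VALID_LABELS:
                raise ValueError(f"{path}: unknown label {label!r}")
            events.append((float(t_str), label))
    times = [t for t, _ in events]
    if times != sorted(times):
        warnings.warn(f"{path}: annotation rows out of order; sorting")
        events.sort(key=lambda e: e[0])
    return events


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
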