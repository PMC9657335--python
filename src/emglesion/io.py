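"""Reading and writing recordings and segment datasets.

Recordings are persisted one per delimited-text file: ``#``-prefixed header
lines carry the sampling rate, label and metadata tags, followed by one
sample per line.  The round trip is lossless to better than 1e-12 relative
(samples are written with 17 significant digits).  Whole segment datasets
use NumPy ``.npz`` containers.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic import EMGRecording, Label


def write_recording(path: str | os.PathLike, rec: EMGRecording) -> None:
    """Write one recording to a text file (header lines + one sample/line)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.sampling_rate!r}\n")
        fh.write(f"# label={int(rec.label)}\n")
        for key, value in rec.meta.items():
            fh.write(f"# {key}={value}\n")
        np.savetxt(fh, rec.samples, fmt="%.17g")


def read_recording(path: str | os.PathLike) -> EMGRecording:
    """Read a recording written by :func:`write_recording`."""
    fs = None
    label = None
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key == "fs":
                fs = float(value)
            elif key == "label":
                label = Label(int(value))
            else:
                meta[key] = value
    if fs is None or label is None:
        raise ValueError(f"{path}: missing fs or label header")
    samples = np.loadtxt(path, skiprows=header_lines, ndmin=1)
    return EMGRecording(samples=samples, sampling_rate=fs, label=label, meta=meta)


def write_dataset(directory: str | os.PathLike, recordings: Sequence[EMGRecording]) -> list[Path]:
    """Write a set of recordings as ``rec_00000.txt`` ... under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(recordings):
        p = directory / f"rec_{i:05d}.txt"
        write_recording(p, rec)
        paths.append(p)
    return paths


def read_dataset(directory: str | os.PathLike) -> list[EMGRecording]:
    """Read every ``rec_*.txt`` recording under ``directory``, sorted by name."""
    directory = Path(directory)
    return [read_recording(p) for p in sorted(directory.glob("rec_*.txt"))]
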