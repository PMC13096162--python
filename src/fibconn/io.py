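"""Recording container and plain-text serialization.

A recording is a dense sample-by-channel matrix with a JSON sidecar holding
the channel labels, sampling rate, units and provenance.  The matrix is
stored as a tab-delimited text file (rows = samples, columns = channels) so
that every artifact of the pipeline stays human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "write_recording", "read_recording"]


@dataclass
class Recording:
    data: np.ndarray  # (n_samples, n_channels), float
    fs: float  # Hz
    channel_labels: list[str]
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but "
                f"{len(self.channel_labels)} channel labels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def write_recording(rec: Recording, base_path) -> tuple[Path, Path]:
    """Write ``<base>.tsv`` (sample matrix) and ``<base>.json`` (sidecar)."""
    base = Path(base_path)
    mat_path = base.with_suffix(".tsv")
    meta_path = base.with_suffix(".json")
    np.savetxt(mat_path, rec.data, fmt="%.6f", delimiter="\t")
    sidecar = {
        "channel_labels": rec.channel_labels,
        "fs_hz": rec.fs,
        "units": rec.units,
        **rec.meta,
    }
    meta_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return mat_path, meta_path


def read_recording(base_path) -> Recording:
    base = Path(base_path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    data = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    labels = sidecar.pop("channel_labels")
    fs = sidecar.pop("fs_hz")
    units = sidecar.pop("units", "uV")
    return Recording(data=data, fs=fs, channel_labels=labels, units=units, meta=sidecar)
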