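"""Signal preprocessing: band-pass + resample, 10-s segmentation, automatic
artifact rejection, and ROI montage averaging.

The artifact screen applies four criteria to every channel of every
segment; a segment is discarded if any channel violates any criterion:

* gradient  – an absolute change above 10 µV per millisecond between two
  consecutive samples (scaled by the inter-sample interval);
* min–max   – a peak-to-peak difference above 100 µV within any 200 ms
  window;
* amplitude – any sample below −150 µV or above +150 µV;
* low activity – a peak-to-peak difference below 0.5 µV within any 100 ms
  window (flat or disconnected channels).

The criteria run fully automatically (no interactive review step).
Re-referencing against a standardized reference is not modelled; an
optional common-average reference is available instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .io import Recording

__all__ = [
    "RejectionCriteria",
    "DEFAULT_MONTAGE",
    "Segment",
    "bandpass_resample",
    "segment",
    "reject_artifacts",
    "apply_montage",
    "common_average_reference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RejectionCriteria:
    gradient_uv_per_ms: float = 10.0
    minmax_uv: float = 100.0
    minmax_window_ms: float = 200.0
    amp_min_uv: float = -150.0
    amp_max_uv: float = 150.0
    low_activity_uv: float = 0.5
    low_activity_window_ms: float = 100.0


#: Default 10–20 grouping of a 32-electrode cap into the eight analysis
#: regions.  This is a configurable convention, not a fixed property of the
#: method; any disjoint region -> electrode map may be passed instead.
DEFAULT_MONTAGE: dict[str, list[str]] = {
    "medial_frontal": ["Fp1", "Fp2", "Fz", "F3", "F4"],
    "left_central": ["FC1", "FC5", "C3"],
    "right_central": ["FC2", "FC6", "C4"],
    "left_temporal": ["F7", "FT9", "T7", "TP9"],
    "right_temporal": ["F8", "FT10", "T8", "TP10"],
    "left_parietal": ["CP1", "CP5", "P3", "P7"],
    "right_parietal": ["CP2", "CP6", "P4", "P8"],
    "medial_occipital": ["Pz", "O1", "Oz", "O2"],
}


@dataclass
class Segment:
    """A fixed-length epoch cut from a recording."""

    data: np.ndarray  # (n_samples, n_channels)
    fs: float
    index: int
    start_sample: int
    channel_labels: list[str]


def bandpass_resample(
    rec: Recording,
    low_hz: float = 0.1,
    high_hz: float | None = 64.0,
    target_fs: float = 128.0,
) -> Recording:
    """Zero-phase Butterworth band-pass, then polyphase resampling.

    ``high_hz=None`` applies a high-pass only (useful when the input is
    already band-limited, e.g. simulated directly at the working rate).
    """
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample: target {target_fs} Hz > input {rec.fs} Hz")
    if high_hz is not None and high_hz >= rec.fs / 2:
        raise ValueError(
            f"high cut-off {high_hz} Hz is at or above Nyquist ({rec.fs / 2} Hz)"
        )
    if high_hz is not None:
        sos = signal.butter(
            4, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos"
        )
    else:
        sos = signal.butter(4, low_hz, btype="highpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=0)
    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
        filtered = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=0)
    return Recording(
        data=filtered,
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        units=rec.units,
        meta=dict(rec.meta),
    )


def segment(rec: Recording, seg_s: float = 10.0, overlap: float = 0.0) -> list[Segment]:
    """Cut consecutive epochs of ``seg_s`` seconds; the remainder is dropped."""
    if overlap != 0.0:
        raise NotImplementedError("only non-overlapping segmentation is supported")
    n_per = int(round(seg_s * rec.fs))
    n_seg = rec.n_samples // n_per
    if n_seg == 0:
        logger.warning(
            "recording of %.1f s shorter than one %.1f s segment", rec.duration_s, seg_s
        )
        return []
    dropped = rec.n_samples - n_seg * n_per
    if dropped:
        logger.info("dropping %.2f s trailing remainder", dropped / rec.fs)
    return [
        Segment(
            data=rec.data[i * n_per : (i + 1) * n_per],
            fs=rec.fs,
            index=i,
            start_sample=i * n_per,
            channel_labels=list(rec.channel_labels),
        )
        for i in range(n_seg)
    ]


def _window_samples(ms: float, fs: float) -> int:
    return max(2, int(round(ms * fs / 1000.0)))


def _check_segment(seg: Segment, c: RejectionCriteria) -> list[dict]:
    """Return one violation record per (channel, criterion) that fires."""
    x = seg.data
    fs = seg.fs
    dt_ms = 1000.0 / fs
    violations = []

    grad = np.abs(np.diff(x, axis=0)) / dt_ms
    for ch in range(x.shape[1]):
        hits = np.nonzero(grad[:, ch] > c.gradient_uv_per_ms)[0]
        if hits.size:
            violations.append(
                {
                    "channel": seg.channel_labels[ch],
                    "criterion": "gradient",
                    "sample_index": int(hits[0]),
                    "value": float(grad[hits[0], ch]),
                }
            )

    w = _window_samples(c.minmax_window_ms, fs)
    if x.shape[0] >= w:
        win = sliding_window_view(x, w, axis=0)
        ptp = win.max(axis=-1) - win.min(axis=-1)  # (n_windows, n_channels)
        for ch in range(x.shape[1]):
            hits = np.nonzero(ptp[:, ch] > c.minmax_uv)[0]
            if hits.size:
                violations.append(
                    {
                        "channel": seg.channel_labels[ch],
                        "criterion": "minmax",
                        "sample_index": int(hits[0]),
                        "value": float(ptp[hits[0], ch]),
                    }
                )

    for ch in range(x.shape[1]):
        bad = (x[:, ch] < c.amp_min_uv) | (x[:, ch] > c.amp_max_uv)
        hits = np.nonzero(bad)[0]
        if hits.size:
            violations.append(
                {
                    "channel": seg.channel_labels[ch],
                    "criterion": "amplitude",
                    "sample_index": int(hits[0]),
                    "value": float(x[hits[0], ch]),
                }
            )

    w = _window_samples(c.low_activity_window_ms, fs)
    if x.shape[0] >= w:
        win = sliding_window_view(x, w, axis=0)
        ptp = win.max(axis=-1) - win.min(axis=-1)
        for ch in range(x.shape[1]):
            hits = np.nonzero(ptp[:, ch] < c.low_activity_uv)[0]
            if hits.size:
                violations.append(
                    {
                        "channel": seg.channel_labels[ch],
                        "criterion": "low_activity",
                        "sample_index": int(hits[0]),
                        "value": float(ptp[hits[0], ch]),
                    }
                )
    return violations


def reject_artifacts(
    segments: list[Segment], criteria: RejectionCriteria | None = None
) -> tuple[list[Segment], pd.DataFrame]:
    """Drop every segment in which any channel violates any criterion.

    Returns the kept segments and a log with one row per violating
    (segment, channel, criterion), carrying the first offending sample
    index and the measured value.
    """
    criteria = criteria or RejectionCriteria()
    kept = []
    log_rows = []
    for seg in segments:
        violations = _check_segment(seg, criteria)
        if violations:
            for v in violations:
                log_rows.append({"segment": seg.index, **v})
        else:
            kept.append(seg)
    log = pd.DataFrame(
        log_rows, columns=["segment", "channel", "criterion", "sample_index", "value"]
    )
    return kept, log


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over all channels (optional step)."""
    return Recording(
        data=rec.data - rec.data.mean(axis=1, keepdims=True),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        units=rec.units,
        meta=dict(rec.meta),
    )


def apply_montage(rec_or_segments, montage: dict[str, list[str]] | None = None):
    """Average electrodes within each region, then z-normalize per region.

    The member channels of each region are averaged sample-wise and the
    resulting regional series is standardized to mean 0, SD 1 over the
    whole recording (over all segments jointly when a segment list is
    given).  Returns a :class:`~fibconn.io.Recording` for recording input,
    or a list of :class:`Segment` for segment-list input.
    """
    montage = montage or DEFAULT_MONTAGE
    regions = list(montage)
    seen: set[str] = set()
    for region, electrodes in montage.items():
        if not electrodes:
            raise ValueError(f"region {region!r} has no electrodes")
        dup = seen.intersection(electrodes)
        if dup:
            raise ValueError(f"electrodes assigned to multiple regions: {sorted(dup)}")
        seen.update(electrodes)

    if isinstance(rec_or_segments, Recording):
        datas = [rec_or_segments.data]
        labels = rec_or_segments.channel_labels
    else:
        if not rec_or_segments:
            raise ValueError("no segments to montage")
        datas = [s.data for s in rec_or_segments]
        labels = rec_or_segments[0].channel_labels

    idx = {lab: i for i, lab in enumerate(labels)}
    for region, electrodes in montage.items():
        missing = [e for e in electrodes if e not in idx]
        if missing:
            raise ValueError(f"region {region!r}: electrode(s) {missing} not in recording")

    averaged = [
        np.column_stack(
            [d[:, [idx[e] for e in montage[r]]].mean(axis=1) for r in regions]
        )
        for d in datas
    ]
    concat = np.concatenate(averaged, axis=0)
    mu = concat.mean(axis=0)
    sd = concat.std(axis=0)
    if np.any(sd == 0):
        flat = [regions[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance region(s): {flat}")
    normed = [(a - mu) / sd for a in averaged]

    if isinstance(rec_or_segments, Recording):
        return Recording(
            data=normed[0],
            fs=rec_or_segments.fs,
            channel_labels=regions,
            units="z",
            meta=dict(rec_or_segments.meta),
        )
    return [
        Segment(
            data=n,
            fs=s.fs,
            index=s.index,
            start_sample=s.start_sample,
            channel_labels=regions,
        )
        for n, s in zip(normed, rec_or_segments)
    ]
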