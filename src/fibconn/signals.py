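"""Ground-truth VAR simulation of resting-state ROI signals, plus artifact
injection fixtures.

Pre- and post-task resting recordings are emulated as realizations of a
stationary vector autoregressive (VAR) process over the eight ROI signals of
the analysis montage.  Directed influence from ROI *x* to ROI *y* is encoded
as a non-zero lag coefficient A[lag][y][x]; a per-edge *modulator* makes
that coefficient depend on the participant's bilingual-experience (LSBQ
composite) score, by default as a baseline plus a Gaussian bump.  This gives
every downstream stage (preprocessing, Granger causality, factor-smooth
regression) a known ground truth to recover.

The generator works directly at ROI level (8 channels).  An optional linear
mixing mode spreads each ROI signal over several scalp channels so the
montage-averaging stage can be exercised as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording

__all__ = [
    "ROI_LABELS",
    "GaussianBump",
    "ConnectivityGroundTruth",
    "default_truth",
    "simulate_rest_recording",
    "ArtifactSpec",
    "inject_artifacts",
    "mix_to_channels",
]

#: The eight analysis regions of the montage.
ROI_LABELS = [
    "medial_frontal",
    "left_central",
    "right_central",
    "left_temporal",
    "right_temporal",
    "left_parietal",
    "right_parietal",
    "medial_occipital",
]


@dataclass(frozen=True)
class GaussianBump:
    """LSBQ-dependent edge coefficient: baseline + Gaussian bump.

    ``value(score) = baseline + height * exp(-(score - center)^2 / (2 width^2))``

    The bump shape lets the generator emulate connections whose strength
    peaks at mid levels of bilingual experience (center near a score of 10)
    as well as monotone-looking profiles (center at the top of the range).
    """

    baseline: float = 0.0
    height: float = 0.0
    center: float = 10.0
    width: float = 1.5

    def value(self, score: float) -> float:
        return self.baseline + self.height * math.exp(
            -((score - self.center) ** 2) / (2.0 * self.width**2)
        )

    def __call__(self, score: float) -> float:
        return self.value(score)


@dataclass
class ConnectivityGroundTruth:
    """Stationary VAR(p) ground truth over the eight ROI signals.

    ``coeffs`` has shape (p, n_roi, n_roi) indexed [lag][to][from];
    ``innovation_sd_uv`` scales the (independent) Gaussian innovations to
    microvolts.  ``edge_modulators`` maps ``(from_roi, to_roi)`` to a
    callable of the LSBQ score whose value is *added* to the lag-1
    coefficient for that directed edge.
    """

    roi_labels: list[str] = field(default_factory=lambda: list(ROI_LABELS))
    coeffs: np.ndarray | None = None  # (p, n, n)
    innovation_sd_uv: float = 10.0
    edge_modulators: dict[tuple[str, str], GaussianBump] = field(default_factory=dict)
    condition: str = "pre"

    def __post_init__(self):
        n = len(self.roi_labels)
        if self.coeffs is None:
            self.coeffs = 0.5 * np.eye(n)[None, :, :]
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1:] != (n, n):
            raise ValueError("coeffs must have shape (p, n_roi, n_roi)")
        for (src, dst) in self.edge_modulators:
            if src not in self.roi_labels or dst not in self.roi_labels:
                raise ValueError(f"modulated edge ({src!r}, {dst!r}) names unknown ROI")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def coeffs_for(self, lsbq: float) -> np.ndarray:
        """Lag coefficients with every modulated edge evaluated at ``lsbq``."""
        A = self.coeffs.copy()
        idx = {lab: i for i, lab in enumerate(self.roi_labels)}
        for (src, dst), mod in self.edge_modulators.items():
            A[0, idx[dst], idx[src]] += mod(lsbq)
        return A

    def spectral_radius(self, lsbq: float) -> float:
        A = self.coeffs_for(lsbq)
        p, n, _ = A.shape
        companion = np.zeros((n * p, n * p))
        companion[:n, :] = A.transpose(1, 0, 2).reshape(n, n * p)
        if p > 1:
            companion[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(companion))))


def default_truth(condition: str = "pre") -> ConnectivityGroundTruth:
    """Default study conditions for the connectivity ground truth.

    One directed edge (left central -> right parietal) carries an LSBQ bump
    centred at a score of 10 in both conditions, with the post-task bump
    twice the height of the pre-task one; the post-task condition adds a
    second modulated edge (medial frontal -> medial occipital).  All other
    ROI signals are independent AR(1) processes.
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    mods = {
        ("left_central", "right_parietal"): GaussianBump(
            baseline=0.0,
            height=0.25 if condition == "pre" else 0.5,
            center=10.0,
            width=1.5,
        )
    }
    if condition == "post":
        mods[("medial_frontal", "medial_occipital")] = GaussianBump(
            baseline=0.0, height=0.4, center=10.0, width=1.5
        )
    return ConnectivityGroundTruth(edge_modulators=mods, condition=condition)


def simulate_rest_recording(
    profile,
    truth: ConnectivityGroundTruth,
    duration_s: float = 300.0,
    fs: float = 128.0,
    seed: int | np.random.SeedSequence = 0,
) -> Recording:
    """Draw one resting recording from the VAR ground truth.

    The VAR coefficients are evaluated at the participant's LSBQ score via
    the edge modulators; a burn-in of max(200, 10 p) samples is discarded so
    the output is (approximately) a draw from the stationary distribution.
    Refuses non-stationary coefficient sets.
    """
    lsbq = profile["lsbq"] if isinstance(profile, (dict, pd.Series)) else profile.lsbq
    pid = (
        profile.get("participant_id", "")
        if isinstance(profile, (dict, pd.Series))
        else getattr(profile, "participant_id", "")
    )
    p = truth.order
    n_roi = len(truth.roi_labels)
    n_samples = int(round(duration_s * fs))
    if n_samples < 10 * p:
        raise ValueError("recording too short for the VAR order")
    rho = truth.spectral_radius(lsbq)
    if rho >= 1.0:
        raise ValueError(
            f"non-stationary ground truth at lsbq={lsbq:.2f}: "
            f"companion spectral radius {rho:.3f} >= 1"
        )
    A = truth.coeffs_for(lsbq)
    rng = np.random.default_rng(seed)
    burn = max(200, 10 * p)
    total = n_samples + burn
    x = np.zeros((total, n_roi))
    innov = rng.standard_normal((total, n_roi)) * truth.innovation_sd_uv
    for t in range(p, total):
        acc = innov[t]
        for lag in range(p):
            acc = acc + A[lag] @ x[t - 1 - lag]
        x[t] = acc
    return Recording(
        data=x[burn:],
        fs=fs,
        channel_labels=list(truth.roi_labels),
        units="uV",
        meta={"participant_id": str(pid), "condition": truth.condition},
    )


@dataclass(frozen=True)
class ArtifactSpec:
    """One synthetic artifact: kind, where, and how big.

    Kinds: ``spike`` (single-sample excursion), ``step`` (sustained offset
    from onset to end of window), ``flatline`` (constant value over the
    window), ``drift`` (linear ramp reaching ``amplitude_uv`` at window
    end).
    """

    kind: str
    channel: int
    start_s: float
    duration_s: float
    amplitude_uv: float


def inject_artifacts(
    rec: Recording, artifact_spec: list[ArtifactSpec], seed: int = 0
) -> tuple[Recording, pd.DataFrame]:
    """Insert artifacts at known sample indices; returns (recording, log)."""
    data = rec.data.copy()
    n = data.shape[0]
    log = []
    for spec in artifact_spec:
        a = int(round(spec.start_s * rec.fs))
        b = a + max(1, int(round(spec.duration_s * rec.fs)))
        if a < 0 or b > n:
            raise ValueError(
                f"artifact [{spec.start_s}, {spec.start_s + spec.duration_s}] s "
                f"outside recording of {n / rec.fs:.1f} s"
            )
        ch = spec.channel
        if spec.kind == "spike":
            data[a, ch] += spec.amplitude_uv
        elif spec.kind == "step":
            data[a:b, ch] += spec.amplitude_uv
        elif spec.kind == "flatline":
            data[a:b, ch] = spec.amplitude_uv
        elif spec.kind == "drift":
            data[a:b, ch] += np.linspace(0.0, spec.amplitude_uv, b - a)
        else:
            raise ValueError(f"unknown artifact kind {spec.kind!r}")
        log.append(
            {
                "kind": spec.kind,
                "channel": ch,
                "start_sample": a,
                "end_sample": b,
                "amplitude_uv": spec.amplitude_uv,
            }
        )
    out = Recording(
        data=data,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        units=rec.units,
        meta=dict(rec.meta),
    )
    return out, pd.DataFrame(log, columns=["kind", "channel", "start_sample", "end_sample", "amplitude_uv"])


def mix_to_channels(
    rec: Recording,
    montage: dict[str, list[str]],
    sensor_noise_sd_uv: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> Recording:
    """Spread each ROI signal over its montage electrodes (plus sensor noise).

    Inverse of the montage-averaging step up to the added noise; used to
    exercise :func:`fibconn.preprocess.apply_montage` on multi-channel
    input.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    cols: list[np.ndarray] = []
    roi_idx = {lab: i for i, lab in enumerate(rec.channel_labels)}
    for region, electrodes in montage.items():
        if region not in roi_idx:
            raise ValueError(f"montage region {region!r} not in recording")
        src = rec.data[:, roi_idx[region]]
        for el in electrodes:
            labels.append(el)
            cols.append(src + sensor_noise_sd_uv * rng.standard_normal(src.shape))
    return Recording(
        data=np.column_stack(cols),
        fs=rec.fs,
        channel_labels=labels,
        units=rec.units,
        meta=dict(rec.meta),
    )
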