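"""Pairwise time-domain Granger causality over ROI series.

For a directed pair x -> y, Granger causality is the log ratio of the
prediction-error variance of y from its own past alone (restricted AR(p))
to the prediction-error variance of y from the past of both y and x (full
bivariate VAR(p)):

    GC(x -> y) = ln( Var[y_t | y_past] / Var[y_t | y_past, x_past] )

Both models are fitted by least squares with an intercept, with residual
variances taken as RSS/N (the maximum-likelihood convention, so that
N * GC is the likelihood-ratio statistic, approximately chi-square with p
degrees of freedom under the null).  GC is non-negative up to estimation
noise and invariant to separate rescaling of x and y.

Recordings arrive as lists of retained segments; lagged regressors are
built strictly within segments so that the gaps left by artifact rejection
never create spurious transitions.  The model order is shared across all
pairs of a recording, selected by BIC on the full 8-dimensional VAR (capped
at ``max_order``) unless a fixed order is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarFit",
    "GcMatrix",
    "granger_pair",
    "granger_matrix",
    "select_order",
    "to_edge_list",
    "matrix_to_frame",
]

#: participant covariates carried onto the edge list
PROFILE_COLS = ["lsbq", "age", "l2_aoa", "education", "gender", "handedness", "task_order"]


def _as_segment_arrays(series) -> list[np.ndarray]:
    """Normalize input to a list of (n_samples, n_channels) float arrays."""
    if isinstance(series, np.ndarray):
        series = [series]
    elif hasattr(series, "data") and not isinstance(series, list):
        series = [series.data]
    out = []
    for s in series:
        arr = np.asarray(getattr(s, "data", s), dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        out.append(arr)
    return out


def _lagged_design(segments: list[np.ndarray], p: int, trim: int | None = None):
    """Stack within-segment lagged regressors.

    Returns (Y, X) where Y holds the current samples of all channels and X
    the p lags of all channels plus an intercept column.  ``trim`` discards
    the first ``trim`` samples of each segment instead of ``p`` so that
    model orders can be compared on an identical sample set.
    """
    t0 = p if trim is None else trim
    ys, xs = [], []
    for seg in segments:
        n = seg.shape[0]
        if n <= t0:
            continue
        ys.append(seg[t0:])
        xs.append(
            np.hstack([seg[t0 - lag : n - lag] for lag in range(1, p + 1)])
        )
    if not ys:
        raise ValueError(f"series too short for order {p}")
    Y = np.vstack(ys)
    X = np.vstack(xs)
    X = np.hstack([np.ones((X.shape[0], 1)), X])
    return Y, X


@dataclass
class VarFit:
    """Least-squares VAR fit: coefficients, residual covariance, sample size."""

    order: int
    coef: np.ndarray  # (n_regressors, n_channels), intercept first
    resid_cov: np.ndarray  # (n_channels, n_channels), ML normalization
    nobs: int

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("VAR order must be >= 1")


def _ols_fit(segments: list[np.ndarray], p: int, trim: int | None = None) -> VarFit:
    Y, X = _lagged_design(segments, p, trim=trim)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (constant or collinear channels?)")
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    cov = resid.T @ resid / Y.shape[0]
    return VarFit(order=p, coef=coef, resid_cov=np.atleast_2d(cov), nobs=Y.shape[0])


def select_order(series, max_order: int = 20) -> int:
    """Shared VAR order by BIC on the full channel set, evaluated on a
    common sample set (all models trimmed to ``max_order`` lost samples)."""
    segments = _as_segment_arrays(series)
    k = segments[0].shape[1]
    best_p, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        try:
            fit = _ols_fit(segments, p, trim=max_order)
        except ValueError:
            break
        n = fit.nobs
        sign, logdet = np.linalg.slogdet(fit.resid_cov)
        if sign <= 0:
            break
        n_params = k * (k * p + 1)
        bic = logdet + n_params * np.log(n) / n
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def granger_pair(x, y, order: int = 1) -> float:
    """GC(x -> y) for a pair of equal-length series (or segment lists)."""
    xs = _as_segment_arrays(x)
    ys = _as_segment_arrays(y)
    if len(xs) != len(ys) or any(a.shape[0] != b.shape[0] for a, b in zip(xs, ys)):
        raise ValueError("x and y must have matching segment lengths")
    total = sum(a.shape[0] for a in ys)
    if total < 10 * order:
        raise ValueError(f"series of {total} samples too short for order {order}")
    restricted = _ols_fit(ys, order)
    pairs = [np.hstack([b, a]) for a, b in zip(xs, ys)]  # columns: y, x
    full = _ols_fit(pairs, order)
    var_r = float(restricted.resid_cov[0, 0])
    var_f = float(full.resid_cov[0, 0])
    if var_f <= 0:
        raise ValueError("degenerate full-model residual variance")
    return float(np.log(var_r / var_f))


@dataclass
class GcMatrix:
    """Directed ROI x ROI Granger-causality values for one recording."""

    roi_labels: list[str]
    values: np.ndarray  # (n, n), diagonal NaN
    condition: str
    participant_id: str
    order: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def n_roi(self) -> int:
        return len(self.roi_labels)


def granger_matrix(
    roi_series,
    order_policy: int | str = "bic",
    max_order: int = 20,
    roi_labels: list[str] | None = None,
    condition: str = "",
    participant_id: str = "",
) -> GcMatrix:
    """All 56 ordered-pair GC values for one recording's retained segments."""
    segments = _as_segment_arrays(roi_series)
    if roi_labels is None:
        first = roi_series[0] if isinstance(roi_series, list) else roi_series
        roi_labels = list(getattr(first, "channel_labels", [])) or [
            f"ch{i}" for i in range(segments[0].shape[1])
        ]
    k = segments[0].shape[1]
    if k < 2:
        raise ValueError("need at least two series")
    if order_policy == "bic":
        p = select_order(segments, max_order=max_order)
    else:
        p = int(order_policy)
        if p < 1:
            raise ValueError("fixed order must be >= 1")
    values = np.full((k, k), np.nan)
    cols = [[seg[:, [i]] for seg in segments] for i in range(k)]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            values[i, j] = granger_pair(cols[i], cols[j], order=p)
    return GcMatrix(
        roi_labels=list(roi_labels),
        values=values,
        condition=condition,
        participant_id=participant_id,
        order=p,
    )


def matrix_to_frame(m: GcMatrix) -> pd.DataFrame:
    """8x8 CSV-ready frame with ROI header row/column, empty diagonal."""
    return pd.DataFrame(m.values, index=m.roi_labels, columns=m.roi_labels)


def to_edge_list(matrices: list[GcMatrix], cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-form table: one row per participant x condition x directed pair.

    Joins the participant covariates from the cohort table; refuses
    duplicate (participant, condition) matrices.
    """
    seen = set()
    profiles = cohort.set_index("participant_id")
    rows = []
    for m in matrices:
        key = (m.participant_id, m.condition)
        if key in seen:
            raise ValueError(f"duplicate matrix for participant/condition {key}")
        seen.add(key)
        if m.participant_id not in profiles.index:
            raise ValueError(f"participant {m.participant_id!r} not in cohort")
        prof = profiles.loc[m.participant_id]
        for i, src in enumerate(m.roi_labels):
            for j, dst in enumerate(m.roi_labels):
                if i == j:
                    continue
                row = {
                    "participant_id": m.participant_id,
                    "condition": m.condition,
                    "from_roi": src,
                    "to_roi": dst,
                    "gc": m.values[i, j],
                }
                for col in PROFILE_COLS:
                    if col in prof.index:
                        row[col] = prof[col]
                rows.append(row)
    return pd.DataFrame(rows)
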