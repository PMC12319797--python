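"""Signal conditioning and vertex functional-connectivity profiles.

A vertex's connectivity profile is the vector of Pearson correlations
between its time course and every cortical vertex's time course.  Profiles
are stored full-length with the self-correlation entry masked to 0, so that
profiles of different vertices live in the same vector space and can be
averaged and compared directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import TimeSeriesMatrix, ValidationError

log = logging.getLogger(__name__)

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityProfileMatrix:
    """ROI-vertex x cortex-vertex Pearson correlation matrix.

    ``roi_indices`` maps each row to its full-mesh vertex index; the entry
    of a vertex with itself is masked to exactly 0 (``self_policy``).
    """

    values: np.ndarray
    roi_indices: np.ndarray
    self_policy: str = "masked-to-zero"
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_indices = np.asarray(self.roi_indices, dtype=np.int64)
        if self.values.shape[0] != self.roi_indices.size:
            raise ValidationError("one profile row per ROI vertex required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profiles contain non-finite entries")
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")


def bandpass_filter(ts: TimeSeriesMatrix, low_hz: float, high_hz: float,
                    order: int = 4) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass applied per vertex.

    The default 4th-order filter is applied forward-backward (``filtfilt``),
    so the pass band is phase-preserving; DC is fully rejected.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValidationError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValidationError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4f} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds,
                        output="sos")
    out = signal.sosfiltfilt(sos, ts.data, axis=1)
    out = out - out.mean(axis=1, keepdims=True)
    return TimeSeriesMatrix(out, ts.tr_seconds, ts.subject_id, ts.session_id, ts.run_id)


def regress_nuisance(ts: TimeSeriesMatrix, regressors: np.ndarray) -> TimeSeriesMatrix:
    """OLS residual per vertex after projecting out regressors plus intercept."""
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.n_timepoints:
        if regressors.shape[1] == ts.n_timepoints:
            regressors = regressors.T
        else:
            raise ValidationError("regressor rows must equal timepoints")
    if regressors.shape[1] >= ts.n_timepoints:
        raise ValidationError("more regressors than timepoints")
    X = np.column_stack([np.ones(ts.n_timepoints), regressors])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        log.warning("rank-deficient nuisance matrix; using pseudoinverse")
    beta = np.linalg.pinv(X) @ ts.data.T
    resid = ts.data - (X @ beta).T
    return TimeSeriesMatrix(resid, ts.tr_seconds, ts.subject_id, ts.session_id, ts.run_id)


def condition_runs(runs, low_hz: float = 0.01, high_hz: float = 0.08,
                   regressors=None) -> TimeSeriesMatrix:
    """Condition each run (band-pass, optional nuisance regression), then concatenate."""
    conditioned = []
    for run in runs:
        out = bandpass_filter(run, low_hz, high_hz)
        if regressors is not None:
            out = regress_nuisance(out, regressors)
        conditioned.append(out.data)
    first = runs[0]
    return TimeSeriesMatrix(
        np.concatenate(conditioned, axis=1),
        first.tr_seconds,
        first.subject_id,
        first.session_id,
        "concat",
    )


def connectivity_profiles(ts: TimeSeriesMatrix, roi_indices) -> ConnectivityProfileMatrix:
    """Pearson correlation of every ROI vertex with every cortical vertex.

    Zero-variance vertices are not dropped: their correlations are set to 0
    and the vertex is reported in the ``excluded`` list of the result.
    """
    roi_indices = np.asarray(roi_indices, dtype=np.int64)
    data = ts.data
    sd = data.std(axis=1)
    degenerate = sd == 0
    z = data - data.mean(axis=1, keepdims=True)
    safe_sd = np.where(degenerate, 1.0, sd)
    z = z / (safe_sd[:, None] * np.sqrt(data.shape[1]))
    corr = z[roi_indices] @ z.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[degenerate[roi_indices], :] = 0.0
    corr[:, degenerate] = 0.0
    corr[np.arange(roi_indices.size), roi_indices] = 0.0  # mask self entries
    excluded = np.flatnonzero(degenerate)
    if excluded.size:
        log.warning("zero-variance vertices flagged: %s", excluded.tolist())
    return ConnectivityProfileMatrix(corr, roi_indices, excluded=excluded)


def fisher_z(r):
    """Variance-stabilizing Fisher transform, atanh with clipping at 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValidationError("correlations must satisfy |r| <= 1")
    out = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    return out if out.ndim else float(out)
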