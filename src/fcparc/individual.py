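"""Iterative confidence-weighted adaptation of the group atlas to a subject.

Starting from reference signals (per-network mean time courses under the
group parcellation), each ROI vertex is reassigned to the network whose
reference it correlates with most strongly.  A confidence ratio — strongest
correlation divided by second strongest — selects the vertices that define
each network unambiguously; their average ("high-confidence signal") is
blended with the current reference to form the next iteration's reference.
Ten iterations of this loop yield a parcellation that respects the group
prior but follows the individual's own connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import Parcellation, TimeSeriesMatrix, ValidationError

log = logging.getLogger(__name__)

CONFIDENCE_THRESHOLD = 1.3
SECOND_CORR_FLOOR = 1e-6
N_ITERATIONS = 10


@dataclass
class ReferenceSignals:
    """K network time courses, each standardized to mean 0, sd 1."""

    signals: np.ndarray  # (K, T)
    k: int
    iteration: int = 0

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[0] != self.k:
            raise ValidationError("one signal row per network required")
        means = self.signals.mean(axis=1)
        sds = self.signals.std(axis=1)
        if np.any(np.abs(means) > 1e-8) or np.any(np.abs(sds - 1.0) > 1e-6):
            raise ValidationError("reference signals must be standardized")


@dataclass
class ConfidenceMap:
    """Per-vertex reassignment confidence: r_max / max(r_second, eps), >= 1."""

    confidence: np.ndarray
    best_label: np.ndarray
    second_label: np.ndarray
    flagged: np.ndarray = None  # zero-variance vertices


@dataclass
class IndividualizationResult:
    parcellation: Parcellation
    confidence: ConfidenceMap
    dice_trace: np.ndarray  # Dice between consecutive-iteration labelings


def _standardize(x, axis=-1):
    x = x - x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd), (sd == 0).squeeze()


def compute_reference_signals(ts_roi: TimeSeriesMatrix, parc: Parcellation,
                              previous: ReferenceSignals = None,
                              iteration: int = 0) -> ReferenceSignals:
    """Per-network standardized mean of standardized member time courses.

    An empty network inherits the previous iteration's signal; at
    initialization (no previous signals) this is an error, as is a network
    whose members cancel to a flat average.
    """
    if ts_roi.n_vertices != parc.n_roi:
        raise ValidationError("time series must be restricted to ROI vertices")
    z, _ = _standardize(ts_roi.data, axis=1)
    signals = np.zeros((parc.k, ts_roi.n_timepoints))
    for lab in range(1, parc.k + 1):
        members = parc.labels == lab
        if not members.any():
            if previous is None:
                raise ValidationError(f"network {lab} has no member vertices")
            signals[lab - 1] = previous.signals[lab - 1]
            continue
        mean = z[members].mean(axis=0)
        sd = mean.std()
        if sd < 1e-6:
            raise ValidationError(
                f"network {lab} average signal is degenerate (sd={sd:.2e})"
            )
        signals[lab - 1] = (mean - mean.mean()) / sd
    return ReferenceSignals(signals, parc.k, iteration=iteration)


def assign_by_correlation(ts_roi: TimeSeriesMatrix, refs: ReferenceSignals):
    """Reassign each ROI vertex to its maximally correlated reference signal.

    Ties go to the lowest label.  The confidence ratio floors a non-positive
    second correlation at 1e-6 (an uncontested winner is maximally
    confident); vertices whose own winning correlation is non-positive get
    confidence 1.  Zero-variance vertices get label 1, confidence 1, and are
    flagged.
    """
    z, degenerate = _standardize(ts_roi.data, axis=1)
    t = ts_roi.n_timepoints
    corr = (z @ refs.signals.T) / t  # refs already standardized
    order = np.argsort(-corr, axis=1, kind="stable")
    best = order[:, 0]
    second = order[:, 1]
    r_max = corr[np.arange(len(best)), best]
    r_second = corr[np.arange(len(best)), second]
    conf = r_max / np.maximum(r_second, SECOND_CORR_FLOOR)
    conf = np.where(r_max <= 0, 1.0, conf)
    labels = best + 1
    second_labels = second + 1
    degenerate = np.atleast_1d(degenerate)
    if degenerate.any():
        labels = np.where(degenerate, 1, labels)
        conf = np.where(degenerate, 1.0, conf)
        log.warning("zero-variance vertices assigned label 1: %s",
                    np.flatnonzero(degenerate).tolist())
    return labels, ConfidenceMap(conf, labels, second_labels,
                                 flagged=np.flatnonzero(degenerate))


def high_confidence_signal(ts_roi: TimeSeriesMatrix, labels, conf: ConfidenceMap,
                           refs: ReferenceSignals,
                           threshold: float = CONFIDENCE_THRESHOLD) -> np.ndarray:
    """Per-network standardized average over vertices exceeding the threshold.

    The inequality is strict: confidence exactly at the threshold is
    excluded.  A network with no qualifying vertex falls back to a copy of
    its current reference, which leaves the reference unchanged after
    averaging.
    """
    z, _ = _standardize(ts_roi.data, axis=1)
    out = refs.signals.copy()
    for lab in range(1, refs.k + 1):
        members = (np.asarray(labels) == lab) & (conf.confidence > threshold)
        if not members.any():
            continue
        mean = z[members].mean(axis=0)
        sd = mean.std()
        if sd < 1e-12:
            continue  # degenerate average: keep the reference
        out[lab - 1] = (mean - mean.mean()) / sd
    return out


def _dice_same_labels(a, b, k):
    vals = []
    for lab in range(1, k + 1):
        n1 = int(np.sum(a == lab))
        n2 = int(np.sum(b == lab))
        if n1 + n2 == 0:
            continue
        vals.append(2.0 * np.sum((a == lab) & (b == lab)) / (n1 + n2))
    return float(np.mean(vals))


def individualize(ts_roi: TimeSeriesMatrix, group_parc: Parcellation,
                  n_iter: int = N_ITERATIONS,
                  threshold: float = CONFIDENCE_THRESHOLD,
                  averaging: str = "current") -> IndividualizationResult:
    """Adapt the group parcellation to one subject's conditioned time series.

    Each iteration reassigns vertices by maximal correlation with the
    reference signals, extracts high-confidence network averages, and blends
    them equally with the reference.  ``averaging="current"`` blends with the
    running reference (the loop semantics); ``averaging="original"`` always
    blends with the initial group-derived reference, for sensitivity
    analysis.  Returns the final labels, final confidence map, and the Dice
    between consecutive iterations' labelings (length ``n_iter``).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if averaging not in ("current", "original"):
        raise ValidationError("averaging must be 'current' or 'original'")
    refs0 = compute_reference_signals(ts_roi, group_parc)
    refs = refs0
    prev_labels = group_parc.labels
    trace = []
    labels, conf = None, None
    for it in range(1, n_iter + 1):
        labels, conf = assign_by_correlation(ts_roi, refs)
        trace.append(_dice_same_labels(prev_labels, labels, group_parc.k))
        prev_labels = labels
        hc = high_confidence_signal(ts_roi, labels, conf, refs, threshold)
        anchor = refs0.signals if averaging == "original" else refs.signals
        blended = 0.5 * (hc + anchor)
        blended, flat = _standardize(blended, axis=1)
        if np.any(flat):  # cancellation: keep previous reference for that network
            blended[flat] = refs.signals[flat]
        refs = ReferenceSignals(blended, group_parc.k, iteration=it)
    parc = Parcellation(labels, group_parc.k, level="individual",
                        provenance=f"individualize n_iter={n_iter} thr={threshold} "
                                   f"avg={averaging}")
    return IndividualizationResult(parc, conf, np.asarray(trace))
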