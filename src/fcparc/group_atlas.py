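"""Group-level parcellation: spherical k-means on connectivity profiles.

The group atlas is built by averaging subjects' connectivity profiles and
clustering ROI vertices by the cosine similarity of their profiles, with
many random restarts; model order is chosen at interior local maxima of the
product of split-half Dice and silhouette; spatial clusters of 10 mm^2 or
smaller are absorbed into their neighborhood by majority vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .connectivity import ConnectivityProfileMatrix, condition_runs, connectivity_profiles
from .types import Parcellation, SurfaceMesh, ValidationError

log = logging.getLogger(__name__)

MAX_LLOYD_ITER = 300


@dataclass
class GroupAtlas:
    """Best-of-restarts spherical k-means solution."""

    parcellation: Parcellation
    centroids: np.ndarray  # (K, D), unit rows
    aggregate_distance: float  # sum over vertices of 1 - cos(profile, centroid)
    k: int
    seed: int
    n_restarts: int


def average_profiles(per_subject) -> ConnectivityProfileMatrix:
    """Element-wise mean of subjects' profile matrices (self entries stay 0)."""
    mats = list(per_subject)
    shape = mats[0].values.shape
    for m in mats[1:]:
        if m.values.shape != shape:
            raise ValidationError("profile matrices must share shape and vertex order")
        if not np.array_equal(m.roi_indices, mats[0].roi_indices):
            raise ValidationError("profile matrices must share ROI vertex order")
    mean = np.mean([m.values for m in mats], axis=0)
    return ConnectivityProfileMatrix(mean, mats[0].roi_indices)


def _normalize_rows(x):
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    flagged = np.flatnonzero(norms[:, 0] == 0)
    safe = np.where(norms == 0, 1.0, norms)
    return x / safe, flagged


def _lloyd(xn, k, rng, check_monotone=False):
    """One spherical k-means run; returns (labels, centroids, objective)."""
    n = xn.shape[0]
    centroids = xn[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    prev_obj = np.inf
    for _ in range(MAX_LLOYD_ITER):
        sims = xn @ centroids.T
        new_labels = np.argmax(sims, axis=1)
        # repair empty clusters by seizing the worst-fitting vertex
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmin(sims[np.arange(n), new_labels]))
                new_labels[worst] = c
                sims[worst, :] = 0.0
        obj = float(np.sum(1.0 - sims[np.arange(n), new_labels].clip(-1, 1)))
        if check_monotone and obj > prev_obj + 1e-9:
            raise AssertionError("aggregate distance increased across Lloyd iteration")
        prev_obj = obj
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = xn[labels == c]
            mean = members.mean(axis=0)
            norm = np.linalg.norm(mean)
            centroids[c] = mean / norm if norm > 0 else centroids[c]
    sims = xn @ centroids.T
    obj = float(np.sum(1.0 - sims[np.arange(n), labels].clip(-1, 1)))
    return labels, centroids, obj


def kmeans_cosine(profiles: ConnectivityProfileMatrix, k: int, n_restarts: int = 500,
                  seed: int = 0, check_monotone: bool = False) -> GroupAtlas:
    """Spherical k-means over profile rows, best of ``n_restarts`` random starts.

    Rows are L2-normalized; assignment is by maximal cosine similarity and
    centroids are normalized means of their members.  The restart with the
    smallest aggregate distance (sum of 1 - cosine to the assigned centroid)
    wins.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    x = profiles.values
    if x.shape[0] <= k:
        raise ValidationError("need more ROI vertices than clusters")
    xn, flagged = _normalize_rows(x)
    if flagged.size:
        log.warning("all-zero profile rows assigned by tie-break: %s", flagged.tolist())
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        labels, centroids, obj = _lloyd(xn, k, rng, check_monotone=check_monotone)
        if best is None or obj < best[2] - 1e-12:
            best = (labels, centroids, obj)
    labels, centroids, obj = best
    parc = Parcellation(labels + 1, k, level="group",
                        provenance=f"kmeans_cosine k={k} seed={seed} restarts={n_restarts}")
    return GroupAtlas(parc, centroids, obj, k, seed, n_restarts)


def silhouette_cosine(profiles, labels) -> float:
    """Mean Rousseeuw silhouette with cosine distance d = 1 - cos.

    a is the mean distance to the vertex's own cluster (self excluded), b the
    smallest mean distance to any other cluster; singletons and exact a=b=0
    ties score 0.
    """
    x = profiles.values if isinstance(profiles, ConnectivityProfileMatrix) else np.asarray(profiles, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette undefined for a single cluster")
    xn, _ = _normalize_rows(x)
    d = 1.0 - xn @ xn.T
    np.clip(d, 0.0, 2.0, out=d)
    n = x.shape[0]
    s = np.zeros(n)
    member = {c: labels == c for c in uniq}
    for i in range(n):
        own = member[labels[i]].copy()
        own[i] = False
        if not own.any():
            s[i] = 0.0  # singleton
            continue
        a = d[i, own].mean()
        b = min(d[i, member[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def match_labels(parc_a: Parcellation, parc_b: Parcellation):
    """Hungarian matching of parc_b's labels onto parc_a's.

    Returns ``(relabeled_b, mapping)`` where ``mapping[old_label] = new_label``
    maximizes total vertex overlap.  When parc_b has more labels than parc_a,
    the unmatched ones keep fresh labels beyond parc_a's range.
    """
    if parc_a.n_roi != parc_b.n_roi:
        raise ValidationError("parcellations must cover the same ROI")
    overlap = np.zeros((parc_a.k, parc_b.k), dtype=np.int64)
    for la, lb in zip(parc_a.labels, parc_b.labels):
        overlap[la - 1, lb - 1] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {}
    for r, c in zip(rows, cols):
        mapping[c + 1] = r + 1
    nxt = parc_a.k + 1
    for lb in range(1, parc_b.k + 1):
        if lb not in mapping:
            mapping[lb] = nxt
            nxt += 1
    new_labels = np.array([mapping[l] for l in parc_b.labels])
    relabeled = Parcellation(new_labels, max(parc_a.k, parc_b.k), level=parc_b.level,
                             provenance=parc_b.provenance + " [relabeled]")
    return relabeled, mapping


def split_half_dice(runs_by_subject: dict, mesh: SurfaceMesh, k: int, seed: int = 0,
                    n_restarts: int = 50, low_hz: float = 0.01, high_hz: float = 0.08) -> float:
    """Reliability of the group atlas from split-half run data.

    Each subject's runs are split in time (first half vs last half, the first
    half taking the extra timepoint for odd lengths), halves concatenated,
    and a group atlas built per half; the two atlases are label-matched and
    compared by network-mean Dice.
    """
    from .metrics import dice  # local import to avoid a cycle

    first_profiles, last_profiles = [], []
    roi = mesh.roi_indices
    for subject, runs in sorted(runs_by_subject.items()):
        firsts, lasts = [], []
        for run in runs:
            t = run.n_timepoints
            if t < 20:
                raise ValidationError("runs must have at least 20 timepoints to split")
            half = (t + 1) // 2
            from .types import TimeSeriesMatrix

            firsts.append(TimeSeriesMatrix(run.data[:, :half], run.tr_seconds,
                                           run.subject_id, run.session_id, run.run_id))
            lasts.append(TimeSeriesMatrix(run.data[:, half:], run.tr_seconds,
                                          run.subject_id, run.session_id, run.run_id))
        for half_runs, acc in ((firsts, first_profiles), (lasts, last_profiles)):
            ts = condition_runs(half_runs, low_hz, high_hz)
            acc.append(connectivity_profiles(ts, roi))
    atlas_a = kmeans_cosine(average_profiles(first_profiles), k, n_restarts, seed)
    atlas_b = kmeans_cosine(average_profiles(last_profiles), k, n_restarts, seed + 1)
    matched_b, _ = match_labels(atlas_a.parcellation, atlas_b.parcellation)
    return dice(atlas_a.parcellation, matched_b, matched=True).weighted_mean


def select_model_order(k_values, dice_values, silhouette_values):
    """K values at strict interior local maxima of Dice x silhouette.

    Endpoints are never selected; at a plateau the smaller K wins (the rise
    into the plateau counts, the flat continuation does not).
    """
    k_values = list(k_values)
    if len(k_values) < 3:
        raise ValidationError("need at least 3 model orders")
    product = np.asarray(dice_values, float) * np.asarray(silhouette_values, float)
    selected = []
    for i in range(1, len(k_values) - 1):
        if product[i] > product[i - 1] and product[i] >= product[i + 1]:
            selected.append(k_values[i])
            if product[i] == product[i + 1]:
                log.info("plateau at K=%s; smaller K selected", k_values[i])
    return selected


def reassign_small_clusters(parc: Parcellation, mesh: SurfaceMesh,
                            profiles: ConnectivityProfileMatrix,
                            min_area_mm2: float = 10.0,
                            max_passes: int = 100) -> Parcellation:
    """Absorb spatial clusters of ``min_area_mm2`` or smaller into their surround.

    A cluster is a connected component of same-labeled ROI vertices on the
    mesh graph.  Each vertex of a small component takes the most frequent
    label among its ROI neighbors; frequency ties are broken by the Pearson
    correlation between the vertex's connectivity profile and the mean
    profile of each tied network.
    """
    roi = mesh.roi_indices
    pos_of = {int(v): i for i, v in enumerate(roi)}
    labels = parc.labels.copy()
    for _ in range(max_passes):
        small = []
        for lab in range(1, parc.k + 1):
            verts = roi[labels == lab]
            for comp in mesh.components(verts):
                if mesh.vertex_area[comp].sum() <= min_area_mm2:
                    small.append(comp)
        if not small:
            break
        changed = False
        for comp in small:
            for v in comp:
                nb = [w for w in mesh.neighbors[v] if int(w) in pos_of]
                nb_labels = np.array([labels[pos_of[int(w)]] for w in nb])
                if nb_labels.size == 0:
                    continue
                counts = np.bincount(nb_labels, minlength=parc.k + 1)
                top = counts.max()
                tied = np.flatnonzero(counts == top)
                if tied.size == 1:
                    new = int(tied[0])
                else:
                    i = pos_of[int(v)]
                    best_r, new = -np.inf, int(tied[0])
                    for lab in tied:
                        members = np.flatnonzero(labels == lab)
                        members = members[members != i]
                        if members.size == 0:
                            continue
                        mean_profile = profiles.values[members].mean(axis=0)
                        r = np.corrcoef(profiles.values[i], mean_profile)[0, 1]
                        if r > best_r:
                            best_r, new = r, int(lab)
                if new != labels[pos_of[int(v)]]:
                    labels[pos_of[int(v)]] = new
                    changed = True
        if not changed:
            log.warning("small clusters remain but no reassignment possible")
            break
    return Parcellation(labels, parc.k, level=parc.level,
                        provenance=parc.provenance + " [small-clusters-reassigned]")
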