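"""Network-seeded whole-cortex connectivity maps and group inference.

For each network of a parcellation, the mean time course of its member
vertices is correlated with every cortical vertex, Fisher-transformed, and
tested across subjects with a one-sample t-test; multiple comparisons are
handled with a sign-flip permutation cluster-extent correction.  Maps of
adjacent networks are contrasted vertex-wise with Wilcoxon + BH.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .connectivity import fisher_z
from .stats import bh_adjust
from .types import Parcellation, SurfaceMesh, TimeSeriesMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ClusterTable:
    """Supra-threshold clusters with extents and corrected p-values."""

    clusters: list = field(default_factory=list)
    # each: dict(id, vertices, extent, peak_vertex, p_corrected, significant)
    null_max_extent: np.ndarray = None
    forming_threshold: float = 8.0


def seed_map(ts: TimeSeriesMatrix, parc: Parcellation, seed_label: int,
             roi_indices) -> np.ndarray:
    """Fisher-z connectivity of the seed network's mean signal with all vertices.

    The seed signal is the mean of the standardized member time courses;
    seed members themselves are included in the map (their values sit near
    the atanh clipping bound).
    """
    roi_indices = np.asarray(roi_indices, dtype=np.int64)
    members = roi_indices[parc.labels == seed_label]
    if members.size == 0:
        raise ValidationError(f"seed network {seed_label} is empty")
    x = ts.data[members]
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    x = x / np.where(sd == 0, 1.0, sd)
    seed_signal = x.mean(axis=0)
    seed_signal = seed_signal - seed_signal.mean()
    s_sd = seed_signal.std()
    if s_sd == 0:
        raise ValidationError("seed signal is degenerate")
    seed_signal /= s_sd
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    v_sd = data.std(axis=1)
    safe = np.where(v_sd == 0, 1.0, v_sd)
    r = (data @ seed_signal) / (safe * ts.n_timepoints)
    r[v_sd == 0] = 0.0
    return fisher_z(np.clip(r, -1.0, 1.0))


def group_onesample(maps: np.ndarray):
    """Per-vertex one-sample t across subjects; zero-sd vertices are masked.

    Returns (t_map with NaN where undefined, valid_mask).
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    valid = sd > 0
    t = np.full(maps.shape[1], np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    return t, valid


def _components_from_mask(mask, neighbors):
    """Connected components of the supra-threshold vertex set (BFS)."""
    idx = np.flatnonzero(mask)
    comps, seen = [], set()
    in_mask = set(int(i) for i in idx)
    for start in idx:
        start = int(start)
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in neighbors[v]:
                w = int(w)
                if w in in_mask and w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(np.array(comp))
    return comps


def cluster_extent_correct(maps: np.ndarray, mesh: SurfaceMesh,
                           forming_threshold: float = 8.0, n_perm: int = 5000,
                           seed: int = 0, alpha: float = 0.05):
    """Sign-flip permutation cluster-extent correction of a one-sample t map.

    Clusters are connected components of |t| > ``forming_threshold`` on the
    mesh graph; cluster extent is surface area (mm², summed vertex areas),
    the natural size measure on a mesh.  The null distribution of the
    maximum cluster extent is built by randomly flipping subject map signs;
    a cluster is significant when its add-one corrected p-value
    (1 + #{null >= extent}) / (1 + n_perm) is <= ``alpha``.
    Returns (significant_mask, ClusterTable).
    """
    maps = np.asarray(maps, dtype=float)
    n_sub, n_vert = maps.shape
    t_obs, valid = group_onesample(maps)
    supra = valid & (np.abs(np.nan_to_num(t_obs)) > forming_threshold)
    obs_comps = _components_from_mask(supra, mesh.neighbors)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    ss = (maps**2).sum(axis=0)  # invariant under sign flips
    means = signs @ maps / n_sub
    var = (ss[None, :] - n_sub * means**2) / (n_sub - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n_sub)
    t_null = np.nan_to_num(t_null)
    area = mesh.vertex_area
    null_max = np.zeros(n_perm)
    supra_null = np.abs(t_null) > forming_threshold
    any_supra = supra_null.any(axis=1)
    for p_i in np.flatnonzero(any_supra):
        comps = _components_from_mask(supra_null[p_i], mesh.neighbors)
        null_max[p_i] = max(area[c].sum() for c in comps)

    table = ClusterTable(null_max_extent=null_max, forming_threshold=forming_threshold)
    mask = np.zeros(n_vert, dtype=bool)
    obs_comps = sorted(obs_comps, key=lambda c: area[c].sum(), reverse=True)
    for cid, comp in enumerate(obs_comps, start=1):
        extent = float(area[comp].sum())
        p = (1.0 + np.sum(null_max >= extent)) / (1.0 + n_perm)
        significant = p <= alpha
        peak = int(comp[np.argmax(np.abs(t_obs[comp]))])
        table.clusters.append({"id": cid, "vertices": comp,
                               "extent": extent, "n_vertices": len(comp),
                               "peak_vertex": peak, "p_corrected": float(p),
                               "significant": bool(significant)})
        if significant:
            mask[comp] = True
    return mask, table


def networks_adjacent(parc: Parcellation, mesh: SurfaceMesh, label_a: int,
                      label_b: int) -> bool:
    """Whether two networks share at least one mesh edge inside the ROI."""
    roi = mesh.roi_indices
    pos_of = {int(v): i for i, v in enumerate(roi)}
    for v in roi[parc.labels == label_a]:
        for w in mesh.neighbors[v]:
            j = pos_of.get(int(w))
            if j is not None and parc.labels[j] == label_b:
                return True
    return False


def adjacent_map_difference(maps_a: np.ndarray, maps_b: np.ndarray,
                            parc: Parcellation, mesh: SurfaceMesh,
                            label_a: int, label_b: int, alpha: float = 0.05):
    """Vertex-wise paired Wilcoxon between two adjacent networks' seed maps.

    Returns (adjusted p per vertex, significance mask at adjusted p < alpha).
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValidationError("seed-map sets must share subjects and vertices")
    if not networks_adjacent(parc, mesh, label_a, label_b):
        raise ValidationError(f"networks {label_a} and {label_b} are not adjacent")
    n_sub, n_vert = maps_a.shape
    if n_sub < 6:
        warnings.warn("fewer than 6 subjects: paired Wilcoxon is underpowered")
    p_raw = np.ones(n_vert)
    diffs = maps_a - maps_b
    for v in range(n_vert):
        d = diffs[:, v]
        if np.all(d == 0):
            continue
        p_raw[v] = sps.wilcoxon(d, zero_method="wilcox").pvalue
    adjusted, _ = bh_adjust(p_raw, alpha=alpha)
    return adjusted, adjusted < alpha
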