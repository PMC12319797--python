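"""Parcellation quality metrics: overlap, task alignment, homogeneity.

Conventions follow the field's printed formulas: the parcellation-level
Dice is the unweighted mean of network Dice coefficients, whereas the
homogeneity metrics weight each network by its vertex count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import fisher_z
from .types import (
    MetricReport,
    Parcellation,
    SimilarityMatrix,
    TaskZMap,
    TimeSeriesMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)


def dice(parc_a: Parcellation, parc_b: Parcellation, matched: bool = True) -> MetricReport:
    """Network-wise Dice = 2*V_overlap/(V1+V2); parcellation value = unweighted mean.

    With ``matched=False`` the labels of ``parc_b`` are first aligned to
    ``parc_a`` by Hungarian matching on overlap counts.
    """
    if parc_a.n_roi != parc_b.n_roi:
        raise ValidationError("parcellations must cover the same ROI")
    if not matched:
        from .group_atlas import match_labels

        parc_b, _ = match_labels(parc_a, parc_b)
    k = max(parc_a.k, parc_b.k)
    per = {}
    for lab in range(1, k + 1):
        a = parc_a.labels == lab
        b = parc_b.labels == lab
        v1, v2 = int(a.sum()), int(b.sum())
        if v1 + v2 == 0:
            continue
        if v1 == 0 or v2 == 0:
            log.info("network %d absent from one parcellation; Dice 0", lab)
        per[lab] = 2.0 * int((a & b).sum()) / (v1 + v2)
    mean = float(np.mean(list(per.values())))
    return MetricReport(per, mean, "dice")


def functional_inhomogeneity(zmap: TaskZMap, parc: Parcellation) -> MetricReport:
    """Size-weighted mean of within-network standard deviations of task z.

    sd uses the sample (N-1) denominator; single-vertex networks contribute
    sd 0 with a warning.  Lower values mean parcel boundaries align with the
    task topography.
    """
    if zmap.z.size != parc.n_roi:
        raise ValidationError("z-map must cover the ROI")
    per, sizes = {}, {}
    for lab in range(1, parc.k + 1):
        members = parc.labels == lab
        n = int(members.sum())
        if n == 0:
            continue
        if n == 1:
            warnings.warn(f"network {lab} has a single vertex; sd set to 0")
            per[lab] = 0.0
        else:
            per[lab] = float(np.std(zmap.z[members], ddof=1))
        sizes[lab] = n
    total = sum(sizes.values())
    weighted = sum(per[l] * sizes[l] for l in per) / total
    return MetricReport(per, float(weighted), "functional_inhomogeneity")


def connectional_homogeneity(ts_roi: TimeSeriesMatrix, parc: Parcellation) -> MetricReport:
    """Size-weighted mean of within-network pairwise Fisher-z correlations.

    For each network, Pearson correlations over all unordered distinct vertex
    pairs are Fisher-transformed and averaged; networks with fewer than two
    vertices are excluded from the weighted mean with a warning.
    """
    if ts_roi.n_vertices != parc.n_roi:
        raise ValidationError("time series must be restricted to ROI vertices")
    per, sizes = {}, {}
    for lab in range(1, parc.k + 1):
        members = np.flatnonzero(parc.labels == lab)
        if members.size < 2:
            if members.size:
                warnings.warn(f"network {lab} has < 2 vertices; excluded from mean")
            continue
        block = np.corrcoef(ts_roi.data[members])
        iu = np.triu_indices(members.size, k=1)
        per[lab] = float(np.mean(fisher_z(block[iu])))
        sizes[lab] = members.size
    total = sum(sizes.values())
    weighted = sum(per[l] * sizes[l] for l in per) / total
    return MetricReport(per, float(weighted), "connectional_homogeneity")


def percent_effect(effect_map: np.ndarray, parc: Parcellation) -> MetricReport:
    """Percent of the total task effect carried by each network.

    Signed network sums divided by the signed total, x100; with mixed signs
    individual networks can fall outside [0, 100] (logged), but the values
    always sum to 100.
    """
    effect_map = np.asarray(effect_map, dtype=float)
    if effect_map.size != parc.n_roi:
        raise ValidationError("effect map must cover the ROI")
    total = float(effect_map.sum())
    if abs(total) < 1e-12:
        raise ValidationError("total effect is zero; percentages undefined")
    per = {}
    for lab in range(1, parc.k + 1):
        per[lab] = 100.0 * float(effect_map[parc.labels == lab].sum()) / total
    if any(v < 0 or v > 100 for v in per.values()):
        log.info("mixed-sign effects: some network percentages fall outside [0, 100]")
    weighted = sum(per[l] * int((parc.labels == l).sum()) for l in per) / parc.n_roi
    return MetricReport(per, float(weighted), "percent_effect")


@dataclass
class VariabilitySummary:
    """Intra- vs inter-subject parcellation overlap distributions."""

    intra: dict  # subject -> Dice between its two sessions
    inter: dict  # subject -> mean Dice against all other subjects' sessions
    dice_matrix: SimilarityMatrix  # subject x subject, sessions pooled

    def paired_values(self):
        """(subjects, 2) array of (intra, inter) pairs for paired tests."""
        subs = sorted(self.intra)
        return np.array([[self.intra[s], self.inter[s]] for s in subs]), subs


def variability_summary(parcellations: dict, matched: bool = True) -> VariabilitySummary:
    """Intra-subject (session 1 vs 2) and inter-subject (all cross pairs) Dice.

    ``parcellations`` maps (subject_id, session_id) -> Parcellation.  The
    inter-subject value per subject pools all cross-subject session pairs.
    """
    subjects = sorted({s for s, _ in parcellations})
    sessions = {s: sorted(ses for s2, ses in parcellations if s2 == s) for s in subjects}
    intra = {}
    for s in subjects:
        if len(sessions[s]) < 2:
            warnings.warn(f"subject {s} lacks two sessions; skipped")
            continue
        a = parcellations[(s, sessions[s][0])]
        b = parcellations[(s, sessions[s][1])]
        intra[s] = dice(a, b, matched=matched).weighted_mean
    inter = {}
    pair_means = np.ones((len(subjects), len(subjects)))
    for i, s in enumerate(subjects):
        vals = []
        for j, s2 in enumerate(subjects):
            if s2 == s:
                continue
            cross = [
                dice(parcellations[(s, se1)], parcellations[(s2, se2)],
                     matched=matched).weighted_mean
                for se1 in sessions[s]
                for se2 in sessions[s2]
            ]
            pair_means[i, j] = np.mean(cross)
            vals.extend(cross)
        inter[s] = float(np.mean(vals))
    pair_means = 0.5 * (pair_means + pair_means.T)  # symmetrize pooled pairs
    sim = SimilarityMatrix(pair_means, "dice", subjects)
    return VariabilitySummary(intra, inter, sim)
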