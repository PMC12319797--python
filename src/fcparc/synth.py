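"""Synthetic surface-fMRI cohorts with known network ground truth.

The generator emulates the statistical structure the parcellation pipeline
assumes: a cohort of subjects sharing a group-level network layout on a
common spherical mesh, subject-specific boundary perturbations of that
layout, band-limited network latent time courses with controllable SNR and
inter-network correlation, task activation maps concentrated in chosen
networks, and smooth anatomy fields that are statistically independent of
network membership.

Defaults describe a small desk-scale cohort: 8 subjects, 2 sessions of one
200-timepoint run each at TR = 2.8 s, a level-3 icosphere (642 vertices,
~25% ROI cap), 4 true networks, 20% boundary jitter, SNR 1, and a modest
0.3 pairwise correlation among network latents (resting-state networks are
never orthogonal in practice).
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .types import Parcellation, SurfaceMesh, TaskZMap, TimeSeriesMatrix, ValidationError

log = logging.getLogger(__name__)

SPHERE_RADIUS_MM = 100.0
ROI_FRACTION = 0.25
ANALYSIS_BAND_HZ = (0.01, 0.08)


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters for one synthetic cohort."""

    n_subjects: int = 8
    sessions_per_subject: int = 2
    runs_per_session: int = 1
    timepoints_per_run: int = 200
    tr_seconds: float = 2.8
    k_true: int = 4
    mesh_subdivisions: int = 3
    boundary_jitter: float = 0.2
    snr: float = 1.0
    latent_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_subjects,
            self.sessions_per_subject,
            self.runs_per_session,
            self.timepoints_per_run,
        )
        if any(c < 1 for c in counts):
            raise ValidationError("all cohort counts must be >= 1")
        if not 0.0 <= self.boundary_jitter <= 0.5:
            raise ValidationError("boundary_jitter must lie in [0, 0.5]")
        if self.snr <= 0:
            raise ValidationError("snr must be positive")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValidationError("latent_correlation must lie in [0, 1)")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")


@dataclass
class GroundTruth:
    """True labels underlying a cohort: shared template plus per-subject variants."""

    group_template: Parcellation
    per_subject: dict
    effect_networks: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """A fully realized cohort: geometry, truth, and per-run time series."""

    spec: SyntheticCohortSpec
    mesh: SurfaceMesh
    truth: GroundTruth
    runs: dict  # (subject_id, session_id) -> list[TimeSeriesMatrix]
    cortex_labels: np.ndarray  # non-ROI network layout (0 on ROI vertices)
    anatomy: dict  # subject_id -> {"thickness": ..., "curvature": ...}

    @property
    def subject_ids(self) -> list:
        return sorted({s for s, _ in self.runs})

    def sessions(self, subject_id) -> list:
        return sorted({ses for s, ses in self.runs if s == subject_id})


def build_mesh(subdivisions: int) -> SurfaceMesh:
    """Icosphere mesh with a contiguous polar cap as the parcellation ROI.

    The icosahedron is subdivided ``subdivisions`` times and projected to a
    sphere of radius 100 mm, so every vertex that is not one of the 12
    originals has exactly six neighbors — the generic cortical-mesh case.
    """
    if subdivisions < 0:
        raise ValidationError("subdivisions must be >= 0")
    if subdivisions > 7:
        raise ValidationError("subdivisions > 7 would exceed the resource guard")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=SPHERE_RADIUS_MM)
    coords = np.asarray(ico.vertices, dtype=float)
    tris = np.asarray(ico.faces, dtype=np.int64)
    # contiguous cap: top quartile of vertices by z
    n_roi = max(1, int(round(ROI_FRACTION * len(coords))))
    z_order = np.argsort(-coords[:, 2], kind="stable")
    roi_mask = np.zeros(len(coords), dtype=bool)
    roi_mask[z_order[:n_roi]] = True
    return SurfaceMesh.from_arrays(coords, tris, roi_mask)


def _bfs_hops(start: np.ndarray, allowed: np.ndarray, neighbors) -> np.ndarray:
    """Multi-source hop distances on the subgraph induced by ``allowed``."""
    dist = np.full(len(neighbors), -1, dtype=np.int64)
    src = np.full(len(neighbors), -1, dtype=np.int64)
    queue = deque()
    for s_i, v in enumerate(np.atleast_1d(start)):
        dist[v] = 0
        src[v] = s_i
        queue.append(v)
    allowed_set = np.zeros(len(neighbors), dtype=bool)
    allowed_set[allowed] = True
    while queue:
        v = queue.popleft()
        for w in neighbors[v]:
            if allowed_set[w] and dist[w] < 0:
                dist[w] = dist[v] + 1
                src[w] = src[v]
                queue.append(w)
    return dist, src


def make_group_template(mesh: SurfaceMesh, k: int, seed: int) -> Parcellation:
    """K spatially contiguous patches grown from farthest-point-sampled seeds."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    roi = mesh.roi_indices
    if k > roi.size:
        raise ValidationError("k exceeds ROI vertex count")
    rng = np.random.default_rng(seed)
    seeds = [roi[rng.integers(roi.size)]]
    for _ in range(k - 1):  # farthest-point sampling by hop distance
        dist, _ = _bfs_hops(np.array(seeds), roi, mesh.neighbors)
        d_roi = dist[roi]
        seeds.append(roi[int(np.argmax(d_roi))])
    _, src = _bfs_hops(np.array(seeds), roi, mesh.neighbors)
    labels = src[roi] + 1
    return Parcellation(labels, k, level="group", provenance=f"template seed={seed}")


def perturb_individual(
    template: Parcellation, mesh: SurfaceMesh, boundary_jitter: float, seed: int
) -> Parcellation:
    """Subject-specific variant of the template obtained by boundary erosion.

    Labels are flipped only at network boundaries (a vertex with at least one
    ROI neighbor carrying another label), always to a neighboring network's
    label, until the disagreement fraction reaches the target.  Flips that
    would empty a network are skipped; if the target is unreachable the
    perturbation stops early with a warning.
    """
    if not 0.0 <= boundary_jitter <= 0.5:
        raise ValidationError("boundary_jitter must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    roi = mesh.roi_indices
    pos_of = {int(v): i for i, v in enumerate(roi)}
    labels = template.labels.copy()
    target = int(round(boundary_jitter * labels.size))
    sizes = np.bincount(labels, minlength=template.k + 1)
    flipped = 0
    stall = 0
    while flipped < target and stall < 20 * labels.size:
        stall += 1
        # candidates: still agree with template and sit on a boundary
        cand = []
        for i, v in enumerate(roi):
            if labels[i] != template.labels[i]:
                continue
            nb_labels = [
                labels[pos_of[int(w)]]
                for w in mesh.neighbors[v]
                if int(w) in pos_of and labels[pos_of[int(w)]] != labels[i]
            ]
            if nb_labels:
                cand.append((i, nb_labels))
        cand = [(i, nb) for i, nb in cand if sizes[labels[i]] > 1]
        if not cand:
            warnings.warn("boundary jitter target unreachable; stopped early")
            break
        i, nb_labels = cand[rng.integers(len(cand))]
        new = int(nb_labels[rng.integers(len(nb_labels))])
        sizes[labels[i]] -= 1
        sizes[new] += 1
        labels[i] = new
        flipped += 1
    return Parcellation(
        labels, template.k, level="individual", provenance=f"jitter seed={seed}"
    )


def _bandlimited_gaussian(rng, n_signals, n_t, tr, band=ANALYSIS_BAND_HZ):
    """Gaussian processes with support restricted to the analysis band."""
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # very short runs: keep the lowest non-DC bin
        keep[1] = True
    white = rng.standard_normal((n_signals, n_t))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_t, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _correlated_latents(rng, k, n_t, tr, rho):
    """K band-limited latents with pairwise correlation about ``rho``."""
    base = _bandlimited_gaussian(rng, k, n_t, tr)
    cov = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    chol = np.linalg.cholesky(cov)
    lat = chol @ base
    lat -= lat.mean(axis=1, keepdims=True)
    lat /= lat.std(axis=1, keepdims=True)
    return lat


def simulate_session(
    mesh: SurfaceMesh,
    truth: Parcellation,
    cortex_labels: np.ndarray,
    spec: SyntheticCohortSpec,
    seed: int,
    subject_id: str = "",
    session_id: str = "",
    run_id: str = "",
) -> TimeSeriesMatrix:
    """One run of vertex time courses driven by network latents.

    ROI vertices follow their true network latent plus white noise with
    sd = 1/snr (latents have unit sd).  Non-ROI cortex carries a second,
    independent K-network layout so that ROI connectivity profiles differ
    between networks, as in real cortex.  Each vertex course is demeaned.
    """
    n_t = spec.timepoints_per_run
    if n_t < 10:
        raise ValidationError("timepoints_per_run must be >= 10")
    rng = np.random.default_rng(seed)
    k = truth.k
    lat_roi = _correlated_latents(rng, k, n_t, spec.tr_seconds, spec.latent_correlation)
    lat_out = _correlated_latents(rng, k, n_t, spec.tr_seconds, spec.latent_correlation)
    data = np.empty((mesh.n_vertices, n_t))
    roi = mesh.roi_indices
    data[roi] = lat_roi[truth.labels - 1]
    out = np.flatnonzero(~mesh.roi_mask)
    data[out] = lat_out[cortex_labels[out] - 1]
    noise_sd = 1.0 / spec.snr
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    data -= data.mean(axis=1, keepdims=True)
    return TimeSeriesMatrix(
        data, spec.tr_seconds, subject_id=subject_id, session_id=session_id, run_id=run_id
    )


def simulate_task_zmap(
    truth: Parcellation,
    effect_networks,
    effect_size: float,
    noise_sd: float,
    seed: int,
    contrast_name: str = "synthetic-contrast",
    subject_id: str = "",
) -> TaskZMap:
    """Z-map with activation confined to the given networks plus Gaussian noise."""
    effect_networks = set(int(e) for e in effect_networks)
    if not effect_networks:
        raise ValidationError("effect_networks must be non-empty")
    if not effect_networks <= set(range(1, truth.k + 1)):
        raise ValidationError("effect_networks must be a subset of 1..K")
    rng = np.random.default_rng(seed)
    z = np.where(np.isin(truth.labels, list(effect_networks)), float(effect_size), 0.0)
    if noise_sd > 0:
        z = z + noise_sd * rng.standard_normal(z.shape)
    return TaskZMap(z, contrast_name=contrast_name, subject_id=subject_id)


def simulate_anatomy(mesh: SurfaceMesh, seed: int, n_smooth: int = 20):
    """Smooth anatomy fields independent of network membership.

    Returns per-vertex cortical thickness (mm; mean 2.5, sd 0.3) and
    curvature (1/mm; mean 0, sd 0.15), generated as neighbor-averaged
    Gaussian random fields on the mesh.
    """
    rng = np.random.default_rng(seed)

    def smooth_field(x):
        for _ in range(n_smooth):
            acc = x.copy()
            for i, nb in enumerate(mesh.neighbors):
                acc[i] += x[nb].sum()
            x = acc / (1.0 + np.array([len(nb) for nb in mesh.neighbors]))
        x = (x - x.mean()) / x.std()
        return x

    thickness = 2.5 + 0.3 * smooth_field(rng.standard_normal(mesh.n_vertices))
    curvature = 0.15 * smooth_field(rng.standard_normal(mesh.n_vertices))
    return thickness, curvature


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Full cohort realization: mesh, truth, runs, anatomy.

    All randomness descends from ``spec.seed`` through independent child
    seeds, so the cohort is bit-reproducible.
    """
    root = np.random.default_rng(spec.seed)
    mesh = build_mesh(spec.mesh_subdivisions)
    template = make_group_template(mesh, spec.k_true, seed=int(root.integers(2**31)))

    # independent K-network layout for non-ROI cortex
    out_idx = np.flatnonzero(~mesh.roi_mask)
    rng_out = np.random.default_rng(int(root.integers(2**31)))
    seeds = [out_idx[rng_out.integers(out_idx.size)]]
    for _ in range(spec.k_true - 1):
        dist, _ = _bfs_hops(np.array(seeds), out_idx, mesh.neighbors)
        seeds.append(out_idx[int(np.argmax(dist[out_idx]))])
    _, src = _bfs_hops(np.array(seeds), out_idx, mesh.neighbors)
    cortex_labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    cortex_labels[out_idx] = src[out_idx] + 1

    per_subject = {}
    runs = {}
    anatomy = {}
    for s in range(spec.n_subjects):
        sid = f"sub-{s + 1:02d}"
        per_subject[sid] = perturb_individual(
            template, mesh, spec.boundary_jitter, seed=int(root.integers(2**31))
        )
        thickness, curvature = simulate_anatomy(mesh, seed=int(root.integers(2**31)))
        anatomy[sid] = {"thickness": thickness, "curvature": curvature}
        for ses in range(spec.sessions_per_subject):
            ses_id = f"ses-{ses + 1}"
            run_list = []
            for r in range(spec.runs_per_session):
                run_list.append(
                    simulate_session(
                        mesh,
                        per_subject[sid],
                        cortex_labels,
                        spec,
                        seed=int(root.integers(2**31)),
                        subject_id=sid,
                        session_id=ses_id,
                        run_id=f"run-{r + 1}",
                    )
                )
            runs[(sid, ses_id)] = run_list
    truth = GroundTruth(group_template=template, per_subject=per_subject)
    return SyntheticCohort(spec, mesh, truth, runs, cortex_labels, anatomy)
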