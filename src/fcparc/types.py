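"""Core data model for surface-based functional-connectivity parcellation.

The central objects are a shared triangulated cortical surface
(:class:`SurfaceMesh`), per-subject vertex x time BOLD matrices
(:class:`TimeSeriesMatrix`), and network labelings of a region of interest
(:class:`Parcellation`).  All vertex indexing is 0-based; network labels are
1..K, with 0 reserved for "outside the ROI" in full-surface exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class SurfaceMesh:
    """Triangulated spherical-topology cortical surface.

    Parameters
    ----------
    vertex_coords : (V, 3) float array, mm
    triangles : (F, 3) int array of vertex indices
    neighbors : list of V int arrays, adjacency from shared triangle edges
    vertex_area : (V,) float array, mm^2; one third of incident triangle area
    roi_mask : (V,) bool array marking the parcellation region
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    neighbors: list
    vertex_area: np.ndarray
    roi_mask: np.ndarray
    _adjacency: sparse.csr_matrix = field(default=None, repr=False, compare=False)

    @classmethod
    def from_arrays(cls, vertex_coords, triangles, roi_mask=None):
        """Build neighbor lists and per-vertex areas from raw geometry."""
        vertex_coords = np.asarray(vertex_coords, dtype=float)
        triangles = np.asarray(triangles, dtype=np.int64)
        n = len(vertex_coords)
        if triangles.size and triangles.max() >= n:
            raise ValidationError("triangle index exceeds vertex count")
        # symmetric adjacency from triangle edges
        edges = np.vstack(
            [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
        )
        data = np.ones(len(edges), dtype=np.int8)
        adj = sparse.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
        adj = ((adj + adj.T) > 0).tocsr()
        neighbors = [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(n)]
        # triangle areas -> one third to each corner vertex
        a = vertex_coords[triangles[:, 0]]
        b = vertex_coords[triangles[:, 1]]
        c = vertex_coords[triangles[:, 2]]
        tri_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        vertex_area = np.zeros(n)
        for corner in range(3):
            np.add.at(vertex_area, triangles[:, corner], tri_area / 3.0)
        if roi_mask is None:
            roi_mask = np.ones(n, dtype=bool)
        roi_mask = np.asarray(roi_mask, dtype=bool)
        mesh = cls(vertex_coords, triangles, neighbors, vertex_area, roi_mask, adj)
        mesh.validate()
        return mesh

    # -- derived views ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def roi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roi_mask)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        if self._adjacency is None:
            object.__setattr__(self, "_adjacency", _adjacency_from_neighbors(self.neighbors))
        return self._adjacency

    def components(self, vertex_indices) -> list:
        """Connected components of the subgraph induced by ``vertex_indices``.

        Returns a list of int arrays of vertex indices (full-mesh numbering).
        """
        vertex_indices = np.asarray(vertex_indices)
        if vertex_indices.size == 0:
            return []
        sub = self.adjacency[vertex_indices][:, vertex_indices]
        n_comp, labels = csgraph.connected_components(sub, directed=False)
        return [vertex_indices[labels == c] for c in range(n_comp)]

    def validate(self):
        if self.triangles.size and self.triangles.max() >= self.n_vertices:
            raise ValidationError("triangle index exceeds vertex count")
        if np.any(self.vertex_area <= 0):
            raise ValidationError("all vertex areas must be positive")
        a = self.vertex_coords[self.triangles[:, 0]]
        b = self.vertex_coords[self.triangles[:, 1]]
        c = self.vertex_coords[self.triangles[:, 2]]
        total = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
        if not np.isclose(self.vertex_area.sum(), total, rtol=1e-6):
            raise ValidationError("vertex areas do not sum to total triangle area")
        for i, nb in enumerate(self.neighbors):
            for j in nb[:2]:  # spot-check symmetry cheaply
                if i not in self.neighbors[j]:
                    raise ValidationError("neighbor relation is not symmetric")


def _adjacency_from_neighbors(neighbors):
    indptr = np.cumsum([0] + [len(nb) for nb in neighbors])
    indices = np.concatenate([np.asarray(nb) for nb in neighbors])
    data = np.ones(len(indices), dtype=np.int8)
    return sparse.csr_matrix((data, indices, indptr), shape=(len(neighbors),) * 2)


@dataclass
class TimeSeriesMatrix:
    """Vertex x timepoint BOLD matrix for one subject/session/run."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    session_id: str = ""
    run_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValidationError("time series must be 2-D with >= 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class Parcellation:
    """ROI-vertex -> network-label map with K networks.

    ``labels`` is aligned with the mesh's ROI vertices in increasing
    vertex-index order; entries are integers in 1..k.
    """

    labels: np.ndarray
    k: int
    level: str = "group"  # "group" | "individual"
    provenance: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector over ROI vertices")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValidationError(f"labels must lie in 1..{self.k}")
        if self.level not in ("group", "individual"):
            raise ValidationError("level must be 'group' or 'individual'")

    @property
    def n_roi(self) -> int:
        return self.labels.size

    def network_sizes(self) -> np.ndarray:
        """Vertex count per label 1..k."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def full_surface_labels(self, mesh: SurfaceMesh) -> np.ndarray:
        """Labels on the whole mesh, 0 outside the ROI."""
        full = np.zeros(mesh.n_vertices, dtype=np.int64)
        full[mesh.roi_indices] = self.labels
        return full


@dataclass
class TaskZMap:
    """Per-ROI-vertex task-contrast z-scores."""

    z: np.ndarray
    contrast_name: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("z-map contains non-finite values")


@dataclass
class SimilarityMatrix:
    """Subject x subject similarity (Dice, Spearman-anatomy, ...)."""

    values: np.ndarray
    metric_name: str
    subject_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix must be square")
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class MetricReport:
    """Per-network values plus their network-size-weighted mean."""

    per_network: dict
    weighted_mean: float
    metric_name: str
    provenance: str = ""
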