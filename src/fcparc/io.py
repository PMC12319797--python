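"""Readers and writers for the pipeline's on-disk formats.

Time series travel as TSV (small), HDF5 (large), or GIFTI ``.func.gii``;
parcellations as two-column TSV (0-based ROI vertex index, label) or
FreeSurfer ``.annot``; meshes as GIFTI ``.surf.gii``.  All writers are
exact inverses of the readers on valid inputs, and none embeds timestamps,
so outputs are bit-reproducible.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import freesurfer as nibfs

from .types import Parcellation, SurfaceMesh, TimeSeriesMatrix, ValidationError

TS_FORMATS = ("tsv", "hdf5", "gifti")


def _require_exists(path):
    if not os.path.exists(path):
        raise IOError(f"input file not found: {path}")


# ---------------------------------------------------------------- time series

def write_timeseries(ts: TimeSeriesMatrix, path, format: str):
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# tr_seconds={ts.tr_seconds!r}\t"
                     f"subject={ts.subject_id}\tsession={ts.session_id}\t"
                     f"run={ts.run_id}\n")
            fh.write("\t".join(f"t{j}" for j in range(ts.n_timepoints)) + "\n")
            for row in ts.data:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "hdf5":
        with h5py.File(path, "w", track_order=False) as fh:
            dset = fh.create_dataset("data", data=ts.data, track_times=False)
            dset.attrs["tr_seconds"] = ts.tr_seconds
            dset.attrs["subject_id"] = ts.subject_id
            dset.attrs["session_id"] = ts.session_id
            dset.attrs["run_id"] = ts.run_id
    elif format == "gifti":
        img = nib.gifti.GiftiImage()
        img.meta["tr_seconds"] = repr(ts.tr_seconds)
        img.meta["subject_id"] = ts.subject_id
        img.meta["session_id"] = ts.session_id
        img.meta["run_id"] = ts.run_id
        for j in range(ts.n_timepoints):
            img.add_gifti_data_array(nib.gifti.GiftiDataArray(
                ts.data[:, j].astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES"))
        nib.save(img, path)
    else:
        raise ValidationError(f"unknown time-series format: {format}")


def read_timeseries(path, format: str, tr_seconds: float = None) -> TimeSeriesMatrix:
    _require_exists(path)
    if format == "tsv":
        meta = {"tr_seconds": tr_seconds or 1.0, "subject": "", "session": "", "run": ""}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for part in first[1:].strip().split("\t"):
                    key, _, val = part.partition("=")
                    meta[key.strip()] = val
                header = fh.readline()
            else:
                header = first
            n_t = len(header.strip().split("\t"))
            rows = []
            for i, line in enumerate(fh):
                cells = line.rstrip("\n").split("\t")
                row = []
                for j, cell in enumerate(cells):
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise ValidationError(
                            f"non-numeric cell at row {i}, column {j} of {path}: {cell!r}"
                        )
                if len(row) != n_t:
                    raise ValidationError(f"row {i} of {path} has {len(row)} cells, "
                                          f"expected {n_t}")
                rows.append(row)
        return TimeSeriesMatrix(np.array(rows), float(meta["tr_seconds"]),
                                meta["subject"], meta["session"], meta["run"])
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            dset = fh["data"]
            return TimeSeriesMatrix(dset[()], float(dset.attrs["tr_seconds"]),
                                    str(dset.attrs["subject_id"]),
                                    str(dset.attrs["session_id"]),
                                    str(dset.attrs["run_id"]))
    if format == "gifti":
        img = nib.load(path)
        data = np.column_stack([d.data for d in img.darrays])
        meta = dict(img.meta)
        tr = float(meta.get("tr_seconds", "1.0"))
        return TimeSeriesMatrix(data, tr_seconds or tr,
                                meta.get("subject_id", ""),
                                meta.get("session_id", ""), meta.get("run_id", ""))
    raise ValidationError(f"unknown time-series format: {format}")


# --------------------------------------------------------------- parcellation

def _check_contiguous(labels):
    uniq = np.unique(labels)
    if uniq.min() < 1:
        raise ValidationError("labels must be >= 1 (0 is reserved for outside ROI)")
    k = int(uniq.max())
    if not np.array_equal(uniq, np.arange(1, k + 1)):
        raise ValidationError("labels must be contiguous 1..K")
    return k


def write_parcellation(parc: Parcellation, path, format: str,
                       roi_indices=None, n_vertices: int = None):
    if format == "tsv":
        if roi_indices is None:
            roi_indices = np.arange(parc.n_roi)
        df = pd.DataFrame({"vertex_index": np.asarray(roi_indices, dtype=int),
                           "label": parc.labels})
        df.to_csv(path, sep="\t", index=False)
    elif format == "annot":
        if roi_indices is None or n_vertices is None:
            raise ValidationError("annot export needs roi_indices and n_vertices")
        full = np.zeros(n_vertices, dtype=np.int32)
        full[np.asarray(roi_indices, dtype=int)] = parc.labels
        # generated color table: distinct colors, entry 0 = unknown
        rng = np.random.default_rng(12345)
        colors = rng.integers(0, 255, size=(parc.k + 1, 3))
        colors[0] = (25, 25, 25)
        ctab = np.column_stack([colors, np.zeros(parc.k + 1, dtype=int)]).astype(np.int32)
        names = [b"unknown"] + [f"network-{i}".encode() for i in range(1, parc.k + 1)]
        nibfs.write_annot(path, full, ctab, names, fill_ctab=True)
    else:
        raise ValidationError(f"unknown parcellation format: {format}")


def read_parcellation(path, format: str):
    """Returns (Parcellation, roi_indices)."""
    _require_exists(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != ["vertex_index", "label"]:
            raise ValidationError("parcellation TSV must have columns "
                                  "vertex_index, label")
        order = np.argsort(df["vertex_index"].to_numpy())
        labels = df["label"].to_numpy()[order]
        k = _check_contiguous(labels)
        return (Parcellation(labels, k),
                df["vertex_index"].to_numpy()[order].astype(np.int64))
    if format == "annot":
        full, ctab, names = nibfs.read_annot(path)
        roi = np.flatnonzero(full > 0)
        labels = full[roi]
        k = _check_contiguous(labels)
        return Parcellation(labels.astype(np.int64), k), roi
    raise ValidationError(f"unknown parcellation format: {format}")


# ----------------------------------------------------------------------- mesh

def write_mesh(mesh: SurfaceMesh, path, roi_path=None):
    """Mesh to GIFTI ``.surf.gii``; ROI mask optionally to a label TSV."""
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
    nib.save(img, path)
    if roi_path is not None:
        pd.DataFrame({"vertex_index": np.arange(mesh.n_vertices),
                      "in_roi": mesh.roi_mask.astype(int)}).to_csv(
            roi_path, sep="\t", index=False)


def read_mesh(path, roi_path=None) -> SurfaceMesh:
    _require_exists(path)
    img = nib.load(path)
    coords = img.darrays[0].data.astype(float)
    tris = img.darrays[1].data.astype(np.int64)
    roi_mask = None
    if roi_path is not None:
        df = pd.read_csv(roi_path, sep="\t")
        roi_mask = df["in_roi"].to_numpy().astype(bool)
    return SurfaceMesh.from_arrays(coords, tris, roi_mask)


# ----------------------------------------------------------------- flat files

def write_vector_tsv(values, path, column: str, index_name: str = "vertex_index"):
    pd.DataFrame({index_name: np.arange(len(values)), column: values}).to_csv(
        path, sep="\t", index=False)


def read_vector_tsv(path, column: str):
    _require_exists(path)
    return pd.read_csv(path, sep="\t")[column].to_numpy()


def write_similarity_tsv(sim, path):
    df = pd.DataFrame(sim.values, index=sim.subject_ids, columns=sim.subject_ids)
    df.index.name = "subject"
    df.to_csv(path, sep="\t")


def read_similarity_tsv(path, metric_name="similarity"):
    from .types import SimilarityMatrix

    _require_exists(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(df.to_numpy(dtype=float), metric_name,
                            [str(c) for c in df.columns])
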