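"""File dialects: Matrix Market connectivity matrices with JSON
sidecars, TSV label tables and map vectors."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DomainError, MetadataError
from .synthetic import CohortGeometry, ConnectivityMatrix, GroundTruthBundle


def geometry_hash(geometry: CohortGeometry) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(geometry.parcel_of.astype("U16")).tobytes())
    h.update(np.ascontiguousarray(geometry.hemisphere_of.astype("U8")).tobytes())
    h.update(np.round(geometry.voxel_position, 12).tobytes())
    return h.hexdigest()[:16]


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path,
                       geometry: CohortGeometry | None = None) -> Path:
    """Write a connectivity matrix as sparse Matrix Market plus a JSON
    sidecar carrying subject/species/hemisphere metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
    sidecar = {"subject_id": matrix.subject_id, "species": matrix.species,
               "hemisphere": matrix.hemisphere,
               "shape": list(matrix.values.shape)}
    if geometry is not None:
        sidecar["geometry_hash"] = geometry_hash(geometry)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    """Read a Matrix Market connectivity matrix and its JSON sidecar.

    Negative entries are a domain error reported with their coordinate;
    a missing sidecar is a metadata error.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise MetadataError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    m = scipy.io.mmread(str(path))
    if scipy.sparse.issparse(m):
        coo = m.tocoo()
        neg = np.flatnonzero(coo.data < 0)
        if neg.size:
            i = neg[0]
            raise DomainError(
                f"negative entry {coo.data[i]} at "
                f"(row={coo.row[i]}, col={coo.col[i]}) in {path}")
        values = np.asarray(m.todense(), dtype=float)
    else:
        values = np.asarray(m, dtype=float)
        if values.size and values.min() < 0:
            r, c = np.unravel_index(np.argmin(values), values.shape)
            raise DomainError(
                f"negative entry {values[r, c]} at (row={r}, col={c}) in {path}")
    return ConnectivityMatrix(meta.get("subject_id", ""),
                              meta.get("species", ""),
                              meta.get("hemisphere", ""), values)


def write_labels(geometry: CohortGeometry, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"vertex_index": np.arange(geometry.n_vertices),
                  "parcel": geometry.parcel_of,
                  "hemisphere": geometry.hemisphere_of}
                 ).to_csv(path, sep="\t", index=False)
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bundles(bundles: list[GroundTruthBundle], path: str | Path) -> Path:
    """Ground-truth bundle loadings as a long-form TSV (one row per
    bundle, loadings serialized as separate gray/white TSVs beside it)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [{"bundle_id": b.bundle_id, "bundle_class": b.bundle_class,
          "species": b.species, "subject_id": b.subject_id,
          "hemisphere": b.hemisphere, "ofc_fraction": b.ofc_fraction}
         for b in bundles])
    meta.to_csv(path, sep="\t", index=False)
    gray = pd.DataFrame({f"{b.species}|{b.subject_id}|{b.hemisphere}|{b.bundle_id}":
                         b.gray_loading for b in bundles})
    white = pd.DataFrame({f"{b.species}|{b.subject_id}|{b.hemisphere}|{b.bundle_id}":
                          b.white_loading for b in bundles})
    gray.to_csv(path.with_name(path.stem + "_gray.tsv"), sep="\t", index=False)
    white.to_csv(path.with_name(path.stem + "_white.tsv"), sep="\t", index=False)
    return path


def write_vector(vector: np.ndarray, path: str | Path, name: str = "value"
                 ) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({name: np.asarray(vector)}).to_csv(path, sep="\t", index=False)
    return path


def read_vector(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").iloc[:, 0].to_numpy(dtype=float)


def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", index=False,
                                            header=False)
    return path


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
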