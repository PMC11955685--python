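"""Data model and delimited-text I/O for connectome gradient analyses.

All matrices travel as plain tab-delimited text so that cohorts are portable
and diffable.  The in-memory containers are thin dataclasses around numpy
arrays and pandas frames with the invariants of each object enforced at
construction time:

* :class:`RegionTable` — cortical + subcortical parcel metadata (hemisphere,
  functional network, volume, unit-sphere centroid).
* :class:`Connectome` — symmetric non-negative cortical structural
  connectivity for one subject.
* :class:`SubcorticalConnectivity` — subcortical-to-cortical connectivity.
* :class:`CohortManifest` — subject table (group, age, sex) plus paths to the
  per-subject matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CORTICAL_NETWORKS",
    "SUBCORTICAL_STRUCTURES",
    "RegionTable",
    "Connectome",
    "SubcorticalConnectivity",
    "CohortManifest",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "volume_scale",
    "sparsify",
]

#: Canonical seven-system cortical parcellation labels (visual, somatomotor,
#: dorsal attention, ventral attention, limbic, frontoparietal, default mode).
CORTICAL_NETWORKS = ("Vis", "Smn", "Dan", "Van", "Lim", "Fpn", "Dmn")

#: Eight bilateral deep-gray structures used for subcortical profiles.
SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventral-DC",
)

_REGION_COLUMNS = [
    "region_id",
    "name",
    "hemisphere",
    "network",
    "volume",
    "x",
    "y",
    "z",
    "is_cortical",
]


class MatrixParseError(ValueError):
    """A delimited numeric table contained a non-numeric or non-finite cell."""


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path, expected_shape=None):
    """Read a tab- or comma-delimited numeric matrix.

    An optional first header row (region names) is detected and discarded.
    NaN / Inf cells are rejected — connectivity and expression matrices must
    be finite everywhere.

    Parameters
    ----------
    path : str or Path
        File to read.
    expected_shape : tuple of int, optional
        If given, the parsed matrix must have exactly this shape.

    Returns
    -------
    numpy.ndarray
        Matrix of float64 values.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "\t" if "\t" in first else ","
    tokens = [t for t in first.rstrip("\n").split(delim)]
    header = not _all_numeric(tokens)
    df = pd.read_csv(
        path,
        sep=delim,
        header=0 if header else None,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    raw = df.to_numpy()
    out = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            try:
                out[i, j] = float(raw[i, j])
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell {raw[i, j]!r} at row {i}, column {j}"
                ) from None
    bad = ~np.isfinite(out)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixParseError(
            f"{path}: non-finite value {out[i, j]!r} at row {i}, column {j}"
        )
    if expected_shape is not None and out.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: expected shape {tuple(expected_shape)}, got {out.shape}"
        )
    return out


def _all_numeric(tokens):
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def write_matrix(path, matrix, header=None):
    """Write a numeric matrix as TSV, lossless to full float64 precision."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(str(h) for h in header) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class RegionTable:
    """Parcel metadata: id, name, hemisphere, network, volume, centroid.

    Cortical centroids live on the unit sphere (the geometry used by the
    spin-permutation null); subcortical rows carry interior anchor points and
    a structure name instead of a functional-network label.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in _REGION_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        t = t.reset_index(drop=True)
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or not np.array_equal(
            np.sort(ids), np.arange(len(ids))
        ):
            raise ValueError("region_id must be unique and contiguous from 0")
        t = t.sort_values("region_id").reset_index(drop=True)
        if (t["volume"] <= 0).any():
            raise ValueError("all region volumes must be positive")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {bad_hemi}")
        cort = t["is_cortical"].astype(bool)
        xyz = t.loc[cort, ["x", "y", "z"]].to_numpy(float)
        norms = np.linalg.norm(xyz, axis=1)
        if xyz.size and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("cortical centroids must have unit norm")
        self.table = t

    # -- accessors ---------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.table["is_cortical"].to_numpy(bool)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def volumes(self) -> np.ndarray:
        return self.table["volume"].to_numpy(float)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def cortical(self) -> "RegionTable":
        """Sub-table of cortical rows, region ids renumbered from 0."""
        sub = self.table[self.cortical_mask].reset_index(drop=True).copy()
        sub["region_id"] = np.arange(len(sub))
        return RegionTable(sub)

    def subcortical(self) -> pd.DataFrame:
        return self.table[~self.cortical_mask].reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "RegionTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(df)

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return Path(path)


@dataclass
class Connectome:
    """One subject's cortical structural connectivity matrix."""

    weights: np.ndarray
    region_table: RegionTable

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must be square")
        n_cortical = int(self.region_table.cortical_mask.sum())
        if w.shape[0] != n_cortical:
            raise ValueError(
                f"connectome size {w.shape[0]} != cortical region count {n_cortical}"
            )
        if not np.isfinite(w).all():
            raise ValueError("connectome contains non-finite values")
        if np.abs(w - w.T).max(initial=0.0) > 1e-10:
            raise ValueError("connectome weights must be symmetric (tol 1e-10)")
        if (w < 0).any():
            raise ValueError("connectome weights must be non-negative")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValueError("connectome diagonal must be zero")
        self.weights = w

    @classmethod
    def read_tsv(cls, path, region_table: RegionTable) -> "Connectome":
        n = int(region_table.cortical_mask.sum())
        return cls(read_matrix(path, expected_shape=(n, n)), region_table)

    def to_tsv(self, path):
        return write_matrix(path, self.weights)


@dataclass
class SubcorticalConnectivity:
    """Subcortical-to-cortical connectivity (structures x cortical regions)."""

    weights: np.ndarray
    structures: list = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("subcortical connectivity must be 2-D")
        if not np.isfinite(w).all():
            raise ValueError("subcortical connectivity contains non-finite values")
        if (w < 0).any():
            raise ValueError("subcortical connectivity must be non-negative")
        if self.structures and len(self.structures) != w.shape[0]:
            raise ValueError("structure label count must match row count")
        self.weights = w

    @classmethod
    def read_tsv(cls, path, n_cortical=None, structures=None):
        w = read_matrix(path)
        if n_cortical is not None and w.shape[1] != n_cortical:
            raise ValueError(
                f"subcortical matrix has {w.shape[1]} columns, expected {n_cortical}"
            )
        return cls(w, list(structures) if structures else [])

    def to_tsv(self, path):
        return write_matrix(path, self.weights)


@dataclass
class CohortManifest:
    """Subject table binding group / age / sex to the per-subject matrices."""

    table: pd.DataFrame

    _COLUMNS = ["subject_id", "group", "age", "sex", "connectome_path", "subcortical_path"]

    def __post_init__(self):
        t = self.table.reset_index(drop=True)
        missing = [c for c in self._COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"cohort manifest missing columns: {missing}")
        if t["subject_id"].duplicated().any():
            raise ValueError("subject_id values must be unique")
        bad_group = set(t["group"]) - {"control", "patient"}
        if bad_group:
            raise ValueError(f"unknown group labels: {bad_group}")
        counts = t["group"].value_counts()
        for g in ("control", "patient"):
            if counts.get(g, 0) < 2:
                raise ValueError(f"group '{g}' needs at least 2 subjects")
        bad_sex = set(t["sex"]) - {"female", "male"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {bad_sex}")
        if (t["age"] <= 0).any():
            raise ValueError("ages must be positive")
        self.table = t

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return Path(path)


# ---------------------------------------------------------------------------
# connectome normalization


def volume_scale(weights, volumes, rule="sum"):
    """Scale connectivity by the inverse of the two region volumes.

    ``rule='sum'`` divides entry (i, j) by ``volumes[i] + volumes[j]`` (the
    common streamline-normalization convention); ``rule='product'`` divides by
    ``volumes[i] * volumes[j]``.
    """
    w = np.asarray(weights, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if v.ndim != 1 or len(v) != w.shape[0]:
        raise ValueError("volumes length must match matrix row count")
    if (v <= 0).any():
        raise ValueError("volumes must be strictly positive")
    if rule == "sum":
        denom = v[:, None] + v[None, :]
    elif rule == "product":
        denom = v[:, None] * v[None, :]
    else:
        raise ValueError(f"unknown volume-scaling rule {rule!r}")
    if w.ndim == 2 and w.shape[0] != w.shape[1]:
        # rectangular (subcortical x cortical): rows are structures
        raise ValueError("volume_scale expects a square matrix; see volume_scale_rect")
    return w / denom


def volume_scale_rect(weights, row_volumes, col_volumes, rule="sum"):
    """Volume scaling for rectangular (subcortical x cortical) matrices."""
    w = np.asarray(weights, dtype=float)
    rv = np.asarray(row_volumes, dtype=float)
    cv = np.asarray(col_volumes, dtype=float)
    if (rv <= 0).any() or (cv <= 0).any():
        raise ValueError("volumes must be strictly positive")
    if w.shape != (len(rv), len(cv)):
        raise ValueError("volume vectors must match matrix shape")
    if rule == "sum":
        denom = rv[:, None] + cv[None, :]
    elif rule == "product":
        denom = rv[:, None] * cv[None, :]
    else:
        raise ValueError(f"unknown volume-scaling rule {rule!r}")
    return w / denom


def sparsify(weights, sparsity):
    """Zero the smallest fraction of off-diagonal entries (unordered pairs).

    Exactly ``round((1 - sparsity) * n_pairs)`` pairs survive.  Ties at the
    threshold are resolved by keeping the pair with the lower (row, col)
    index, so output is deterministic.  ``sparsity=0`` returns a copy of the
    input unchanged.
    """
    w = np.asarray(weights, dtype=float)
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must lie in [0, 1)")
    if np.abs(w - w.T).max(initial=0.0) > 1e-10:
        raise ValueError("sparsify expects a symmetric matrix")
    if sparsity == 0:
        return w.copy()
    n = w.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = w[rows, cols]
    n_pairs = len(vals)
    n_keep = int(round((1 - sparsity) * n_pairs))
    n_zero = n_pairs - n_keep
    # ascending value; ties: higher (row, col) zeroed first, keeping lower pairs
    order = np.lexsort((-cols, -rows, vals))
    kill = order[:n_zero]
    out = w.copy()
    out[rows[kill], cols[kill]] = 0.0
    out[cols[kill], rows[kill]] = 0.0
    return out
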