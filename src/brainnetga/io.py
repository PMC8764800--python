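"""Reading and writing connectome datasets.

A dataset is a manifest TSV (columns ``subject_id``, ``label``,
``matrix_path``) pointing at dense delimited-text files, one region-by-region
functional-connectivity matrix per subject, plus an atlas giving the region
names.  Matrices may also be computed on the fly from ROI time-series tables
with :func:`correlation_matrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Literal class labels used in manifests. SSD (schizophrenia spectrum
#: disorders) is the positive class throughout the package.
POSITIVE_LABEL = "SSD"
NEGATIVE_LABEL = "HC"
LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)

SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """A dataset or matrix violates a structural invariant."""


class DimensionError(ValidationError):
    """A matrix does not match the atlas size."""


@dataclass(frozen=True)
class Atlas:
    """A brain parcellation: an ordered list of unique region names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("atlas region names must be unique")
        if len(self.names) < 1:
            raise ValidationError("atlas must have at least one region")

    @property
    def n_regions(self) -> int:
        return len(self.names)


def default_atlas() -> Atlas:
    """The 116-region AAL (Automated Anatomical Labeling) atlas."""
    text = resources.files("brainnetga.data").joinpath("aal116.txt").read_text()
    return Atlas(tuple(text.split()))


def load_atlas(path: str | Path) -> Atlas:
    """Load an atlas from a text file with one region name per line."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Atlas(tuple(names))


@dataclass
class SubjectRecord:
    subject_id: str
    label: str
    matrix: np.ndarray


@dataclass
class ConnectomeDataset:
    """Per-subject connectivity matrices with labels and atlas metadata."""

    subjects: list[SubjectRecord]
    atlas: Atlas

    def __len__(self) -> int:
        return len(self.subjects)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``(X, y)``: X of shape (n_subjects, n, n), y of labels."""
        X = np.stack([s.matrix for s in self.subjects])
        y = np.array([s.label for s in self.subjects])
        return X, y


def _check_square_symmetric(values: np.ndarray, *, tol: float = SYMMETRY_TOL,
                            context: str = "matrix") -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DimensionError(f"{context}: expected a square matrix, got shape {values.shape}")
    if not np.isfinite(values).all():
        raise ValidationError(f"{context}: non-finite entries")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        # rejected, not repaired: silent symmetrization would hide upstream bugs
        raise ValidationError(
            f"{context}: asymmetric beyond tolerance ({asym:.3g} > {tol:.3g})")
    return values


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a dense connectivity matrix from delimited text.

    The dialect (whitespace vs. comma separated) is sniffed from the first
    line; no header row is expected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return values


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited text, full double precision."""
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.17g")


def load_dataset(manifest_path: str | Path, atlas: Atlas) -> ConnectomeDataset:
    """Load a dataset from a manifest TSV, validating every matrix.

    Each matrix must be square of size ``atlas.n_regions``, finite and
    symmetric within ``SYMMETRY_TOL``; subject ids must be unique and labels
    must be ``SSD`` or ``HC``.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"subject_id", "label", "matrix_path"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id in manifest: {sorted(set(dup))}")

    subjects: list[SubjectRecord] = []
    for row in df.itertuples(index=False):
        if row.label not in LABELS:
            raise ValidationError(
                f"subject {row.subject_id}: label {row.label!r} not in {LABELS}")
        mpath = Path(row.matrix_path)
        if not mpath.is_absolute():
            mpath = manifest_path.parent / mpath
        if not mpath.exists():
            raise FileNotFoundError(
                f"subject {row.subject_id}: matrix file not found: {mpath}")
        values = read_matrix(mpath)
        if values.shape != (atlas.n_regions, atlas.n_regions):
            raise DimensionError(
                f"subject {row.subject_id}: matrix is {values.shape}, "
                f"atlas has {atlas.n_regions} regions")
        values = _check_square_symmetric(values, context=f"subject {row.subject_id}")
        subjects.append(SubjectRecord(row.subject_id, row.label, values))
    return ConnectomeDataset(subjects, atlas)


def correlation_matrix(ts: np.ndarray, *, diag: float = 0.0,
                       region_names: Sequence[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix of a T-by-n ROI time-series table.

    Entry (i, j) is the Pearson correlation of region columns i and j; the
    diagonal is set to ``diag`` (self-connections carry no information for
    edge filters, so the default is 0).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValidationError(f"time series must be 2-D (T x n), got shape {ts.shape}")
    if ts.shape[0] < 3:
        raise ValidationError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ([region_names[i] for i in bad] if region_names is not None
                 else list(bad))
        raise ValidationError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, diag)
    return r


def fisher_z(m: np.ndarray, *, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher z-transform (arctanh) of off-diagonal correlations.

    Entries with ``|r| >= 1`` are clipped to ``±clip`` before the transform
    (logged); the diagonal is preserved as-is.
    """
    m = np.asarray(m, dtype=float)
    off = ~np.eye(m.shape[0], dtype=bool)
    n_clip = int(np.sum(np.abs(m[off]) >= 1.0))
    if n_clip:
        logger.info("fisher_z: clipping %d entries with |r| >= 1", n_clip)
    out = m.copy()
    out[off] = np.arctanh(np.clip(m[off], -clip, clip))
    return out
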