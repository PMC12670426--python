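"""Trajectory pose-ordering statistics and dihedral PCA.

Given ligand coordinates already superposed on the receptor (Cα alignment
is assumed done upstream), the module measures how tightly a simulated
ligand keeps to a crystallographic reference pose:

* per-frame ligand RMSD to the reference (no re-fitting — a rigidly
  translated ligand scores its full displacement),
* bound-frame classification at a strict RMSD < threshold (2 Å default),
* deterministic equally spaced frame subsampling,
* dPCA: principal component analysis on sine/cosine-transformed dihedral
  angles, which removes the ±180° wrap-around artifact of raw angles.

``DihedralPCA`` is a scikit-learn transformer; it is fitted on the pooled
dihedrals of all ligands and then applied per ligand with the same means
and loadings, so embeddings of different ligands share one coordinate
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .errors import DegenerateModelError, ValidationError

__all__ = [
    "PoseTrajectory",
    "DihedralDataset",
    "BoundFrameCount",
    "rmsd_to_reference",
    "count_bound_frames",
    "subsample_equally_spaced",
    "dihedral_featurize",
    "DihedralPCA",
    "dpca_fit",
    "dpca_transform",
]


@dataclass
class PoseTrajectory:
    """Receptor-aligned ligand coordinates plus a reference pose.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å, time-ordered;
    ``reference`` is (n_atoms, 3) with identical atom ordering.
    """

    frames: np.ndarray
    reference: np.ndarray
    atom_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.reference.shape != self.frames.shape[1:]:
            raise ValidationError(
                f"reference shape {self.reference.shape} does not match frames "
                f"{self.frames.shape[1:]}"
            )
        if not (np.all(np.isfinite(self.frames)) and np.all(np.isfinite(self.reference))):
            raise ValidationError("coordinates must be finite")
        if self.atom_labels and len(self.atom_labels) != self.frames.shape[1]:
            raise ValidationError("atom_labels length must equal the atom count")

    @property
    def n_frames(self):
        return self.frames.shape[0]

    @property
    def n_atoms(self):
        return self.frames.shape[1]


@dataclass
class DihedralDataset:
    """Per-frame dihedral angles (degrees) for one or more ligands.

    ``data`` carries columns ``ligand_id``, ``frame`` and one ``phi{i}``
    column per dihedral, wrapped to (-180, 180].
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in ("ligand_id", "frame"):
            if col not in self.data.columns:
                raise ValidationError(f"dihedral table is missing column {col!r}")
        if not self.angle_columns:
            raise ValidationError("dihedral table has no phi* columns")
        angles = self.angles()
        if not np.all(np.isfinite(angles)):
            raise ValidationError("dihedral angles must be finite")

    @property
    def angle_columns(self):
        return [c for c in self.data.columns if c.startswith("phi")]

    @property
    def n_dihedrals(self):
        return len(self.angle_columns)

    def angles(self, ligand_id=None):
        """Angle matrix (n_frames, n_dihedrals) in degrees."""
        table = self.data if ligand_id is None else self.data[
            self.data["ligand_id"] == ligand_id
        ]
        return table[self.angle_columns].to_numpy(dtype=float)

    @property
    def ligand_ids(self):
        return list(pd.unique(self.data["ligand_id"]))


class BoundFrameCount(NamedTuple):
    count: int
    fraction: float


def rmsd_to_reference(traj: PoseTrajectory) -> np.ndarray:
    """Per-frame RMSD (Å) of ligand atoms to the reference pose.

    RMSD_t = sqrt(mean_i ||x_{t,i} - x_{ref,i}||^2).  Deliberately performs
    no superposition: frames are expected to arrive receptor-aligned, so a
    ligand drifting out of the site shows its full displacement.
    """
    diff = traj.frames - traj.reference[None, :, :]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


def count_bound_frames(rmsd_series, threshold=2.0) -> BoundFrameCount:
    """Frames with RMSD strictly below ``threshold`` (Å).

    Strict ``<`` is the classification convention; a frame exactly at the
    threshold counts as unbound.
    """
    series = np.asarray(rmsd_series, dtype=float).reshape(-1)
    if series.size == 0:
        raise ValidationError("RMSD series must be non-empty")
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold!r}")
    count = int(np.count_nonzero(series < threshold))
    return BoundFrameCount(count, count / series.size)


def subsample_equally_spaced(n_frames, n_samples) -> np.ndarray:
    """Deterministic equally spaced frame indices: floor(k·N/n), k = 0..n-1.

    Strictly increasing; consecutive spacings differ by at most 1.  With
    n_frames = 3000 and n_samples = 30 this is exactly stride 100.
    """
    if not (1 <= n_samples <= n_frames):
        raise ValidationError(
            f"need 1 <= n_samples <= n_frames, got n_samples={n_samples}, "
            f"n_frames={n_frames}"
        )
    return (np.arange(n_samples, dtype=np.int64) * n_frames) // n_samples


def dihedral_featurize(angles_deg) -> np.ndarray:
    """Sine/cosine featurization of dihedral angles (degrees).

    Column order is (sin φ1, cos φ1, sin φ2, cos φ2, …); the map is exactly
    periodic, so φ and φ + 360° produce identical rows.  Accepts an angle
    matrix or a :class:`DihedralDataset`.
    """
    if isinstance(angles_deg, DihedralDataset):
        angles_deg = angles_deg.angles()
    angles = np.asarray(angles_deg, dtype=float)
    if angles.ndim == 1:
        angles = angles[:, None]
    if not np.all(np.isfinite(angles)):
        raise ValidationError("dihedral angles must be finite")
    rad = np.deg2rad(angles)
    features = np.empty((angles.shape[0], 2 * angles.shape[1]))
    features[:, 0::2] = np.sin(rad)
    features[:, 1::2] = np.cos(rad)
    return features


class DihedralPCA(TransformerMixin, BaseEstimator):
    """PCA in the space of sine/cosine-transformed dihedral angles (dPCA).

    Fit on the pooled angle matrix of all ligands; transform projects any
    ligand's angles with the pooled feature means and loadings.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so embeddings are reproducible across runs.

    Parameters
    ----------
    n_components : int, default 2
        Retained components (dPC1, dPC2).

    Attributes
    ----------
    components_ : ndarray (n_components, 2·n_dihedrals)
        Orthonormal loadings over the sin/cos features.
    mean_ : ndarray
        Feature means used for centering.
    explained_variance_ : ndarray
        Eigenvalues of the feature covariance for the retained components.
    explained_variance_ratio_ : ndarray
        Their fractions of total variance.
    explained_variance_ratio_full_ : ndarray
        Fractions for the complete spectrum (sums to 1).
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y=None):
        """Fit on pooled dihedral angles (degrees), shape (n_frames, n_dihedrals)."""
        features = dihedral_featurize(X)
        if features.shape[0] < 2:
            raise ValidationError("dPCA needs at least 2 frames")
        if self.n_components > min(features.shape):
            raise ValidationError(
                f"n_components={self.n_components} exceeds feature rank bound "
                f"{min(features.shape)}"
            )
        # sin/cos features are bounded by 1, so 1e-12 total variance means
        # numerically constant input up to summation rounding.
        if float(features.var(axis=0).sum()) <= 1e-12:
            raise DegenerateModelError("dihedral features have zero variance")
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(features)
        components = pca.components_[: self.n_components].copy()
        # Sign convention: dominant loading of each component is positive.
        for row in components:
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1.0
        self.components_ = components
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_[: self.n_components].copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[
            : self.n_components
        ].copy()
        self.explained_variance_ratio_full_ = pca.explained_variance_ratio_.copy()
        self.n_features_in_ = features.shape[1]
        return self

    def transform(self, X):
        """Project dihedral angles (degrees) onto the fitted components."""
        features = dihedral_featurize(X)
        if features.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_ // 2} dihedrals, got {features.shape[1] // 2}"
            )
        return (features - self.mean_) @ self.components_.T


def dpca_fit(angles_deg, n_components=2) -> DihedralPCA:
    """Fit a :class:`DihedralPCA` on pooled dihedral angles (degrees)."""
    return DihedralPCA(n_components=n_components).fit(angles_deg)


def dpca_transform(model: DihedralPCA, angles_deg) -> np.ndarray:
    """Project dihedral angles with an already-fitted :class:`DihedralPCA`."""
    return model.transform(angles_deg)
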