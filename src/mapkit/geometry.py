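"""CoG point-cloud geometry: spatial normalization and confidence
ellipsoids.

A group's CoG cluster dispersion is summarized by the ellipsoid whose
semi-axes are the sample-covariance eigenvectors scaled by
sqrt(q·lambda_i), with q the chi-square quantile (3 df) at the chosen
confidence level.  The covariance is NOT divided by n: the ellipsoid
describes within-group scatter of the cluster, not the uncertainty of
its mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy.stats import chi2

from .config import DEFAULTS

# RAS axis labels for principal-orientation reporting
_AXIS_LABELS = ("lateral-medial", "anterior-posterior", "superior-inferior")


@dataclass
class Ellipsoid:
    center: np.ndarray          # 3-vector mm
    axis_lengths: np.ndarray    # 3 semi-axes, mm, descending
    axis_dirs: np.ndarray       # (3, 3) orthonormal rows, matching lengths
    volume: float               # cm³
    level: float                # confidence level in (0, 1)
    n_points: int = 0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis_lengths = np.asarray(self.axis_lengths, dtype=float)
        self.axis_dirs = np.asarray(self.axis_dirs, dtype=float)
        if (self.axis_lengths <= 0).any():
            raise ValueError("axis lengths must be positive")
        if (np.diff(self.axis_lengths) > 1e-9).any():
            raise ValueError("axis lengths must be descending")


def apply_affine(points: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Homogeneous 4×4 transform of one point or an (n, 3) array."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("expected a 4x4 matrix")
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("affine matrix is singular")
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ matrix[:3, :3].T + matrix[:3, 3]
    return out[0] if single else out


def fit_confidence_ellipsoid(points: np.ndarray,
                             level: float = DEFAULTS.ellipsoid_level,
                             ) -> Ellipsoid:
    """Confidence ellipsoid of a 3D point cloud.

    center = sample mean; semi-axis i = sqrt(q·lambda_i) along the i-th
    eigenvector of the sample covariance (n−1 divisor), with
    q = chi2.ppf(level, df=3); volume = (4/3)·pi·prod(semi-axes) in cm³.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError("need at least 4 three-dimensional points")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    rank = int((evals > 1e-10 * max(evals.max(), 1e-12)).sum())
    if rank < 3:
        raise ValueError(f"rank-deficient covariance (rank {rank} < 3)")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(level, df=3)
    lengths = np.sqrt(q * evals)
    volume = 4.0 / 3.0 * np.pi * float(np.prod(lengths)) / 1000.0
    return Ellipsoid(center=center, axis_lengths=lengths,
                     axis_dirs=evecs.T, volume=volume, level=level,
                     n_points=pts.shape[0])


def point_in_ellipsoid(e: Ellipsoid, p: np.ndarray) -> np.ndarray:
    """True iff the point lies inside or on the ellipsoid boundary
    (squared Mahalanobis distance within the chi-square bound).
    Accepts a single point or an (n, 3) array."""
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    local = (pts - e.center) @ e.axis_dirs.T / e.axis_lengths
    inside = (local ** 2).sum(axis=1) <= 1.0 + 1e-12
    return bool(inside[0]) if np.asarray(p).ndim == 1 else inside


def principal_orientation(e: Ellipsoid, tie_tol: float = 1e-6) -> str:
    """Coordinate-axis label with the largest |cosine| to the leading
    ellipsoid axis ("oblique" on a tie)."""
    lead = np.abs(e.axis_dirs[0])
    order = np.argsort(lead)[::-1]
    if lead[order[0]] - lead[order[1]] <= tie_tol:
        return "oblique"
    return _AXIS_LABELS[order[0]]


def ellipsoid_summary(ellipsoids: Mapping[str, Ellipsoid]) -> Dict[str, object]:
    """Volumes, principal orientations and pairwise volume ratios for a
    set of named group ellipsoids (assumed to share a normalized space)."""
    names = list(ellipsoids)
    volumes = {n: ellipsoids[n].volume for n in names}
    orientations = {n: principal_orientation(ellipsoids[n]) for n in names}
    ratios = {f"{a}/{b}": volumes[a] / volumes[b]
              for a in names for b in names if a != b}
    return {"volumes_cm3": volumes, "orientations": orientations,
            "volume_ratios": ratios}
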